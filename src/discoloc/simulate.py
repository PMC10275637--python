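"""Synthetic-data generators with ground-truth labels.

Everything downstream of I/O consumes summary statistics, so simulation
uses the summary-statistic (RSS) model directly: given locus LD ``R`` and
a sparse non-centrality vector λ over causal variants, the per-trait
z-scores are drawn MVN(R·λ, R). Betas and standard errors are
reconstructed from z, simulated allele frequency and sample size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SimulationError
from .io_formats import AnnotationMap, LDMatrix, SummaryStats

#: ridge added to LD before Cholesky; renormalized to unit diagonal
LD_RIDGE_EPS = 1e-6

SCENARIOS = ("H0", "H1", "H2", "H3", "H4", "H4_discordant")


@dataclass
class ScenarioTruth:
    """Ground truth for one simulated locus."""

    hypothesis: str                       # H0..H4
    causal_a: list[str] = field(default_factory=list)
    causal_b: list[str] = field(default_factory=list)
    sign_concordant: bool = True
    lam: float = 0.0

    def __post_init__(self):
        if self.hypothesis not in ("H0", "H1", "H2", "H3", "H4"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.hypothesis == "H4" and set(self.causal_a) != set(self.causal_b):
            raise ValueError("H4 requires identical causal ids in both traits")
        if self.hypothesis == "H3" and set(self.causal_a) & set(self.causal_b):
            raise ValueError("H3 requires distinct causal ids")

    @property
    def discordant(self) -> bool:
        return self.hypothesis == "H4" and not self.sign_concordant

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ScenarioTruth":
        return cls(**json.loads(s))


def _ridge_repair(r: np.ndarray, eps: float = LD_RIDGE_EPS) -> np.ndarray:
    """Minimal ridge repair: add eps·I then renormalize to unit diagonal."""
    p = r.shape[0]
    rr = r + eps * np.eye(p)
    d = np.sqrt(np.diag(rr))
    rr = rr / np.outer(d, d)
    np.fill_diagonal(rr, 1.0)
    return rr


def cholesky_of_ld(ld: LDMatrix, eps: float = LD_RIDGE_EPS) -> np.ndarray:
    rr = _ridge_repair(ld.r, eps)
    try:
        return np.linalg.cholesky(rr)
    except np.linalg.LinAlgError:
        rr = _ridge_repair(ld.r, 1e-3)
        try:
            return np.linalg.cholesky(rr)
        except np.linalg.LinAlgError as exc:
            raise SimulationError("LD matrix not PSD after ridge repair") from exc


def simulate_ld(p: int, decay: float, n_hap: int = 0,
                maf_range: tuple[float, float] = (0.05, 0.5),
                seed: int = 0, chrom: str = "1", start: int = 1_000_000,
                span: int = 200_000, prefix: str = "rs"
                ) -> tuple[LDMatrix, pd.DataFrame]:
    """Simulate locus LD plus variant metadata.

    With ``n_hap == 0`` (default) the correlation is AR(1):
    R_ij = decay^|i−j|. With ``n_hap > 0`` it is the empirical correlation
    of ``n_hap`` binary haplotypes generated with the same serial
    dependence. ``decay = 0`` gives identity LD; ``decay = 1`` is the
    degenerate all-ones matrix and raises.
    """
    if p < 2:
        raise DomainError("p must be >= 2")
    if not 0 <= decay <= 1:
        raise DomainError("decay must be in [0,1]")
    if decay == 1.0:
        raise SimulationError("decay=1 yields a degenerate all-ones LD matrix")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=p)

    if n_hap > 0:
        # serially correlated binary haplotypes -> empirical correlation
        h = np.empty((n_hap, p))
        h[:, 0] = rng.random(n_hap) < mafs[0]
        for j in range(1, p):
            copy = rng.random(n_hap) < decay
            fresh = rng.random(n_hap) < mafs[j]
            h[:, j] = np.where(copy, h[:, j - 1], fresh)
        sd = h.std(axis=0)
        if np.any(sd == 0):
            h[:, sd == 0] += rng.normal(0, 1e-6, size=(n_hap, int((sd == 0).sum())))
        r = np.corrcoef(h, rowvar=False)
    else:
        idx = np.arange(p)
        r = decay ** np.abs(idx[:, None] - idx[None, :])
    r = _ridge_repair(r)

    step = max(span // max(p - 1, 1), 1)
    meta = pd.DataFrame({
        "SNP": [f"{prefix}{i}" for i in range(p)],
        "CHR": chrom,
        "POS": start + step * np.arange(p),
        "EA": "A", "NEA": "G",
        "EAF": mafs,
    })
    ld = LDMatrix(meta["SNP"].tolist(), r)
    cholesky_of_ld(ld)  # fail fast if not repairable
    return ld, meta


def _stats_from_z(meta: pd.DataFrame, z: np.ndarray, n: int, trait_name: str,
                  trait_type: str, case_fraction: float | None) -> SummaryStats:
    eaf = meta["EAF"].to_numpy()
    phi = case_fraction if (trait_type == "case_control" and case_fraction) else None
    denom = 2.0 * n * eaf * (1.0 - eaf)
    if phi is not None:
        denom = denom * phi * (1.0 - phi)
    se = 1.0 / np.sqrt(denom)
    lnp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    df = meta[["SNP", "CHR", "POS", "EA", "NEA", "EAF"]].copy()
    df["BETA"] = z * se
    df["SE"] = se
    df["P"] = np.exp(lnp)
    df["LNP"] = lnp
    df["Z"] = z
    df["N"] = float(n)
    return SummaryStats(df, trait_name=trait_name, trait_type=trait_type,
                        case_fraction=case_fraction)


def simulate_gwas_pair(ld: LDMatrix, meta: pd.DataFrame, truth: ScenarioTruth,
                       n_a: int = 100_000, n_b: int = 100_000, seed: int = 0,
                       trait_type_a: str = "quantitative",
                       trait_type_b: str = "quantitative",
                       case_fraction_a: float | None = None,
                       case_fraction_b: float | None = None
                       ) -> tuple[SummaryStats, SummaryStats, ScenarioTruth]:
    """Draw a pair of trait z-score vectors z ~ MVN(R·λ, R) under ``truth``.

    A discordant H4 scenario flips the sign of λ for trait b.
    """
    if not np.isfinite(truth.lam):
        raise DomainError("lambda must be finite")
    rng = np.random.default_rng(seed)
    idx = {v: i for i, v in enumerate(ld.variant_ids)}
    lam_a = np.zeros(ld.p)
    lam_b = np.zeros(ld.p)
    for vid in truth.causal_a:
        lam_a[idx[vid]] = truth.lam
    sign_b = 1.0 if truth.sign_concordant else -1.0
    for vid in truth.causal_b:
        lam_b[idx[vid]] = sign_b * truth.lam
    chol = cholesky_of_ld(ld)
    z_a = ld.r @ lam_a + chol @ rng.standard_normal(ld.p)
    z_b = ld.r @ lam_b + chol @ rng.standard_normal(ld.p)
    a = _stats_from_z(meta, z_a, n_a, "trait_a", trait_type_a, case_fraction_a)
    b = _stats_from_z(meta, z_b, n_b, "trait_b", trait_type_b, case_fraction_b)
    return a, b, truth


@dataclass
class SimulatedLocus:
    """One locus: LD, metadata, paired trait stats and its ground truth."""

    locus_id: str
    ld: LDMatrix
    meta: pd.DataFrame
    stats_a: SummaryStats
    stats_b: SummaryStats
    truth: ScenarioTruth


def _make_truth(scenario: str, ids: list[str], lam: float,
                rng: np.random.Generator, ld: LDMatrix | None = None,
                max_r2_h3: float = 0.1) -> ScenarioTruth:
    if scenario == "H0":
        return ScenarioTruth("H0", [], [], True, lam)
    pick = lambda: ids[int(rng.integers(len(ids)))]  # noqa: E731
    if scenario == "H1":
        return ScenarioTruth("H1", [pick()], [], True, lam)
    if scenario == "H2":
        return ScenarioTruth("H2", [], [pick()], True, lam)
    if scenario == "H3":
        # distinct causals, weakly linked if LD is available
        best, best_r2 = None, np.inf
        for _ in range(200):
            va, vb = pick(), pick()
            if va == vb:
                continue
            if ld is None:
                return ScenarioTruth("H3", [va], [vb], True, lam)
            ia, ib = ld.index_of([va, vb])
            r2 = float(ld.r[ia, ib] ** 2)
            if r2 < max_r2_h3:
                return ScenarioTruth("H3", [va], [vb], True, lam)
            if r2 < best_r2:
                best, best_r2 = (va, vb), r2
        if best is None:
            raise SimulationError("could not draw distinct H3 causal pair")
        return ScenarioTruth("H3", [best[0]], [best[1]], True, lam)
    if scenario in ("H4", "H4_concordant"):
        v = pick()
        return ScenarioTruth("H4", [v], [v], True, lam)
    if scenario == "H4_discordant":
        v = pick()
        return ScenarioTruth("H4", [v], [v], False, lam)
    raise DomainError(f"unknown scenario {scenario!r}")


def simulate_locus_set(n_loci: int, mix: dict[str, float] | None = None,
                       seed: int = 0, p: int = 100, decay: float = 0.9,
                       lam: float = 7.0, n_a: int = 100_000,
                       n_b: int = 100_000, span: int = 200_000,
                       scenario_sequence: list[str] | None = None
                       ) -> list[SimulatedLocus]:
    """Simulate ``n_loci`` independent loci with scenarios drawn from ``mix``.

    ``scenario_sequence`` fixes the per-locus scenario exactly (length
    ``n_loci``) instead of sampling from ``mix``. Loci are placed far
    apart (alternating chromosomes, 10-Mb spacing) so analysis windows
    never merge across loci.
    """
    if n_loci < 0:
        raise DomainError("n_loci must be >= 0")
    if scenario_sequence is not None:
        if len(scenario_sequence) != n_loci:
            raise DomainError("scenario_sequence length must equal n_loci")
        names = list(dict.fromkeys(scenario_sequence))
        props = None
    else:
        if mix is None:
            raise DomainError("either mix or scenario_sequence is required")
        names = list(mix)
        props = np.array([mix[k] for k in names], dtype=float)
        if abs(props.sum() - 1.0) > 1e-8:
            raise DomainError("mix proportions must sum to 1")
    unknown = set(names) - set(SCENARIOS)
    if unknown:
        raise DomainError(f"unknown scenarios: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_loci):
        if scenario_sequence is not None:
            scenario = scenario_sequence[i]
        else:
            scenario = names[int(rng.choice(len(names), p=props))]
        chrom = str(i % 22 + 1)
        start = 1_000_000 + 10_000_000 * (i // 22)
        ld, meta = simulate_ld(p, decay, seed=int(rng.integers(2 ** 31)),
                               chrom=chrom, start=start, span=span,
                               prefix=f"L{i}v")
        truth = _make_truth(scenario, meta["SNP"].tolist(), lam, rng, ld)
        a, b, truth = simulate_gwas_pair(
            ld, meta, truth, n_a=n_a, n_b=n_b,
            seed=int(rng.integers(2 ** 31)))
        loci.append(SimulatedLocus(f"locus{i}", ld, meta, a, b, truth))
    return loci


def simulate_annotations(meta: pd.DataFrame, gamma: dict[tuple[str, str], float],
                         truth: ScenarioTruth, base_rate: float = 0.1,
                         seed: int = 0) -> AnnotationMap:
    """Plant annotation enrichment at causal variants.

    Each variant receives label k with probability
    logistic(logit(base_rate) + γ_k·causal_indicator).
    """
    if not 0 < base_rate < 1:
        raise DomainError("base_rate must be in (0,1)")
    rng = np.random.default_rng(seed)
    causal = set(truth.causal_a) | set(truth.causal_b)
    logit0 = np.log(base_rate / (1.0 - base_rate))
    labels: dict[str, set] = {}
    for vid in meta["SNP"]:
        labs = set()
        is_causal = vid in causal
        for key, g in gamma.items():
            eta = logit0 + (g if is_causal else 0.0)
            if np.isposinf(eta):
                prob = 1.0
            else:
                prob = 1.0 / (1.0 + np.exp(-eta))
            if rng.random() < prob:
                labs.add(tuple(key))
        labels[vid] = labs
    return AnnotationMap.from_variant_labels(labels)


def simulate_expression_study(n_samples: int, true_bicor: np.ndarray,
                              noise: float = 0.0, seed: int = 0,
                              gene_names: list[str] | None = None,
                              pheno_names: list[str] | None = None
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaussian-copula expression/phenotype matrices with target correlations.

    ``true_bicor`` is genes × phenotypes; the joint correlation matrix
    [[I, T], [Tᵀ, I]] must be PSD. ``noise > 0`` adds independent Gaussian
    noise to the expression values (attenuating observed correlations by
    1/sqrt(1+noise²)). Returns (expression, phenotype) frames with feature
    rows and sample columns.
    """
    t = np.atleast_2d(np.asarray(true_bicor, dtype=float))
    if np.any(np.abs(t) >= 1):
        raise DomainError("target correlations must have |r| < 1")
    if n_samples < 4:
        raise DomainError("need at least 4 samples")
    g, q = t.shape
    joint = np.block([[np.eye(g), t], [t.T, np.eye(q)]])
    evals = np.linalg.eigvalsh(joint)
    if evals.min() < -1e-10:
        raise SimulationError("target correlation matrix is not realizable (non-PSD)")
    chol = np.linalg.cholesky(joint + 1e-10 * np.eye(g + q))
    rng = np.random.default_rng(seed)
    x = (chol @ rng.standard_normal((g + q, n_samples)))
    expr = x[:g]
    pheno = x[g:]
    if noise > 0:
        expr = expr + noise * rng.standard_normal(expr.shape)
    samples = [f"s{i}" for i in range(n_samples)]
    genes = gene_names or [f"gene{i}" for i in range(g)]
    phenos = pheno_names or [f"pheno{i}" for i in range(q)]
    return (pd.DataFrame(expr, index=genes, columns=samples),
            pd.DataFrame(pheno, index=phenos, columns=samples))


def simulate_timecourse(n_genes: int, dynamic_fraction: float,
                        timepoints: list[float], effect: float = 1.0,
                        noise: float = 1.0, replicates: int = 3,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Time-course expression with a planted fraction of dynamic genes.

    Returns (expression genes × samples, sample design with a ``time``
    column, boolean truth vector marking dynamic genes). Dynamic genes
    follow mean + effect·time; null genes are flat.
    """
    if len(set(timepoints)) < 3:
        raise DomainError("need at least 3 distinct timepoints")
    if not 0 <= dynamic_fraction <= 1:
        raise DomainError("dynamic_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    times = np.repeat(np.asarray(timepoints, dtype=float), replicates)
    n_dyn = int(round(dynamic_fraction * n_genes))
    truth = np.zeros(n_genes, dtype=bool)
    truth[:n_dyn] = True
    base = rng.normal(5.0, 1.0, size=n_genes)
    mean = base[:, None] + np.where(truth[:, None], effect, 0.0) * times[None, :]
    expr = mean + noise * rng.standard_normal((n_genes, times.size))
    samples = [f"t{t:g}_r{r}" for t in timepoints for r in range(replicates)]
    design = pd.DataFrame({"sample": samples, "time": times})
    frame = pd.DataFrame(expr, index=[f"gene{i}" for i in range(n_genes)],
                         columns=samples)
    return frame, design, truth
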