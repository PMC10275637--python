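"""GWAS–QTL colocalization by two routes and their reconciliation.

Route 1: ABF colocalization with a pass at PPH4 > 0.50. Route 2: the SMR
chi-square statistic at the top QTL instrument with a 5% FDR across the
tested family. Agreement/disagreement maps to pleiotropy categories
(candidate_causal / horizontal_pleiotropy / locus_level / none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coloc import DEFAULT_PRIORS, coloc_abf
from .discordance import AnalysisWindow
from .errors import DomainError
from .io_formats import SummaryStats, harmonize

DEFAULT_QTL_PPH4 = 0.50
DEFAULT_FDR = 0.05
DEFAULT_GENE_MARGIN = 1_000_000

CATEGORIES = ("candidate_causal", "horizontal_pleiotropy", "locus_level", "none")


@dataclass
class QTLColocRecord:
    gene: str
    tissue: str
    qtl_kind: str                    # eQTL | sQTL
    abf_pph4: float
    abf_pass: bool
    smr_T: float
    smr_p: float
    smr_q: float | None = None
    smr_pass: bool | None = None
    category: str | None = None
    expression_direction: int | None = None

    def finalize(self) -> "QTLColocRecord":
        self.category = reconcile(self.abf_pass, bool(self.smr_pass))
        return self


def select_qtl_genes(window: AnalysisWindow, qtl_catalog: dict,
                     margin: int = DEFAULT_GENE_MARGIN) -> list[str]:
    """Genes whose span overlaps the window extended by ``margin`` bp.

    ``qtl_catalog`` maps gene -> dict with at least chrom/start/end keys
    (extra keys such as the per-gene SummaryStats are ignored here).
    """
    lo, hi = window.start - margin, window.end + margin
    out = []
    for gene, info in qtl_catalog.items():
        if str(info["chrom"]) != str(window.chrom):
            continue
        if info["end"] >= lo and info["start"] <= hi:
            out.append(gene)
    return sorted(out)


def smr_test(z_gwas: float, z_qtl: float) -> tuple[float, float]:
    """SMR statistic T = z_g²·z_q²/(z_g²+z_q²), p from χ²₁.

    T = 0 by continuity when both arguments are 0.
    """
    if not (np.isfinite(z_gwas) and np.isfinite(z_qtl)):
        raise DomainError("z scores must be finite")
    zg2, zq2 = z_gwas ** 2, z_qtl ** 2
    if zg2 + zq2 == 0:
        return 0.0, 1.0
    t = zg2 * zq2 / (zg2 + zq2)
    return float(t), float(stats.chi2.sf(t, df=1))


def qtl_coloc_abf(gwas: SummaryStats, qtl: SummaryStats,
                  priors=DEFAULT_PRIORS,
                  pph4_thresh: float = DEFAULT_QTL_PPH4) -> tuple[float, bool]:
    """ABF colocalization of a GWAS locus with one gene's QTL signal.

    Pass requires PPH4 strictly greater than the threshold (the GWAS–QTL
    rule uses PPH4 alone, not PPH3+PPH4).
    """
    pair = harmonize(gwas, qtl)
    res = coloc_abf(pair, priors=priors)
    pph4 = res.pp["PPH4"]
    return pph4, pph4 > pph4_thresh


def smr_fdr(records: pd.DataFrame, alpha: float = DEFAULT_FDR) -> pd.DataFrame:
    """Benjamini–Hochberg q-values over the whole tested family.

    ``records`` needs a ``smr_p`` column; adds ``smr_q`` and ``smr_pass``
    (q < alpha).
    """
    if records.empty:
        out = records.copy()
        out["smr_q"] = pd.Series(dtype=float)
        out["smr_pass"] = pd.Series(dtype=bool)
        return out
    p = records["smr_p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must be in (0,1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = records.copy()
    out["smr_q"] = q
    out["smr_pass"] = q < alpha
    return out


def reconcile(abf_pass: bool, smr_pass: bool) -> str:
    """Map the two routes' verdicts to a pleiotropy category."""
    if abf_pass and smr_pass:
        return "candidate_causal"
    if abf_pass:
        return "horizontal_pleiotropy"
    if smr_pass:
        return "locus_level"
    return "none"


def run_qtl_integration(gwas: SummaryStats, qtl_studies: list[dict],
                        priors=DEFAULT_PRIORS,
                        pph4_thresh: float = DEFAULT_QTL_PPH4,
                        fdr: float = DEFAULT_FDR) -> list[QTLColocRecord]:
    """Both routes over a family of (gene, tissue, qtl_kind, stats) entries.

    Each entry in ``qtl_studies`` is a dict with keys gene, tissue,
    qtl_kind and stats (a SummaryStats). The SMR instrument is the top QTL
    variant (smallest QTL p among variants shared with the GWAS).
    """
    recs: list[QTLColocRecord] = []
    for entry in qtl_studies:
        st: SummaryStats = entry["stats"]
        pph4, abf_pass = qtl_coloc_abf(gwas, st, priors=priors,
                                       pph4_thresh=pph4_thresh)
        pair = harmonize(gwas, st)
        top = pair.df.loc[pair.df["LNP_B"].idxmin()]
        t, p = smr_test(float(top["Z_A"]), float(top["Z_B"]))
        recs.append(QTLColocRecord(
            gene=entry["gene"], tissue=entry["tissue"],
            qtl_kind=entry.get("qtl_kind", "eQTL"),
            abf_pph4=pph4, abf_pass=abf_pass, smr_T=t, smr_p=p,
            expression_direction=int(np.sign(top["Z_B"])) or None))
    if recs:
        fam = pd.DataFrame({"smr_p": [r.smr_p for r in recs]})
        fam = smr_fdr(fam, alpha=fdr)
        for r, q, ok in zip(recs, fam["smr_q"], fam["smr_pass"]):
            r.smr_q = float(q)
            r.smr_pass = bool(ok)
            r.finalize()
    return recs


def egene_catalog(records: list[QTLColocRecord],
                  protective_sign: int = 1) -> pd.DataFrame:
    """Per-gene/tissue summary of passing records.

    ``protective_sign`` flips expression directions so they are reported
    with respect to the trait-protective allele. Genes replicated by both
    routes are flagged ``consensus``. An empty frame is returned (with a
    note row suppressed) when nothing passes.
    """
    rows = []
    for r in records:
        if r.category in (None, "none"):
            continue
        direction = (r.expression_direction or 0) * protective_sign
        rows.append({
            "gene": r.gene, "tissue": r.tissue, "qtl_kind": r.qtl_kind,
            "category": r.category, "abf_pph4": r.abf_pph4,
            "smr_q": r.smr_q, "direction": direction,
            "consensus": r.category == "candidate_causal",
        })
    return pd.DataFrame(rows, columns=["gene", "tissue", "qtl_kind", "category",
                                       "abf_pph4", "smr_q", "direction",
                                       "consensus"])
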