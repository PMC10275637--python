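"""Readers/writers for summary statistics, BED annotations and LD matrices,
plus cross-study allele harmonization.

Conventions
-----------
* Variant positions are 1-based; BED intervals are 0-based half-open.
  The conversion lives in :func:`pos_to_bed0` and nowhere else.
* Summary-statistic tables are tab- or whitespace-delimited with a header.
  Canonical column names: ``SNP CHR POS EA NEA EAF BETA SE P N`` (``Z`` is
  also recognized); arbitrary file columns are mapped via ``column_map``.
* Very small p-values are carried in natural-log space (column ``LNP``)
  so that genome-wide lead variants do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    EmptyInputError,
    EmptyOverlapError,
    FormatError,
    IdLookupError,
    MissingSampleSizeError,
)

CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N", "Z")
_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: label used for genome-level (non-tissue) annotations, e.g. coding regions
GENOME_TISSUE = "genome"


def pos_to_bed0(pos: int) -> int:
    """Convert a 1-based variant position to its 0-based BED coordinate."""
    return pos - 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association record for one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float | None = None

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class LoadReport:
    """Bookkeeping of rows discarded while reading a summary-stat file."""

    total: int = 0
    dropped: int = 0
    reasons: dict = field(default_factory=dict)

    def drop(self, reason: str, count: int) -> None:
        if count:
            self.dropped += count
            self.reasons[reason] = self.reasons.get(reason, 0) + int(count)


class SummaryStats:
    """Validated per-trait GWAS/QTL summary statistics.

    Backed by a DataFrame with canonical columns ``SNP CHR POS EA NEA EAF
    BETA SE P LNP Z`` and optionally ``N``; variant ids are unique.
    """

    def __init__(self, df: pd.DataFrame, trait_name: str = "trait",
                 trait_type: str = "quantitative",
                 case_fraction: float | None = None,
                 report: LoadReport | None = None):
        if trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        if trait_type == "case_control" and case_fraction is not None:
            if not 0 < case_fraction < 1:
                raise ValueError("case_fraction must be in (0,1)")
        if df["SNP"].duplicated().any():
            raise ValueError("variant ids must be unique")
        self.df = df.reset_index(drop=True)
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.case_fraction = case_fraction
        self.report = report or LoadReport(total=len(df))

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.df["SNP"])

    @property
    def variant_ids(self) -> list[str]:
        return self.df["SNP"].tolist()

    def record(self, variant_id: str) -> VariantAssoc:
        sub = self.df[self.df["SNP"] == variant_id]
        if sub.empty:
            raise IdLookupError([variant_id])
        r = sub.iloc[0]
        n = float(r["N"]) if "N" in sub.columns and np.isfinite(r.get("N", np.nan)) else None
        return VariantAssoc(r["SNP"], str(r["CHR"]), int(r["POS"]), r["EA"], r["NEA"],
                            float(r["EAF"]), float(r["BETA"]), float(r["SE"]),
                            float(r["P"]), n)

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStats":
        idx = self.df.set_index("SNP")
        missing = [v for v in variant_ids if v not in idx.index]
        if missing:
            raise IdLookupError(missing)
        sub = idx.loc[list(variant_ids)].reset_index()
        return SummaryStats(sub, self.trait_name, self.trait_type,
                            self.case_fraction)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """Signed pairwise correlation matrix over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        p = len(self.variant_ids)
        if self.r.shape != (p, p):
            raise FormatError(f"LD matrix shape {self.r.shape} != ({p},{p})")

    @property
    def p(self) -> int:
        return len(self.variant_ids)

    @property
    def r2(self) -> np.ndarray:
        return self.r ** 2

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise IdLookupError(missing)
        return np.array([lookup[v] for v in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = self.index_of(ids)
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(self.variant_ids) + "\n")
            for row in self.r:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


class AnnotationMap:
    """Mapping from genomic position / variant id to (tissue, state) labels.

    Built either from BED interval files (``from_bed_paths``) or from an
    explicit per-variant label mapping (``from_variant_labels``).
    Genome-level labels use tissue :data:`GENOME_TISSUE`.
    """

    def __init__(self):
        # per-chrom arrays: starts, ends (0-based half-open), label index
        self._intervals: dict[str, list[tuple[int, int, tuple[str, str]]]] = {}
        self._variant_labels: dict[str, frozenset] = {}
        self.vocabulary: set[tuple[str, str]] = set()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_bed_paths(cls, paths: Iterable[tuple[str, str, str]]) -> "AnnotationMap":
        amap = cls()
        for tissue, state, path in paths:
            label = (tissue, state)
            amap.vocabulary.add(label)
            with open(path) as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t") if "\t" in line else line.split()
                    if len(parts) < 3:
                        raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
                    chrom = parts[0]
                    try:
                        start, end = int(parts[1]), int(parts[2])
                    except ValueError as exc:
                        raise FormatError(f"{path}:{lineno}: non-integer interval") from exc
                    if end < start:
                        raise FormatError(f"{path}:{lineno}: end < start")
                    amap._intervals.setdefault(chrom, []).append((start, end, label))
        return amap

    @classmethod
    def from_variant_labels(cls, labels: Mapping[str, Iterable[tuple[str, str]]]) -> "AnnotationMap":
        amap = cls()
        for vid, labs in labels.items():
            fs = frozenset(tuple(l) for l in labs)
            amap._variant_labels[vid] = fs
            amap.vocabulary.update(fs)
        return amap

    # -- queries ----------------------------------------------------------
    def labels_at(self, chrom: str, pos: int) -> frozenset:
        """Labels overlapping 1-based position ``pos``: s <= pos-1 < e."""
        pos0 = pos_to_bed0(pos)
        out = set()
        for start, end, label in self._intervals.get(chrom, ()):
            if start <= pos0 < end:
                out.add(label)
        return frozenset(out)

    def labels_for(self, variant_id: str, chrom: str | None = None,
                   pos: int | None = None) -> frozenset:
        labs = set(self._variant_labels.get(variant_id, frozenset()))
        if chrom is not None and pos is not None:
            labs |= self.labels_at(chrom, pos)
        return frozenset(labs)

    def annotate(self, meta: pd.DataFrame) -> dict[str, frozenset]:
        """Label every variant in a metadata frame with SNP/CHR/POS columns."""
        return {row.SNP: self.labels_for(row.SNP, str(row.CHR), int(row.POS))
                for row in meta.itertuples()}

    def tissues(self) -> list[str]:
        return sorted({t for t, _ in self.vocabulary if t != GENOME_TISSUE})


# ---------------------------------------------------------------------------
# summary-statistic reading
# ---------------------------------------------------------------------------

def _rename(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        inverse = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inverse)
    return df


def read_gwas_sumstats(path, column_map: Mapping[str, str] | None = None,
                       trait_type: str = "quantitative",
                       trait_name: str | None = None,
                       case_fraction: float | None = None) -> SummaryStats:
    """Read and validate a GWAS/QTL summary-statistic table.

    Rows violating the record invariants are dropped and counted in the
    attached :class:`LoadReport`. If ``P`` is absent it is filled from the
    two-sided normal tail of z = beta/se; if ``BETA``/``SE`` are absent but
    ``Z``, ``EAF`` and ``N`` are present they are back-filled from
    ``se = 1/sqrt(2·eaf·(1−eaf)·(n+z²))``, ``beta = z·se``.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str})
    df = _rename(df, column_map)
    mandatory = {"SNP", "CHR", "POS", "EA", "NEA", "EAF"}
    missing = mandatory - set(df.columns)
    if missing:
        raise FormatError(f"missing mandatory columns: {sorted(missing)}")
    has_beta = "BETA" in df.columns and "SE" in df.columns
    if not has_beta:
        if "Z" not in df.columns:
            raise FormatError("need either BETA+SE or Z columns")
        if "N" not in df.columns:
            raise MissingSampleSizeError(
                "back-filling BETA/SE from Z requires per-variant N")

    report = LoadReport(total=len(df))
    df = df.copy()
    df["CHR"] = df["CHR"].astype(str)
    for col in ("EA", "NEA"):
        df[col] = df[col].astype(str).str.upper()

    dup = df["SNP"].duplicated(keep="first")
    report.drop("duplicate_id", int(dup.sum()))
    df = df[~dup]

    if not has_beta:
        z = pd.to_numeric(df["Z"], errors="coerce")
        eaf = pd.to_numeric(df["EAF"], errors="coerce")
        n = pd.to_numeric(df["N"], errors="coerce")
        se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z ** 2))
        df["SE"] = se
        df["BETA"] = z * se

    for col in ("POS", "EAF", "BETA", "SE"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = (
        np.isfinite(df["BETA"]) & np.isfinite(df["SE"]) & (df["SE"] > 0)
        & df["EAF"].between(0.0, 1.0)
        & df["EA"].isin(list(_VALID_ALLELES)) & df["NEA"].isin(list(_VALID_ALLELES))
        & (df["EA"] != df["NEA"])
        & np.isfinite(df["POS"]) & (df["POS"] >= 1)
    )
    report.drop("invalid_record", int((~ok).sum()))
    df = df[ok]
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after validation")

    df["POS"] = df["POS"].astype(int)
    df["Z"] = df["BETA"] / df["SE"]
    if "P" in df.columns:
        df["P"] = pd.to_numeric(df["P"], errors="coerce")
        bad_p = ~(df["P"].gt(0) & df["P"].le(1))
        report.drop("invalid_p", int(bad_p.sum()))
        df = df[~bad_p]
        if df.empty:
            raise EmptyInputError(f"{path}: no valid rows after validation")
        df["LNP"] = np.log(df["P"])
    else:
        df["LNP"] = np.log(2.0) + stats.norm.logsf(np.abs(df["Z"]))
        df["P"] = np.exp(df["LNP"])

    if "N" in df.columns:
        df["N"] = pd.to_numeric(df["N"], errors="coerce")

    keep = [c for c in ("SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE",
                        "P", "LNP", "Z", "N") if c in df.columns]
    name = trait_name or str(path)
    return SummaryStats(df[keep], trait_name=name, trait_type=trait_type,
                        case_fraction=case_fraction, report=report)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedPair:
    """Intersection of two studies with study b's alleles aligned to a's.

    ``df`` carries shared columns (SNP/CHR/POS/EA/NEA) plus per-study
    ``{EAF,BETA,SE,P,LNP,Z}_A`` / ``_B`` columns.
    """

    df: pd.DataFrame
    trait_a: str
    trait_b: str
    n_flipped: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_irreconcilable: int = 0

    def __len__(self):
        return len(self.df)

    @property
    def z_a(self) -> np.ndarray:
        return self.df["Z_A"].to_numpy()

    @property
    def z_b(self) -> np.ndarray:
        return self.df["Z_B"].to_numpy()

    def b_stats(self, source_b: SummaryStats) -> SummaryStats:
        """Reconstruct aligned study-b SummaryStats (for round-trips)."""
        cols = {"SNP": self.df["SNP"], "CHR": self.df["CHR"], "POS": self.df["POS"],
                "EA": self.df["EA"], "NEA": self.df["NEA"]}
        for c in ("EAF", "BETA", "SE", "P", "LNP", "Z"):
            cols[c] = self.df[f"{c}_B"]
        if "N_B" in self.df.columns:
            cols["N"] = self.df["N_B"]
        return SummaryStats(pd.DataFrame(cols), source_b.trait_name,
                            source_b.trait_type, source_b.case_fraction)


def harmonize(a: SummaryStats, b: SummaryStats,
              drop_ambiguous: bool = True) -> HarmonizedPair:
    """Align study b's effect alleles to study a's over the shared variants.

    Exact allele matches are kept as-is; swapped effect/other alleles flip
    b's beta/z sign and replace eaf by 1−eaf; A/T and C/G pairs are dropped
    when ``drop_ambiguous``; anything else is irreconcilable and dropped.
    """
    da = a.df.add_suffix("_A").rename(columns={"SNP_A": "SNP"})
    db = b.df.add_suffix("_B").rename(columns={"SNP_B": "SNP"})
    m = da.merge(db, on="SNP", how="inner")
    if m.empty:
        raise EmptyOverlapError(
            f"no shared variants between {a.trait_name!r} and {b.trait_name!r}")

    ea_a, nea_a = m["EA_A"], m["NEA_A"]
    ea_b, nea_b = m["EA_B"], m["NEA_B"]
    same = (ea_a == ea_b) & (nea_a == nea_b)
    swapped = (ea_a == nea_b) & (nea_a == ea_b)
    ambiguous = pd.Series(
        [tuple(x) in _AMBIGUOUS_PAIRS for x in zip(ea_a, nea_a)], index=m.index)

    n_irr = int((~(same | swapped)).sum())
    keep = same | swapped
    n_amb = 0
    if drop_ambiguous:
        n_amb = int((keep & ambiguous).sum())
        keep &= ~ambiguous
    m = m[keep].copy()
    swapped = swapped[keep]
    if m.empty:
        raise EmptyOverlapError("no reconcilable variants after harmonization")

    flip = swapped.to_numpy()
    for col, how in (("BETA_B", "neg"), ("Z_B", "neg"), ("EAF_B", "comp")):
        vals = m[col].to_numpy(dtype=float, copy=True)
        if how == "neg":
            vals[flip] = -vals[flip]
        else:
            vals[flip] = 1.0 - vals[flip]
        m[col] = vals
    m.loc[:, "EA_B"] = m["EA_A"]
    m.loc[:, "NEA_B"] = m["NEA_A"]

    out = m.rename(columns={"CHR_A": "CHR", "POS_A": "POS",
                            "EA_A": "EA", "NEA_A": "NEA"})
    out = out.drop(columns=[c for c in ("CHR_B", "POS_B", "EA_B", "NEA_B")
                            if c in out.columns])
    out = out.sort_values(["CHR", "POS", "SNP"]).reset_index(drop=True)
    return HarmonizedPair(out, a.trait_name, b.trait_name,
                          n_flipped=int(flip.sum()),
                          n_dropped_ambiguous=n_amb,
                          n_dropped_irreconcilable=n_irr)


# ---------------------------------------------------------------------------
# BED / LD readers
# ---------------------------------------------------------------------------

def read_bed_annotations(paths: Iterable[tuple[str, str, str]]) -> AnnotationMap:
    """Build an :class:`AnnotationMap` from (tissue, state, bed-path) triples."""
    return AnnotationMap.from_bed_paths(paths)


def read_ld_matrix(path, ids: Sequence[str] | None = None,
                   sym_tol: float = 1e-8) -> LDMatrix:
    """Read a whitespace-delimited square LD matrix with an id header row.

    The matrix is checked for symmetry (within ``sym_tol``, then
    symmetrized), range [−1, 1], and the diagonal is pinned to 1. When
    ``ids`` is given the matrix is reordered/sliced to that order.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise FormatError(f"{path}: empty header")
        r = np.loadtxt(fh, dtype=float, ndmin=2)
    p = len(header)
    if r.shape != (p, p):
        raise FormatError(f"{path}: matrix shape {r.shape} does not match "
                          f"{p} header ids")
    if np.abs(r - r.T).max() > sym_tol:
        raise FormatError(f"{path}: asymmetry exceeds tolerance {sym_tol}")
    r = 0.5 * (r + r.T)
    if np.abs(r).max() > 1.0 + 1e-9:
        raise FormatError(f"{path}: correlation entries outside [-1, 1]")
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    ld = LDMatrix(header, r)
    if ids is not None:
        ld = ld.subset(ids)
    return ld


def align_to_ld(pair: HarmonizedPair, ld: LDMatrix) -> tuple[HarmonizedPair, LDMatrix]:
    """Restrict a harmonized pair and an LD matrix to their shared variants,
    in the pair's order."""
    shared = [v for v in pair.df["SNP"] if v in set(ld.variant_ids)]
    if not shared:
        raise AlignmentError("no overlap between harmonized pair and LD matrix")
    df = pair.df[pair.df["SNP"].isin(shared)].reset_index(drop=True)
    sub = HarmonizedPair(df, pair.trait_a, pair.trait_b, pair.n_flipped,
                         pair.n_dropped_ambiguous, pair.n_dropped_irreconcilable)
    return sub, ld.subset(df["SNP"].tolist())
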