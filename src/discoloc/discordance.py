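"""Analysis-window construction, discordance classification, LD clumping
into signals, and PheWAS-style lookups across local summary-stat files."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import HarmonizedPair, LDMatrix, SummaryStats

DEFAULT_SIG_P = 5e-8
DEFAULT_FLANK = 500_000
DEFAULT_MERGE_GAP = 250_000
DEFAULT_MIN_EAF = 0.01
DEFAULT_DISCORD_P = 1e-5
DEFAULT_CLUMP_R2 = 0.50


@dataclass
class AnalysisWindow:
    """A merged ±flank region around genome-wide-significant variants."""

    chrom: str
    start: int                      # 1-based inclusive
    end: int
    seed_variants: list[str]
    variant_ids: list[str]

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("window end < start")

    def __len__(self):
        return len(self.variant_ids)


@dataclass
class Signal:
    """One clumped association signal with its discordance label."""

    lead_id: str
    member_ids: list[str]
    label: str                      # concordant | discordant | unlabeled
    z_a: float
    z_b: float
    locus: AnalysisWindow | None = None
    posteriors: dict = field(default_factory=dict)


def build_windows(pair: HarmonizedPair, sig_p: float = DEFAULT_SIG_P,
                  flank: int = DEFAULT_FLANK,
                  merge_gap: int = DEFAULT_MERGE_GAP,
                  min_eaf: float = DEFAULT_MIN_EAF) -> list[AnalysisWindow]:
    """Windows of ±``flank`` around variants significant in either trait.

    Rare variants (eaf < ``min_eaf`` or > 1−``min_eaf`` in either study)
    are excluded before seeding and from window contents. Same-chromosome
    windows whose gap is below ``merge_gap`` (or that overlap) are merged.
    """
    df = pair.df
    common = (df["EAF_A"].between(min_eaf, 1 - min_eaf)
              & df["EAF_B"].between(min_eaf, 1 - min_eaf))
    df = df[common]
    ln_sig = np.log(sig_p)
    sig = df[(df["LNP_A"] < ln_sig) | (df["LNP_B"] < ln_sig)]
    if sig.empty:
        return []

    windows: list[AnalysisWindow] = []
    for chrom, grp in sig.groupby("CHR", sort=True):
        grp = grp.sort_values(["POS", "SNP"])
        cur_start = cur_end = None
        cur_seeds: list[str] = []
        intervals = []
        for row in grp.itertuples():
            # 1-based inclusive bounds spanning exactly 2*flank bases
            s, e = max(row.POS - flank + 1, 1), row.POS + flank
            if cur_start is None:
                cur_start, cur_end, cur_seeds = s, e, [row.SNP]
            elif s - cur_end < merge_gap:       # overlap or gap below merge_gap
                cur_end = max(cur_end, e)
                cur_seeds.append(row.SNP)
            else:
                intervals.append((cur_start, cur_end, cur_seeds))
                cur_start, cur_end, cur_seeds = s, e, [row.SNP]
        intervals.append((cur_start, cur_end, cur_seeds))

        chrom_df = df[df["CHR"] == chrom]
        for s, e, seeds in intervals:
            inside = chrom_df[(chrom_df["POS"] >= s) & (chrom_df["POS"] <= e)]
            inside = inside.sort_values(["POS", "SNP"])
            windows.append(AnalysisWindow(str(chrom), int(s), int(e),
                                          seeds, inside["SNP"].tolist()))
    return windows


def classify_discordance(pair: HarmonizedPair,
                         variant_ids: list[str] | None = None,
                         p_thresh: float = DEFAULT_DISCORD_P) -> pd.DataFrame:
    """Label variants discordant/concordant/unlabeled.

    Discordant: opposite z signs (w.r.t. the shared effect allele) and
    p < ``p_thresh`` in both traits; concordant: same signs, both p pass;
    otherwise unlabeled (including z exactly 0).
    """
    df = pair.df
    if variant_ids is not None:
        df = df[df["SNP"].isin(set(variant_ids))]
    z_a = df["Z_A"].to_numpy()
    z_b = df["Z_B"].to_numpy()
    ln_t = np.log(p_thresh)
    both_sig = (df["LNP_A"].to_numpy() < ln_t) & (df["LNP_B"].to_numpy() < ln_t)
    prod = np.sign(z_a) * np.sign(z_b)
    label = np.where(both_sig & (prod < 0), "discordant",
                     np.where(both_sig & (prod > 0), "concordant", "unlabeled"))
    return pd.DataFrame({"SNP": df["SNP"].to_numpy(), "Z_A": z_a, "Z_B": z_b,
                         "LNP_A": df["LNP_A"].to_numpy(),
                         "LNP_B": df["LNP_B"].to_numpy(), "label": label})


def clump_signals(labeled: pd.DataFrame, ld: LDMatrix,
                  r2_thresh: float = DEFAULT_CLUMP_R2,
                  locus: AnalysisWindow | None = None) -> list[Signal]:
    """Greedy LD clumping of labeled variants into signals.

    Repeatedly seed on the most significant unassigned variant (smallest
    min(p_a, p_b)) and absorb every unassigned variant with r² >
    ``r2_thresh`` to the lead. Clumping runs within each label class so a
    signal's members all share the lead's label.
    """
    ids = labeled["SNP"].tolist()
    idx = ld.index_of(ids)          # raises IdLookupError listing missing ids
    r2 = ld.r2[np.ix_(idx, idx)]
    min_lnp = np.minimum(labeled["LNP_A"].to_numpy(), labeled["LNP_B"].to_numpy())

    signals: list[Signal] = []
    for label in ("discordant", "concordant", "unlabeled"):
        mask = (labeled["label"] == label).to_numpy()
        pool = set(np.flatnonzero(mask).tolist())
        while pool:
            lead = min(pool, key=lambda i: (min_lnp[i], ids[i]))
            members = {i for i in pool if r2[lead, i] > r2_thresh} | {lead}
            pool -= members
            ordered = sorted(members, key=lambda i: (min_lnp[i], ids[i]))
            row = labeled.iloc[lead]
            signals.append(Signal(
                lead_id=ids[lead],
                member_ids=[ids[i] for i in ordered],
                label=label,
                z_a=float(row["Z_A"]), z_b=float(row["Z_B"]),
                locus=locus))
    return signals


def phewas_lookup(variant_id: str, studies: list[SummaryStats],
                  effect_allele: str | None = None) -> pd.DataFrame:
    """Aligned per-study association rows for one variant.

    Betas are reported with respect to ``effect_allele`` (default: the
    first study listing the variant). Studies lacking the variant get a
    ``present=False`` row rather than an error.
    """
    rows = []
    ref_ea = effect_allele
    for st in studies:
        sub = st.df[st.df["SNP"] == variant_id]
        if sub.empty:
            rows.append({"trait": st.trait_name, "present": False,
                         "beta": np.nan, "se": np.nan, "p": np.nan})
            continue
        r = sub.iloc[0]
        beta, ea, nea, p = float(r["BETA"]), r["EA"], r["NEA"], float(r["P"])
        if ref_ea is None:
            ref_ea = ea
        if ea != ref_ea:
            if nea == ref_ea:
                beta = -beta
            else:
                rows.append({"trait": st.trait_name, "present": False,
                             "beta": np.nan, "se": np.nan, "p": np.nan})
                continue
        rows.append({"trait": st.trait_name, "present": True, "beta": beta,
                     "se": float(r["SE"]), "p": p})
    out = pd.DataFrame(rows, columns=["trait", "present", "beta", "se", "p"])
    if not out.empty and not out["present"].any():
        warnings.warn(f"{variant_id} absent from all studies", stacklevel=2)
    return out
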