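"""Robust expression–phenotype correlation and time-course dynamics tests.

Biweight midcorrelation (bicor): deviations from the median are weighted
by Tukey's biweight with scale 9·mad; weights vanish outside |u| < 1.
Dynamic-expression testing: Gaussian likelihood-ratio test of a
time-dependent model (continuous slope or per-timepoint means) against an
intercept-only null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, DegenerateFitError, DomainError

DEFAULT_FDR = 0.05
DEFAULT_LRT_ALPHA = 0.05


@dataclass
class CorrelationResult:
    gene: str
    phenotype: str
    bicor: float
    pvalue: float
    qvalue: float | None
    n_used: int


@dataclass
class LRTResult:
    gene: str
    ll_alt: float
    ll_null: float
    statistic: float
    df: int
    pvalue: float

    @property
    def dynamic(self) -> bool:
        return self.pvalue < DEFAULT_LRT_ALPHA


def _biweight_terms(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateFitError("mad = 0: biweight scale is degenerate")
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (pairwise-complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AlignmentError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise DomainError("need at least 4 complete pairs")
    a = _biweight_terms(x)
    b = _biweight_terms(y)
    denom = np.sqrt(np.sum(a ** 2) * np.sum(b ** 2))
    if denom == 0:
        raise DegenerateFitError("all weights vanished")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def _bicor_pvalue(r: float, n: int) -> float:
    # Student-t transform, as for Pearson correlation
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bicor_screen(expr: pd.DataFrame, pheno: pd.DataFrame,
                 fdr: float = DEFAULT_FDR,
                 method: str = "bh") -> pd.DataFrame:
    """All gene × phenotype bicor tests with family-wide FDR control.

    ``expr`` and ``pheno`` are feature × sample frames sharing sample
    columns. p-values use the Student-t transform with n−2 df; q-values
    are Benjamini–Hochberg by default (``method='storey'`` applies a
    Storey-style π₀ correction).
    """
    shared = [s for s in expr.columns if s in set(pheno.columns)]
    if not shared:
        raise AlignmentError("no shared samples between expression and phenotypes")
    rows = []
    for gene in expr.index:
        gx = expr.loc[gene, shared].to_numpy(dtype=float)
        for ph in pheno.index:
            py = pheno.loc[ph, shared].to_numpy(dtype=float)
            ok = np.isfinite(gx) & np.isfinite(py)
            n_used = int(ok.sum())
            r = bicor(gx[ok], py[ok])
            rows.append({"gene": gene, "phenotype": ph, "bicor": r,
                         "pvalue": _bicor_pvalue(r, n_used), "n_used": n_used})
    out = pd.DataFrame(rows)
    p = out["pvalue"].to_numpy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    if method == "storey":
        pi0 = min(1.0, 2.0 * np.mean(p > 0.5))
        q = np.minimum(q * pi0, 1.0)
    out["qvalue"] = q
    out["significant"] = out["qvalue"] < fdr
    return out


def _gaussian_loglik(resid: np.ndarray) -> tuple[float, float]:
    n = resid.size
    s2 = float(np.mean(resid ** 2))
    if s2 <= 0:
        raise DegenerateFitError("zero residual variance")
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0), s2


def lrt_dynamic(values, times, gene: str = "gene",
                time_model: str = "factor") -> LRTResult:
    """LRT of time-dependent expression against a flat null.

    ``factor`` fits a mean per distinct timepoint (df = k−1); ``linear``
    fits an intercept + slope (df = 1). Gaussian likelihoods with the MLE
    variance; the statistic is n·log(σ̂₀²/σ̂₁²) ~ χ²(df).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise AlignmentError("values and times must align")
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    uniq = np.unique(t)
    if uniq.size < 3:
        raise DomainError("need at least 3 distinct timepoints")
    if time_model not in ("factor", "linear"):
        raise DomainError(f"unknown time_model {time_model!r}")

    ll_null, _ = _gaussian_loglik(y - y.mean())
    if time_model == "factor":
        fitted = np.empty_like(y)
        for u in uniq:
            m = t == u
            fitted[m] = y[m].mean()
        df = uniq.size - 1
    else:
        slope, intercept = np.polyfit(t, y, 1)
        fitted = intercept + slope * t
        df = 1
    if y.size - (df + 1) < 1:
        raise DomainError("no residual degrees of freedom under the alternative")
    ll_alt, _ = _gaussian_loglik(y - fitted)
    stat = max(2.0 * (ll_alt - ll_null), 0.0)
    p = float(stats.chi2.sf(stat, df=df))
    return LRTResult(gene, ll_alt, ll_null, stat, df, p)


def lrt_screen(expr: pd.DataFrame, times, time_model: str = "factor"
               ) -> pd.DataFrame:
    """Apply :func:`lrt_dynamic` to every row of a genes × samples frame."""
    rows = []
    for gene in expr.index:
        res = lrt_dynamic(expr.loc[gene].to_numpy(dtype=float), times,
                          gene=gene, time_model=time_model)
        rows.append({"gene": gene, "statistic": res.statistic, "df": res.df,
                     "pvalue": res.pvalue, "dynamic": res.dynamic})
    return pd.DataFrame(rows)
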