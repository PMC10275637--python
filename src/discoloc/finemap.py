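"""Sum-of-single-effects fine-mapping on summary statistics (z, R).

The model treats the z-score vector as z ~ MVN(R·b, R) with b a sum of L
single-effect vectors, each having exactly one nonzero coordinate with a
uniform prior over variants and a Gaussian effect prior. Fitting is
iterative Bayesian stepwise selection: each effect is residualized
against the others and refit exactly; the variational objective is
non-decreasing and convergence is declared on its change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .coloc import CredibleSet
from .errors import DomainError
from .io_formats import LDMatrix
from .simulate import cholesky_of_ld
from .errors import SimulationError

DEFAULT_L = 5
DEFAULT_TOL = 1e-3
DEFAULT_COVERAGE = 0.95
DEFAULT_MIN_PURITY = 0.5
#: treat an effect as null when its estimated prior variance falls below this
_NULL_PRIOR_VAR = 1e-8


@dataclass
class SusieFit:
    """Result of a sum-of-single-effects fit."""

    L: int
    alpha: np.ndarray            # L x p per-effect inclusion posteriors
    mu: np.ndarray               # L x p posterior mean effects (given inclusion)
    prior_var: np.ndarray        # per-effect prior variance used/estimated
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = False
    variant_ids: list[str] = field(default_factory=list)

    @property
    def pip(self) -> np.ndarray:
        """Per-variant posterior inclusion probability 1 − ∏ₗ(1 − αₗᵢ)."""
        return 1.0 - np.prod(1.0 - self.alpha, axis=0)


def _single_effect_lbf(bhat: np.ndarray, v: float) -> np.ndarray:
    # shat² = 1 on the z scale; Wakefield form with prior variance v
    return 0.5 * (np.log(1.0 / (1.0 + v)) + bhat ** 2 * v / (1.0 + v))


def _optimize_prior_var(bhat: np.ndarray) -> float:
    """Empirical-Bayes prior variance maximizing the effect's marginal lBF."""
    def neg_loglik(u: float) -> float:
        return -float(logsumexp(_single_effect_lbf(bhat, np.exp(u))))

    res = minimize_scalar(neg_loglik, bounds=(-12.0, 10.0), method="bounded",
                          options={"xatol": 1e-6})
    v = float(np.exp(res.x))
    # if the optimized effect has BF <= 1 against the null, drop the effect
    if -res.fun <= np.log(len(bhat)):
        return 0.0
    return v


def susie_rss(z, R: LDMatrix | np.ndarray, L: int = DEFAULT_L,
              prior_var: float | None = None, max_iter: int = 100,
              tol: float = DEFAULT_TOL, seed: int = 0) -> SusieFit:
    """Fit the sum-of-single-effects model to (z, R).

    ``prior_var=None`` (default) estimates each effect's prior variance by
    empirical Bayes; a number fixes it for all effects. Deterministic:
    effects start at zero and are updated in order 1..L (``seed`` is
    accepted for interface symmetry and unused).
    """
    if isinstance(R, LDMatrix):
        variant_ids = list(R.variant_ids)
        r = R.r
        try:
            cholesky_of_ld(R)
        except SimulationError as exc:
            raise DomainError(str(exc)) from exc
    else:
        r = np.asarray(R, dtype=float)
        variant_ids = [f"v{i}" for i in range(r.shape[0])]
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise DomainError("z must be finite")
    if L < 1:
        raise DomainError("L must be >= 1")
    p = z.size
    if r.shape != (p, p):
        raise DomainError("z and R dimensions disagree")

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    s2 = np.zeros((L, p))            # posterior variance given inclusion
    vvec = np.zeros(L)
    b_l = np.zeros((L, p))           # per-effect posterior mean vectors
    rb_l = np.zeros((L, p))          # R @ b_l, cached
    estimate_v = prior_var is None

    elbo_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        for l in range(L):
            resid = z - (rb_l.sum(axis=0) - rb_l[l])
            bhat = resid                              # d_j = R_jj = 1
            v = _optimize_prior_var(bhat) if estimate_v else float(prior_var)
            vvec[l] = v
            if v < _NULL_PRIOR_VAR:
                alpha[l] = 1.0 / p
                mu[l] = 0.0
                s2[l] = 0.0
            else:
                lbf = _single_effect_lbf(bhat, v)
                alpha[l] = np.exp(lbf - logsumexp(lbf))
                s1 = v / (1.0 + v)
                mu[l] = s1 * bhat
                s2[l] = s1
            b_l[l] = alpha[l] * mu[l]
            rb_l[l] = r @ b_l[l]

        elbo_trace.append(_elbo(z, r, alpha, mu, s2, vvec, b_l, rb_l))
        if len(elbo_trace) > 1:
            delta = elbo_trace[-1] - elbo_trace[-2]
            if delta < -1e-6:
                warnings.warn(f"objective decreased by {-delta:.3g}",
                              RuntimeWarning, stacklevel=2)
            if abs(delta) < tol:
                converged = True
                break
    if not converged:
        warnings.warn("susie_rss did not converge within max_iter",
                      RuntimeWarning, stacklevel=2)
    return SusieFit(L=L, alpha=alpha, mu=mu, prior_var=vvec.copy(),
                    elbo_trace=elbo_trace, converged=converged,
                    variant_ids=variant_ids)


def _elbo(z, r, alpha, mu, s2, vvec, b_l, rb_l) -> float:
    """Variational objective E_q[b'z − ½ b'Rb] − Σₗ KL(qₗ ‖ priorₗ)."""
    p = z.size
    bbar = b_l.sum(axis=0)
    quad = bbar @ (r @ bbar)
    quad -= sum(b_l[l] @ rb_l[l] for l in range(len(b_l)))
    quad += float(np.sum(alpha * (mu ** 2 + s2)))     # R_jj = 1
    fit = float(bbar @ z) - 0.5 * quad

    kl = 0.0
    logp = np.log(p)
    for l in range(alpha.shape[0]):
        a = alpha[l]
        nz = a > 0
        ent = float(np.sum(a[nz] * (np.log(a[nz]) + logp)))
        v = vvec[l]
        if v < _NULL_PRIOR_VAR:
            kl += ent
            continue
        gauss = 0.5 * (np.log(v / s2[l][nz]) + (s2[l][nz] + mu[l][nz] ** 2) / v - 1.0)
        kl += ent + float(np.sum(a[nz] * gauss))
    return fit - kl


def _set_purity(member_idx: np.ndarray, r: np.ndarray) -> float:
    if member_idx.size <= 1:
        return 1.0
    sub = np.abs(r[np.ix_(member_idx, member_idx)])
    off = sub[~np.eye(sub.shape[0], dtype=bool)]
    return float(off.min())


def susie_credible_sets(fit: SusieFit, R: LDMatrix | np.ndarray,
                        coverage: float = DEFAULT_COVERAGE,
                        min_purity: float = DEFAULT_MIN_PURITY,
                        pip_confidence: float = 0.70
                        ) -> list[CredibleSet]:
    """Coverage sets per effect, filtered by LD purity and deduplicated.

    Each retained set carries a ``high_confidence`` attribute: True when
    its lead variant's PIP exceeds ``pip_confidence``.
    """
    r = R.r if isinstance(R, LDMatrix) else np.asarray(R, dtype=float)
    if not 0 < coverage < 1:
        raise DomainError("coverage must be in (0,1)")
    pip = fit.pip
    out: list[CredibleSet] = []
    seen: set[frozenset] = set()
    for l in range(fit.L):
        if fit.prior_var[l] < _NULL_PRIOR_VAR:
            continue
        a = fit.alpha[l]
        order = np.argsort(-a, kind="stable")
        cum = np.cumsum(a[order])
        k = int(np.searchsorted(cum, coverage) + 1)
        k = min(k, a.size)
        members = order[:k]
        if cum[k - 1] < coverage:
            continue
        if _set_purity(members, r) < min_purity:
            continue
        key = frozenset(members.tolist())
        if key in seen:
            continue
        seen.add(key)
        ids = [fit.variant_ids[i] for i in members]
        cs = CredibleSet(coverage, ids, float(cum[k - 1]), a[members].copy())
        cs.high_confidence = bool(pip[members[0]] > pip_confidence)
        out.append(cs)
    return out


def sensitivity_scan(z, R: LDMatrix | np.ndarray, prior_var_grid,
                     L: int = DEFAULT_L, coverage: float = DEFAULT_COVERAGE,
                     min_purity: float = DEFAULT_MIN_PURITY,
                     max_iter: int = 100, tol: float = DEFAULT_TOL):
    """Refit across a grid of prior variances and tabulate set stability.

    Returns a list of dicts: prior_var, n_credible_sets, lead ids.
    """
    grid = list(prior_var_grid)
    if not grid:
        raise DomainError("prior_var_grid must be non-empty")
    rows = []
    for v in grid:
        fit = susie_rss(z, R, L=L, prior_var=v, max_iter=max_iter, tol=tol)
        sets = susie_credible_sets(fit, R, coverage=coverage,
                                   min_purity=min_purity)
        rows.append({
            "prior_var": float(v),
            "n_credible_sets": len(sets),
            "leads": [cs.member_ids[0] for cs in sets],
        })
    return rows
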