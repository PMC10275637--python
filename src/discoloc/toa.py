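"""Annotation enrichment over colocalization Bayes factors and
tissue-of-action (TOA) scoring of credible-set signals.

Enrichment model: each locus harbors exactly one causal variant with
prior πᵢ ∝ exp(Σₖ γₖ·a_ik); the per-locus marginal likelihood is
Σᵢ πᵢ(γ)·BFᵢ with lnBFᵢ the per-variant colocalization log-Bayes-factor.
γ is fitted by maximizing the summed log marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import DomainError
from .io_formats import GENOME_TISSUE

DEFAULT_PRIMARY_THRESH = 0.20
DEFAULT_SHARE_MARGIN = 0.10
GAMMA_BOUND = 10.0

Label = tuple[str, str]


@dataclass
class EnrichmentModel:
    """Fitted per-annotation log-enrichment coefficients."""

    gamma: dict[Label, float]
    se_gamma: dict[Label, float]
    fitted_loglik: float
    empirical_gamma: dict[Label, float] = field(default_factory=dict)

    def coef(self, label: Label) -> float:
        g = self.gamma.get(tuple(label), 0.0)
        return 0.0 if not np.isfinite(g) else g


@dataclass
class TOAResult:
    """Per-tissue allocation of a signal's posterior mass."""

    signal_id: str
    scores: dict[str, float]            # tissues plus "unclassified"
    classification: str                 # tissue name | "shared" | "unclassified"
    shared_tissues: list[str] = field(default_factory=list)


def _design(loci, vocabulary):
    """Stack loci into (lnbf arrays, binary annotation matrices)."""
    vocab = [tuple(v) for v in vocabulary]
    col = {lab: k for k, lab in enumerate(vocab)}
    lnbfs, mats = [], []
    for lnbf, labels in loci:
        lnbf = np.asarray(lnbf, dtype=float)
        a = np.zeros((lnbf.size, len(vocab)))
        for i, labs in enumerate(labels):
            for lab in labs:
                lab = tuple(lab)
                if lab in col:
                    a[i, col[lab]] = 1.0
        lnbfs.append(lnbf)
        mats.append(a)
    return vocab, lnbfs, mats


def _loglik_and_grad(gamma, lnbfs, mats):
    ll = 0.0
    grad = np.zeros_like(gamma)
    for lnbf, a in zip(lnbfs, mats):
        eta = a @ gamma
        l_post = logsumexp(eta + lnbf)
        l_prior = logsumexp(eta)
        ll += l_post - l_prior
        w_post = np.exp(eta + lnbf - l_post)
        w_prior = np.exp(eta - l_prior)
        grad += a.T @ (w_post - w_prior)
    return ll, grad


def fit_enrichment(loci, vocabulary, n_starts: int = 3,
                   compute_se: bool = True) -> EnrichmentModel:
    """Fit annotation log-enrichments over colocalized loci.

    ``loci`` is a list of (per-variant lnBF vector, per-variant label
    iterables); ``vocabulary`` the annotation labels to model. Annotations
    absent from every variant get coefficient NaN ("missing"). A
    closed-form empirical estimator — posterior-weighted frequency over
    raw frequency, pooled across loci — is reported alongside.
    """
    if not loci:
        raise DomainError("need at least one locus")
    vocab, lnbfs, mats = _design(loci, vocabulary)
    k = len(vocab)
    occur = np.sum([m.sum(axis=0) for m in mats], axis=0)
    active = occur > 0

    gamma_full = np.full(k, np.nan)
    se_full = np.full(k, np.nan)
    loglik = float(sum(logsumexp(l) - np.log(l.size) for l in lnbfs))

    if active.any():
        mats_a = [m[:, active] for m in mats]
        ka = int(active.sum())

        def objective(g):
            ll, gr = _loglik_and_grad(g, lnbfs, mats_a)
            return -ll, -gr

        best = None
        starts = [np.zeros(ka)]
        rng = np.random.default_rng(0)
        for _ in range(max(n_starts - 1, 0)):
            starts.append(rng.uniform(-2, 2, size=ka))
        for x0 in starts:
            res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                           bounds=[(-GAMMA_BOUND, GAMMA_BOUND)] * ka)
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if not best.success and not np.isfinite(best.fun):
            raise RuntimeError(f"enrichment optimizer failed: {best.message}")
        g_hat = best.x
        loglik = -float(best.fun)
        gamma_full[active] = g_hat

        if compute_se:
            se_full[active] = _curvature_se(g_hat, lnbfs, mats_a)

    empirical = _empirical_gamma(lnbfs, mats)
    return EnrichmentModel(
        gamma={lab: float(gamma_full[i]) for i, lab in enumerate(vocab)},
        se_gamma={lab: float(se_full[i]) for i, lab in enumerate(vocab)},
        fitted_loglik=loglik,
        empirical_gamma={lab: float(empirical[i]) for i, lab in enumerate(vocab)})


def _curvature_se(g_hat, lnbfs, mats, h: float = 1e-5) -> np.ndarray:
    """SEs from the observed-information curvature (finite-difference Hessian
    of the gradient)."""
    ka = g_hat.size
    hess = np.zeros((ka, ka))
    for j in range(ka):
        gp = g_hat.copy(); gp[j] += h
        gm = g_hat.copy(); gm[j] -= h
        _, grad_p = _loglik_and_grad(gp, lnbfs, mats)
        _, grad_m = _loglik_and_grad(gm, lnbfs, mats)
        hess[:, j] = (grad_p - grad_m) / (2 * h)
    info = -0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        return np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    except np.linalg.LinAlgError:
        return np.full(ka, np.nan)


def _empirical_gamma(lnbfs, mats) -> np.ndarray:
    k = mats[0].shape[1]
    w_num = np.zeros(k)
    w_den = 0.0
    raw_num = np.zeros(k)
    raw_den = 0.0
    for lnbf, a in zip(lnbfs, mats):
        w = np.exp(lnbf - logsumexp(lnbf))
        w_num += a.T @ w
        w_den += 1.0
        raw_num += a.sum(axis=0)
        raw_den += a.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log((w_num / w_den) / (raw_num / raw_den))


def toa_scores(signal_id: str, posteriors, variant_labels,
               model: EnrichmentModel | None, tissues: list[str],
               coding_to_unclassified: bool = True,
               primary_thresh: float = DEFAULT_PRIMARY_THRESH,
               share_margin: float = DEFAULT_SHARE_MARGIN) -> TOAResult:
    """Allocate credible-set posterior mass to tissues.

    Each variant's posterior pᵢ splits across tissues proportionally to
    wᵢₜ = Σₖ exp(γₖₜ)·a_ikt. Unannotated variants, residual posterior mass
    outside the credible set and (by default) coding-region variants all
    feed "unclassified". Scores sum to 1.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.size == 0:
        raise DomainError("empty credible set")
    if post.sum() > 1 + 1e-8:
        raise DomainError("posteriors must sum to <= 1")
    scores = {t: 0.0 for t in tissues}
    unclassified = max(1.0 - float(post.sum()), 0.0)
    for p_i, labs in zip(post, variant_labels):
        labs = {tuple(l) for l in labs}
        if coding_to_unclassified and any(t == GENOME_TISSUE for t, _ in labs):
            unclassified += p_i
            continue
        w = {t: 0.0 for t in tissues}
        for t, state in labs:
            if t in w:
                g = model.coef((t, state)) if model is not None else 0.0
                w[t] += np.exp(g)
        tot = sum(w.values())
        if tot <= 0:
            unclassified += p_i
        else:
            for t in tissues:
                scores[t] += p_i * w[t] / tot
    scores["unclassified"] = unclassified
    total = sum(scores.values())
    if total > 0:
        scores = {k: v / total for k, v in scores.items()}
    cls, shared = classify_toa({t: scores[t] for t in tissues},
                               primary_thresh, share_margin)
    return TOAResult(signal_id, scores, cls, shared)


def classify_toa(scores: dict[str, float],
                 primary_thresh: float = DEFAULT_PRIMARY_THRESH,
                 share_margin: float = DEFAULT_SHARE_MARGIN
                 ) -> tuple[str, list[str]]:
    """Threshold rule: below ``primary_thresh`` → unclassified; top−second
    below ``share_margin`` → shared (listing both); else the top tissue."""
    if not scores:
        return "unclassified", []
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top_t, top_s = ranked[0]
    if top_s < primary_thresh:
        return "unclassified", []
    if len(ranked) > 1 and (top_s - ranked[1][1]) < share_margin:
        return "shared", [top_t, ranked[1][0]]
    return top_t, []
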