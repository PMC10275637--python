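import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from discoloc.coloc import (
    coloc_abf,
    consensus_call,
    credible_set,
    lead_ld_heuristic,
    multi_trait_shared_posterior,
    wakefield_labf,
)
from discoloc.errors import AlignmentError, DomainError
from discoloc.io_formats import LDMatrix, harmonize

from conftest import make_sumstats, variant_row


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def labf_quadrature(z: float, se: float, prior_sd: float) -> float:
    """Numerical integration of the normal-normal marginal likelihood ratio.

    BF = ∫ N(beta_hat; b, se²) N(b; 0, prior_sd²) db / N(beta_hat; 0, se²),
    evaluated by quadrature, independent of the closed form.
    """
    beta_hat = z * se

    def integrand(b):
        return (stats.norm.pdf(beta_hat, loc=b, scale=se)
                * stats.norm.pdf(b, loc=0.0, scale=prior_sd))

    num, _ = integrate.quad(integrand, -10 * prior_sd, 10 * prior_sd,
                            limit=200, epsabs=1e-14, epsrel=1e-12)
    den = stats.norm.pdf(beta_hat, loc=0.0, scale=se)
    return math.log(num / den)


def coloc_bruteforce(labf_a, labf_b, priors):
    """Definitional enumeration over causal-configuration pairs."""
    p1, p2, p12 = priors
    bf_a = [math.exp(v) for v in labf_a]
    bf_b = [math.exp(v) for v in labf_b]
    n = len(bf_a)
    s0 = 1.0
    s1 = p1 * math.fsum(bf_a)
    s2 = p2 * math.fsum(bf_b)
    s3 = p1 * p2 * math.fsum(bf_a[i] * bf_b[j]
                             for i in range(n) for j in range(n) if i != j)
    s4 = p12 * math.fsum(bf_a[i] * bf_b[i] for i in range(n))
    tot = s0 + s1 + s2 + s3 + s4
    return [s / tot for s in (s0, s1, s2, s3, s4)]


# ---------------------------------------------------------------------------
# wakefield_labf
# ---------------------------------------------------------------------------

class TestWakefield:
    def test_null_z(self):
        se, prior_sd = 0.1, 0.15
        r = prior_sd ** 2 / (se ** 2 + prior_sd ** 2)
        val = wakefield_labf(0.0, se, prior_sd)
        assert val == pytest.approx(0.5 * np.log(1 - r))
        assert val < 0

    def test_point_null_prior(self):
        assert wakefield_labf(3.0, 0.1, 0.0) == 0.0

    def test_quadrature_oracle(self):
        for z in (0.5, 2.0, 5.0):
            for se in (0.02, 0.1):
                for prior_sd in (0.15, 0.2):
                    expected = labf_quadrature(z, se, prior_sd)
                    got = wakefield_labf(z, se, prior_sd)
                    assert got == pytest.approx(expected, rel=1e-8, abs=1e-10)

    def test_monotone_in_abs_z(self):
        zs = np.linspace(0, 10, 50)
        vals = wakefield_labf(zs, 0.05, 0.15)
        assert np.all(np.diff(vals) > 0)

    def test_se_domain(self):
        with pytest.raises(DomainError):
            wakefield_labf(1.0, 0.0, 0.15)


# ---------------------------------------------------------------------------
# coloc_abf
# ---------------------------------------------------------------------------

class TestColocAbf:
    def test_single_variant_h3_impossible(self):
        res = coloc_abf((np.array([20.0]), np.array([20.0])))
        assert res.pp["PPH3"] == 0.0
        assert res.pp["PPH4"] > 0.99

    def test_all_null_pph0_modal(self, rng):
        labf = np.full(100, -3.0)
        res = coloc_abf((labf, labf))
        assert max(res.pp, key=res.pp.get) == "PPH0"

    def test_trait_swap_symmetry(self, rng):
        la = rng.normal(0, 3, size=40)
        lb = rng.normal(0, 3, size=40)
        r1 = coloc_abf((la, lb))
        r2 = coloc_abf((lb, la))
        assert r1.pp["PPH1"] == pytest.approx(r2.pp["PPH2"], abs=1e-12)
        assert r1.pp["PPH2"] == pytest.approx(r2.pp["PPH1"], abs=1e-12)
        for h in ("PPH0", "PPH3", "PPH4"):
            assert r1.pp[h] == pytest.approx(r2.pp[h], abs=1e-12)

    def test_bruteforce_oracle(self, rng):
        priors = (1e-4, 1e-4, 5e-6)
        for n in (1, 2, 5, 12):
            for _ in range(5):
                la = rng.normal(0, 4, size=n)
                lb = rng.normal(0, 4, size=n)
                expected = coloc_bruteforce(la, lb, priors)
                res = coloc_abf((la, lb), priors=priors)
                for i in range(5):
                    assert res.pp[f"PPH{i}"] == pytest.approx(
                        expected[i], abs=1e-10)

    def test_snp_pp_sums_to_one(self, rng):
        la = rng.normal(0, 5, size=30)
        lb = rng.normal(0, 5, size=30)
        res = coloc_abf((la, lb))
        assert res.snp_pp_h4.sum() == pytest.approx(1.0, abs=1e-10)

    def test_regional_prob(self):
        res = coloc_abf((np.array([2.0, 1.0]), np.array([1.5, 0.5])))
        assert res.regional_prob == pytest.approx(
            res.pp["PPH3"] + res.pp["PPH4"])

    def test_extreme_labf_no_overflow(self):
        la = np.array([900.0, 10.0, 0.0])
        lb = np.array([850.0, 5.0, 0.0])
        res = coloc_abf((la, lb))
        assert np.isfinite(list(res.pp.values())).all()
        assert res.pp["PPH4"] > 0.99

    @given(st.lists(st.floats(-30, 60), min_size=1, max_size=60),
           st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_pp_sums_to_one_property(self, la, seed):
        lb = np.random.default_rng(seed).normal(0, 10, size=len(la))
        res = coloc_abf((np.array(la), lb))
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-10)

    def test_harmonized_pair_input(self):
        a = make_sumstats([variant_row("rs1", 100, 0.5, 0.02),
                           variant_row("rs2", 200, 0.01, 0.02)])
        b = make_sumstats([variant_row("rs1", 100, 0.4, 0.02),
                           variant_row("rs2", 200, -0.01, 0.02)])
        res = coloc_abf(harmonize(a, b))
        assert res.pp["PPH4"] > 0.5
        assert res.variant_ids == ["rs1", "rs2"]


# ---------------------------------------------------------------------------
# credible_set
# ---------------------------------------------------------------------------

class TestCredibleSet:
    def test_uniform(self):
        cs = credible_set(np.full(100, 0.01), level=0.99)
        assert len(cs) == 99

    def test_concentrated(self):
        cs = credible_set([0.995, 0.005], level=0.99)
        assert len(cs) == 1

    def test_arithmetic(self):
        cs = credible_set([0.5, 0.3, 0.15, 0.05], level=0.9)
        assert len(cs) == 3

    def test_level_domain(self):
        with pytest.raises(DomainError):
            credible_set([1.0], level=1.5)

    def test_sum_constraint(self):
        with pytest.raises(DomainError):
            credible_set([0.5, 0.2], level=0.9)

    def test_tie_break_lexicographic(self):
        cs = credible_set([0.5, 0.5], level=0.4, variant_ids=["b", "a"])
        assert cs.member_ids == ["a"]

    @given(st.integers(2, 200), st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_minimality_property(self, n, seed):
        rg = np.random.default_rng(seed)
        post = rg.dirichlet(np.ones(n))
        cs = credible_set(post, level=0.95)
        assert cs.cum_posterior >= 0.95
        if len(cs) > 1:
            assert cs.cum_posterior - cs.posteriors[-1] < 0.95


# ---------------------------------------------------------------------------
# multi-trait posterior + consensus
# ---------------------------------------------------------------------------

class TestMultiTrait:
    def test_two_trait_equivalence(self, rng):
        la = rng.normal(0, 4, size=50)
        lb = rng.normal(0, 4, size=50)
        res = coloc_abf((la, lb))
        _, per_variant = multi_trait_shared_posterior([la, lb])
        np.testing.assert_allclose(per_variant, res.snp_pp_h4, atol=1e-12)

    def test_all_null_regional_low(self, rng):
        hits = 0
        for _ in range(200):
            mats = [rng.normal(-3, 1, size=100) for _ in range(2)]
            regional, _ = multi_trait_shared_posterior(mats)
            hits += regional >= 0.05
        assert hits == 0

    def test_four_trait_limit(self):
        mats = []
        for _ in range(4):
            v = np.zeros(20)
            v[7] = 10.0
            mats.append(v)
        regional, per_variant = multi_trait_shared_posterior(mats)
        assert per_variant[7] > 0.999

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            multi_trait_shared_posterior([np.zeros(3), np.zeros(4)])


class TestConsensus:
    @pytest.mark.parametrize("votes,expected", [
        ({"abf": True, "multi": True, "heuristic": False}, True),
        ({"abf": True, "multi": False, "heuristic": False}, False),
        ({"abf": False, "multi": False, "heuristic": False}, False),
    ])
    def test_two_of_three(self, votes, expected):
        assert consensus_call(votes) is expected

    def test_min_votes_one(self):
        assert consensus_call({"a": True, "b": False}, min_votes=1) is True

    def test_requires_two_methods(self):
        with pytest.raises(DomainError):
            consensus_call({"abf": True})


def test_lead_ld_heuristic():
    a = make_sumstats([variant_row("rs1", 100, 0.5, 0.02),
                       variant_row("rs2", 200, 0.1, 0.02)])
    b = make_sumstats([variant_row("rs1", 100, 0.01, 0.02),
                       variant_row("rs2", 200, 0.5, 0.02)])
    pair = harmonize(a, b)
    high = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.95], [0.95, 1.0]]))
    low = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.2], [0.2, 1.0]]))
    assert lead_ld_heuristic(pair, high) is True
    assert lead_ld_heuristic(pair, low) is False
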