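import numpy as np
import pytest

from discoloc.errors import DomainError, SimulationError
from discoloc.exprstats import bicor
from discoloc.simulate import (
    ScenarioTruth,
    simulate_annotations,
    simulate_expression_study,
    simulate_gwas_pair,
    simulate_ld,
    simulate_locus_set,
    simulate_timecourse,
)


class TestSimulateLd:
    def test_decay_zero_identity(self):
        ld, _ = simulate_ld(10, 0.0, seed=1)
        np.testing.assert_allclose(ld.r, np.eye(10), atol=1e-12)

    def test_decay_one_degenerate(self):
        with pytest.raises(SimulationError):
            simulate_ld(10, 1.0, seed=1)

    def test_deterministic(self):
        ld1, m1 = simulate_ld(50, 0.9, seed=7)
        ld2, m2 = simulate_ld(50, 0.9, seed=7)
        assert np.array_equal(ld1.r, ld2.r)
        assert m1.equals(m2)

    def test_haplotype_mode_valid(self):
        ld, _ = simulate_ld(20, 0.8, n_hap=500, seed=3)
        assert np.all(np.abs(ld.r) <= 1 + 1e-9)
        assert np.all(np.diag(ld.r) == 1.0)
        # PSD after repair
        assert np.linalg.eigvalsh(ld.r).min() > -1e-8

    def test_p_too_small(self):
        with pytest.raises(DomainError):
            simulate_ld(1, 0.5)


class TestSimulateGwasPair:
    def test_h0_no_extreme_z(self):
        ld, meta = simulate_ld(1000, 0.5, seed=1)
        truth = ScenarioTruth("H0", [], [], True, 0.0)
        a, b, _ = simulate_gwas_pair(ld, meta, truth, seed=2)
        frac = np.mean(a.df["P"] < 1e-5)
        assert frac <= 1 / 1000          # ~0 expected among 1000 nulls

    def test_h4_mean_z_at_causal(self):
        ld, meta = simulate_ld(20, 0.9, seed=1)
        truth = ScenarioTruth("H4", ["rs5"], ["rs5"], True, 7.0)
        zs = []
        for rep in range(500):
            a, _, _ = simulate_gwas_pair(ld, meta, truth, seed=rep)
            zs.append(float(a.df.loc[a.df["SNP"] == "rs5", "Z"].iloc[0]))
        assert np.mean(zs) == pytest.approx(7.0, abs=0.2)

    def test_h4_discordant_sign_flip(self):
        ld, meta = simulate_ld(20, 0.9, seed=1)
        truth = ScenarioTruth("H4", ["rs5"], ["rs5"], False, 7.0)
        flips = 0
        for rep in range(500):
            a, b, _ = simulate_gwas_pair(ld, meta, truth, seed=rep)
            za = float(a.df.loc[5, "Z"])
            zb = float(b.df.loc[5, "Z"])
            flips += np.sign(za) != np.sign(zb)
        assert flips >= 495              # >= 99% of reps

    def test_h0_marginal_variance_one(self):
        ld, meta = simulate_ld(5, 0.7, seed=1)
        truth = ScenarioTruth("H0", [], [], True, 0.0)
        z = np.array([simulate_gwas_pair(ld, meta, truth, seed=r)[0]
                      .df["Z"].to_numpy() for r in range(2000)])
        np.testing.assert_allclose(z.var(axis=0), 1.0, atol=0.15)

    def test_case_control_se(self):
        ld, meta = simulate_ld(5, 0.0, seed=1)
        truth = ScenarioTruth("H0", [], [], True, 0.0)
        _, b, _ = simulate_gwas_pair(ld, meta, truth, seed=1,
                                     trait_type_b="case_control",
                                     case_fraction_b=0.2)
        assert b.trait_type == "case_control"
        assert (b.df["SE"] > 0).all()


class TestScenarioTruth:
    def test_h4_requires_shared(self):
        with pytest.raises(ValueError):
            ScenarioTruth("H4", ["rs1"], ["rs2"], True, 5.0)

    def test_h3_requires_distinct(self):
        with pytest.raises(ValueError):
            ScenarioTruth("H3", ["rs1"], ["rs1"], True, 5.0)

    def test_discordant_flag(self):
        t = ScenarioTruth("H4", ["rs1"], ["rs1"], False, 5.0)
        assert t.discordant

    def test_json_roundtrip(self):
        t = ScenarioTruth("H3", ["rs1"], ["rs2"], True, 5.0)
        assert ScenarioTruth.from_json(t.to_json()) == t


class TestLocusSet:
    def test_all_discordant(self):
        loci = simulate_locus_set(6, {"H4_discordant": 1.0}, seed=1, p=20)
        assert len(loci) == 6
        assert all(l.truth.discordant for l in loci)

    def test_empty(self):
        assert simulate_locus_set(0, {"H0": 1.0}) == []

    def test_scenario_sequence(self):
        seq = ["H0", "H4", "H4_discordant"]
        loci = simulate_locus_set(3, scenario_sequence=seq, seed=2, p=10)
        assert [l.truth.hypothesis for l in loci] == ["H0", "H4", "H4"]
        assert [l.truth.discordant for l in loci] == [False, False, True]

    def test_mix_marginals_across_seeds(self):
        mix = {k: 0.2 for k in ("H0", "H1", "H2", "H3", "H4")}
        def counts(seed):
            loci = simulate_locus_set(100, mix, seed=seed, p=10)
            out = {}
            for l in loci:
                out[l.truth.hypothesis] = out.get(l.truth.hypothesis, 0) + 1
            return out
        c1, c2 = counts(11), counts(12)
        assert c1 != c2                          # different draws
        for h in mix:
            # 20 +- 4 sd of binomial(100, .2)
            assert abs(c1.get(h, 0) - 20) <= 16
            assert abs(c2.get(h, 0) - 20) <= 16

    def test_bad_mix(self):
        with pytest.raises(DomainError):
            simulate_locus_set(5, {"H0": 0.5})
        with pytest.raises(DomainError):
            simulate_locus_set(5, {"H9": 1.0})


class TestAnnotations:
    def _meta(self, p=400):
        _, meta = simulate_ld(p, 0.0, seed=1)
        return meta

    def test_gamma_zero_base_rate(self):
        meta = self._meta()
        truth = ScenarioTruth("H4", ["rs0"], ["rs0"], True, 5.0)
        amap = simulate_annotations(meta, {("adipose", "Enh"): 0.0}, truth,
                                    base_rate=0.2, seed=1)
        freq = np.mean([bool(amap.labels_for(v)) for v in meta["SNP"]])
        assert freq == pytest.approx(0.2, abs=0.06)

    def test_gamma_inf_causal_always_labeled(self):
        meta = self._meta(50)
        truth = ScenarioTruth("H4", ["rs7"], ["rs7"], True, 5.0)
        amap = simulate_annotations(meta, {("adipose", "Enh"): np.inf}, truth,
                                    base_rate=0.01, seed=1)
        assert amap.labels_for("rs7") == {("adipose", "Enh")}

    def test_seed_reproducible(self):
        meta = self._meta(50)
        truth = ScenarioTruth("H0", [], [], True, 0.0)
        g = {("adipose", "Enh"): 1.0}
        m1 = simulate_annotations(meta, g, truth, seed=5)
        m2 = simulate_annotations(meta, g, truth, seed=5)
        assert all(m1.labels_for(v) == m2.labels_for(v) for v in meta["SNP"])

    def test_bad_base_rate(self):
        meta = self._meta(10)
        truth = ScenarioTruth("H0", [], [], True, 0.0)
        with pytest.raises(DomainError):
            simulate_annotations(meta, {}, truth, base_rate=0.0)


class TestExpressionStudy:
    def test_null_target(self):
        expr, pheno = simulate_expression_study(2000, [[0.0]], seed=1)
        r = bicor(expr.iloc[0], pheno.iloc[0])
        assert abs(r) < 0.05

    def test_strong_target(self):
        expr, pheno = simulate_expression_study(2000, [[0.9]], seed=1)
        r = bicor(expr.iloc[0], pheno.iloc[0])
        assert r == pytest.approx(0.9, abs=0.03)

    def test_min_samples(self):
        with pytest.raises(DomainError):
            simulate_expression_study(3, [[0.5]])

    def test_non_psd_target(self):
        # two genes both correlated 0.99 with two phenotypes that are
        # mutually independent -> joint matrix not PSD
        t = [[0.99, 0.99], [0.99, -0.99]]
        with pytest.raises(SimulationError):
            simulate_expression_study(100, t, seed=1)

    def test_target_magnitude_guard(self):
        with pytest.raises(DomainError):
            simulate_expression_study(100, [[1.0]])


class TestTimecourse:
    def test_all_null(self):
        _, _, truth = simulate_timecourse(20, 0.0, [0, 2, 4, 8], seed=1)
        assert not truth.any()

    def test_zero_effect_indistinguishable(self):
        f1, _, t1 = simulate_timecourse(10, 0.5, [0, 2, 4], effect=0.0, seed=3)
        assert t1[:5].all()              # labels still say dynamic

    def test_deterministic(self):
        f1, d1, _ = simulate_timecourse(10, 0.5, [0, 2, 4], seed=9)
        f2, d2, _ = simulate_timecourse(10, 0.5, [0, 2, 4], seed=9)
        assert f1.equals(f2) and d1.equals(d2)

    def test_needs_three_timepoints(self):
        with pytest.raises(DomainError):
            simulate_timecourse(5, 0.5, [0, 1])
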