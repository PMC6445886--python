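import math

import numpy as np
import pytest

from benchmeta.datatypes import EffectSize, StudyRecord
from benchmeta.pooling import (TAU2_METHODS, coverage, critical_value,
                               estimate_tau2, fixed_effect_summary,
                               heterogeneity, pool, weighted_histogram,
                               weighting_diagnostic)
from benchmeta.simulate import SimulationSpec, simulate_meta_dataset
from benchmeta.effects import effects_from_dataset


class TestCriticalValue:
    @pytest.mark.parametrize("alpha,n,dist,expected", [
        (0.05, 3, "z", 1.96),
        (0.05, 5, "t", 2.78),
        (0.05, 100, "t", 1.98),
    ])
    def test_reference_values(self, alpha, n, dist, expected):
        assert critical_value(alpha, n, dist) == pytest.approx(expected, abs=5e-3)

    def test_t_needs_two_studies(self):
        with pytest.raises(ValueError):
            critical_value(0.05, 1, "t")

    def test_t_converges_to_z(self):
        assert abs(critical_value(0.05, 500, "t") - critical_value(0.05, 500, "z")) < 0.01

    def test_auto_switches_at_30(self):
        assert critical_value(0.05, 10, "auto") == critical_value(0.05, 10, "t")
        assert critical_value(0.05, 30, "auto") == critical_value(0.05, 30, "z")


class TestTau2:
    def test_homogeneous_set_truncates_to_zero(self, homogeneous_effects):
        for m in TAU2_METHODS:
            assert estimate_tau2(homogeneous_effects, m) == 0.0

    @pytest.mark.parametrize("method,expected", [
        ("DL", 0.75), ("PM", 0.75), ("HS", 5 / 12), ("HM", 2 / 3),
        ("H", 0.75), ("SJ", 8 / 11),
    ])
    def test_hand_checked_instance(self, three_effects, method, expected):
        assert estimate_tau2(three_effects, method) == pytest.approx(expected, abs=1e-6)

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            estimate_tau2([EffectSize("a", 1, 0.5, 5)], "DL")

    def test_zero_se_rejected(self):
        eff = [EffectSize("a", 0, 0.0, 5), EffectSize("b", 1, 0.5, 5)]
        with pytest.raises(ValueError):
            estimate_tau2(eff, "DL")


class TestPool:
    def test_symmetric_two_study_fixed(self):
        eff = [EffectSize("a", 0, 1, 5), EffectSize("b", 2, 1, 5)]
        p = pool(eff, "fixed", dist="z")
        assert p.theta_hat == pytest.approx(1.0)
        assert p.se_hat == pytest.approx(1 / math.sqrt(2))

    def test_random_effects_hand_instance(self, three_effects):
        p = pool(three_effects, "random", "DL", dist="z")
        assert p.tau2 == pytest.approx(0.75)
        assert np.allclose(p.weights, p.weights[0])  # equal weights
        assert p.theta_hat == pytest.approx(1.0)
        assert p.se_hat == pytest.approx(1 / math.sqrt(3))

    def test_single_study_identity(self):
        p = pool([EffectSize("a", 3.0, 0.4, 5)], "fixed")
        assert p.theta_hat == 3.0
        assert p.se_hat == 0.4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool([])

    def test_zero_se_under_fixed_rejected(self):
        eff = [EffectSize("a", 0, 0.0, 5), EffectSize("b", 1, 0.5, 5)]
        with pytest.raises(ValueError, match="infinite weight"):
            pool(eff, "fixed")

    def test_tau2_zero_reduces_random_to_fixed(self, three_effects):
        pf = pool(three_effects, "fixed", dist="z")
        pr = pool(three_effects, "random", dist="z", tau2=0.0)
        assert pr.theta_hat == pf.theta_hat
        assert pr.se_hat == pf.se_hat

    def test_huge_tau2_tends_to_unweighted_mean(self):
        eff = [EffectSize("a", 0, 0.1, 5), EffectSize("b", 1, 0.5, 5),
               EffectSize("c", 5, 2.0, 5)]
        big = 1e9 * max(e.se for e in eff) ** 2
        pr = pool(eff, "random", dist="z", tau2=big)
        assert pr.theta_hat == pytest.approx(2.0, rel=1e-6)

    def test_equal_variances_align_sample_size_and_fixed_weights(self):
        eff = [EffectSize(f"s{i}", float(i), 0.3, n) for i, n in enumerate((3, 6, 9))]
        pn = pool(eff, "sample_size")
        w_fe = np.array([1 / e.se ** 2 for e in eff])
        # with equal variances both weight vectors are proportional to n
        assert np.allclose(pn.weights / pn.weights.sum(),
                           [3 / 18, 6 / 18, 9 / 18])
        assert np.allclose(w_fe / w_fe.sum(), 1 / 3)

    def test_sample_size_pooled_se(self):
        eff = [EffectSize("a", 0, 0.2, 5), EffectSize("b", 1, 0.4, 9)]
        p = pool(eff, "sample_size")
        expected = math.sqrt((0.2 ** 2 * 4 + 0.4 ** 2 * 8) / 12)
        assert p.se_hat == pytest.approx(expected)

    def test_unknown_scheme_rejected(self, three_effects):
        with pytest.raises(ValueError):
            pool(three_effects, scheme="inverse")


class TestHeterogeneity:
    def test_homogeneous_set(self, homogeneous_effects):
        h = heterogeneity(homogeneous_effects)
        assert h.Q == pytest.approx(0.0)
        assert h.H2 == 1.0
        assert h.I2 == 0.0

    def test_hand_checked_instance(self, three_effects):
        h = heterogeneity(three_effects)
        assert h.Q == pytest.approx(8.0)
        assert h.df == 2
        assert h.H2 == pytest.approx(4.0)
        assert h.I2 == pytest.approx(75.0)
        assert h.H2_ci[0] >= 1.0

    def test_truncation_branch(self):
        # Q < df: H2 truncated at 1, I2 floored at 0
        eff = [EffectSize(f"s{i}", t, 1.0, 5) for i, t in enumerate((0.0, 0.5, 1.0))]
        h = heterogeneity(eff)
        assert h.Q < h.df
        assert h.H2 == 1.0
        assert h.I2 == 0.0

    def test_df_one_has_no_interval(self):
        eff = [EffectSize("a", 0, 0.5, 5), EffectSize("b", 1, 0.5, 5)]
        h = heterogeneity(eff)
        assert h.H2_ci is None and h.I2_ci is None

    def test_brute_force_Q_matches_vectorized(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            N = rng.integers(2, 6)
            theta = rng.normal(0, 2, N)
            se = rng.uniform(0.1, 1.0, N)
            w = 1 / se ** 2
            fe = sum(wi * ti for wi, ti in zip(w, theta)) / sum(w)
            q_brute = sum(wi * (ti - fe) ** 2 for wi, ti in zip(w, theta))
            _, _, q_vec = fixed_effect_summary(theta, se)
            assert q_vec == pytest.approx(q_brute, abs=1e-12)

    def test_identity_I2_from_H2(self):
        rng = np.random.default_rng(3)
        eff = [EffectSize(f"s{i}", float(t), float(s), 5)
               for i, (t, s) in enumerate(zip(rng.normal(0, 1, 8),
                                              rng.uniform(0.2, 0.8, 8)))]
        h = heterogeneity(eff)
        assert h.I2 == pytest.approx((h.H2 - 1) / h.H2 * 100)


class TestCoverage:
    def test_identical_studies_fully_covered(self, homogeneous_effects):
        p = pool(homogeneous_effects, "fixed")
        c = coverage(homogeneous_effects, p)
        assert c.proportion == 1.0

    def test_far_study_not_covered(self):
        # c lies far beyond both CI half-widths; a and b dominate the pool
        eff = [EffectSize("a", 0.0, 0.1, 5), EffectSize("b", 0.0, 0.1, 5),
               EffectSize("c", 100.0, 10.0, 5)]
        p = pool(eff, "fixed", dist="z")
        c = coverage(eff, p)
        assert c.covered == 2

    def test_hand_inequality(self):
        # |0.5 - 0| > 1.96*0.1 + 1.96*0.1 = 0.392 -> not covered
        from benchmeta.datatypes import PooledEstimate
        pooled = PooledEstimate(0.0, 0.1, (-0.196, 0.196), np.ones(1), 0.0,
                                "fixed", 0.05, 1.96, "z", 1)
        eff = [EffectSize("a", 0.5, 0.1, 5)]
        c = coverage(eff, pooled)
        assert c.covered == 0

    def test_scale_mismatch_rejected(self, three_effects):
        p = pool(three_effects, "fixed")
        bad = [EffectSize(e.study_id, e.theta, e.se, e.n_total, scale="log10")
               for e in three_effects]
        with pytest.raises(ValueError, match="scale"):
            coverage(bad, p)


class TestWeightedHistogram:
    def test_single_bin_normalizes(self, three_effects):
        h = weighted_histogram(three_effects, [1, 1, 1], n_bins=1)
        assert h.P.tolist() == [1.0]

    def test_two_weight_split(self):
        eff = [EffectSize("a", 0.0, 0.1, 5), EffectSize("b", 1.0, 0.1, 5)]
        h = weighted_histogram(eff, [3.0, 1.0], n_bins=2)
        assert h.P.tolist() == [0.75, 0.25]

    def test_empty_bin_retained(self):
        eff = [EffectSize("a", 0.0, 0.1, 5), EffectSize("b", 3.0, 0.1, 5)]
        h = weighted_histogram(eff, [1.0, 1.0], n_bins=3)
        assert len(h.P) == 3
        assert h.P[1] == 0.0

    def test_all_zero_weights_rejected(self, three_effects):
        with pytest.raises(ValueError):
            weighted_histogram(three_effects, [0, 0, 0], n_bins=2)


class TestWeightingDiagnostic:
    def test_sd2_proportional_to_n_flags_sample_size(self):
        recs = [StudyRecord(f"s{i}", 1.0, math.sqrt(0.1 * n), n)
                for i, n in enumerate((4, 8, 12, 16, 20))]
        slope, p, rec = weighting_diagnostic(recs)
        assert rec == "sample_size"
        assert slope == pytest.approx(0.1)

    def test_independent_sd_permits_inverse_variance(self):
        rng = np.random.default_rng(0)
        recs = [StudyRecord(f"s{i}", 1.0, float(s), int(n))
                for i, (s, n) in enumerate(zip(rng.uniform(0.5, 1.5, 30),
                                               rng.integers(3, 30, 30)))]
        _, _, rec = weighting_diagnostic(recs)
        assert rec == "inverse_variance"

    def test_too_few_studies(self):
        recs = [StudyRecord("a", 1, 0.5, 3), StudyRecord("b", 1, 0.5, 4)]
        with pytest.raises(ValueError):
            weighting_diagnostic(recs)

    def test_constant_n_warns_and_defaults(self):
        recs = [StudyRecord(f"s{i}", 1.0, 0.5 + 0.1 * i, 5) for i in range(4)]
        slope, p, rec = weighting_diagnostic(recs)
        assert math.isnan(slope)
        assert rec == "inverse_variance"


def test_tau2_recovery_under_random_effects_model():
    """DL/PM means across replicates track the generative tau2."""
    for tau2 in (0.1, 0.5):
        dl, pm = [], []
        for r in range(200):
            ds = simulate_meta_dataset(SimulationSpec(tau2=tau2, N=50, seed=800 + r))
            eff = effects_from_dataset(ds)
            dl.append(estimate_tau2(eff, "DL"))
            pm.append(estimate_tau2(eff, "PM"))
        assert np.mean(dl) == pytest.approx(tau2, rel=0.15)
        assert np.mean(pm) == pytest.approx(tau2, rel=0.15)
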