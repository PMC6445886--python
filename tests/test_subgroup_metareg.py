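import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benchmeta.datatypes import EffectSize
from benchmeta.effects import effects_from_dataset
from benchmeta.metareg import intrastudy_regression, meta_regression
from benchmeta.pooling import pool
from benchmeta.simulate import (SimulationSpec, simulate_meta_dataset,
                                simulate_regression_dataset,
                                simulate_subgrouped)
from benchmeta.subgroup import bonferroni, subgroup_analysis


def _effects(thetas, se=1.0):
    return [EffectSize(f"s{i}", float(t), se, 5) for i, t in enumerate(thetas)]


class TestSubgroup:
    def test_perfectly_explained_heterogeneity(self):
        eff = _effects([1, 1, 3, 3])
        labels = ["A", "A", "B", "B"]
        res = subgroup_analysis(eff, labels, scheme="fixed")
        assert res.Q_total == pytest.approx(4.0)
        assert res.Q_within == pytest.approx(0.0)
        assert res.Q_between == pytest.approx(4.0)
        assert res.R2_explained == pytest.approx(100.0)

    def test_identical_groups_explain_nothing(self):
        eff = _effects([0, 2, 0, 2])
        res = subgroup_analysis(eff, ["A", "A", "B", "B"], scheme="fixed")
        assert res.Q_between == pytest.approx(0.0)

    def test_single_level_covariate_rejected(self):
        with pytest.raises(ValueError, match="single level"):
            subgroup_analysis(_effects([0, 1, 2]), ["A", "A", "A"])

    def test_missing_covariate_rejected(self):
        eff = _effects([0, 1])
        with pytest.raises(ValueError, match="missing"):
            subgroup_analysis(eff, {"s0": "A"})

    def test_decomposition_identity_on_simulated_data(self):
        for r in range(100):
            ds = simulate_subgrouped(SimulationSpec(N=12, seed=300 + r),
                                     {"A": 0.0, "B": 0.7, "C": -0.4})
            eff = effects_from_dataset(ds)
            labels = {rec.study_id: rec.covariates["group"] for rec in ds}
            res = subgroup_analysis(eff, labels)
            assert res.Q_between + res.Q_within == pytest.approx(res.Q_total, abs=1e-9)

    def test_strong_separation_explains_most_heterogeneity(self):
        ds = simulate_subgrouped(
            SimulationSpec(N=30, tau2=0.01, se_dist=(0.05, 0.1), seed=5),
            {"A": 0.0, "B": 5.0})
        eff = effects_from_dataset(ds)
        labels = {rec.study_id: rec.covariates["group"] for rec in ds}
        res = subgroup_analysis(eff, labels)
        assert res.R2_explained > 90.0
        assert res.p_between < 1e-6


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 5, 0.01), (0.05, 1, 0.05), (0.01, 4, 0.0025)])
    def test_division(self, alpha, m, expected):
        assert bonferroni(alpha, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.001, 0.2), st.integers(1, 50))
    def test_adjusted_threshold_never_exceeds_alpha(self, alpha, m):
        assert 0 < bonferroni(alpha, m) <= alpha


class TestMetaRegression:
    def test_perfect_linear_fit(self):
        eff = _effects([1.0, 3.0, 5.0])
        res = meta_regression(eff, np.array([0.0, 1.0, 2.0]), model="fixed")
        assert res.beta == pytest.approx([1.0, 2.0])
        assert res.Q_residual == pytest.approx(0.0, abs=1e-12)
        assert res.R2_explained == pytest.approx(100.0)

    def test_intercept_only_equals_pooled_mean(self, three_effects):
        res = meta_regression(three_effects, np.empty((3, 0)), model="fixed")
        p = pool(three_effects, "fixed")
        assert res.beta[0] == pytest.approx(p.theta_hat, abs=1e-10)

    def test_decomposition_identity_on_simulated_data(self):
        for r in range(100):
            ds = simulate_regression_dataset(SimulationSpec(N=15, seed=600 + r), slope=1.0)
            eff = effects_from_dataset(ds)
            x = np.array([rec.covariates["x"] for rec in ds])
            res = meta_regression(eff, x)
            assert res.Q_model + res.Q_residual == pytest.approx(res.Q_total, abs=1e-9)

    def test_rank_deficiency_rejected(self):
        eff = _effects([0, 1, 2, 3, 4])
        X = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="rank"):
            meta_regression(eff, X)

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError, match="more studies"):
            meta_regression(_effects([0, 1]), np.array([0.0, 1.0]))

    def test_categorical_covariate_dummy_coding(self):
        eff = _effects([1, 1, 3, 3, 2, 2])
        X = pd.DataFrame({"grp": ["a", "a", "b", "b", "a", "b"]})
        res = meta_regression(eff, X, model="fixed")
        assert res.coef_names == ["intercept", "grp[b]"]

    def test_slope_ci_coverage_under_random_effects(self):
        """beta1 95% CI covers the generative slope in >=93% of replicates."""
        hits = 0
        n_rep = 200
        for r in range(n_rep):
            ds = simulate_regression_dataset(
                SimulationSpec(mu=0.0, tau2=0.1, N=50, seed=7000 + r), slope=1.0)
            eff = effects_from_dataset(ds)
            x = np.array([rec.covariates["x"] for rec in ds])
            res = meta_regression(eff, x, model="random")
            lo, hi = res.ci_beta[1]
            hits += lo <= 1.0 <= hi
        assert hits / n_rep >= 0.93


class TestIntrastudyRegression:
    def test_equal_weight_mean_of_exact_slopes(self):
        series = {
            "a": ([0, 1, 2], [0, 1, 2], [0.1] * 3, [3] * 3),       # slope 1
            "b": ([0, 1, 2], [0, 3, 6], [0.1] * 3, [3] * 3),       # slope 3
        }
        beta, ci, per = intrastudy_regression(series, scheme="unweighted")
        assert beta == pytest.approx(2.0)
        assert {s.study_id: s.beta_intra for s in per} == {"a": 1.0, "b": 3.0}

    def test_flat_studies_pool_to_zero(self):
        series = {f"s{i}": ([0, 1, 2], [5.0, 5.0, 5.0], [0.1] * 3, [3] * 3)
                  for i in range(3)}
        beta, _, _ = intrastudy_regression(series, scheme="unweighted")
        assert beta == pytest.approx(0.0)

    def test_single_x_level_study_skipped(self):
        series = {
            "ok1": ([0, 1, 2, 3], [0, 1.1, 1.9, 3.2], [0.1] * 4, [3] * 4),
            "ok2": ([0, 1, 2, 3], [0, 0.9, 2.1, 2.8], [0.1] * 4, [3] * 4),
            "flat_x": ([1, 1, 1], [0, 1, 2], [0.1] * 3, [3] * 3),
        }
        _, _, per = intrastudy_regression(series)
        assert {s.study_id for s in per} == {"ok1", "ok2"}

    def test_sign_agreement_with_interstudy_slope(self):
        """Pooled within-study slope agrees in sign with the meta-regression
        coefficient when the relationship is real at both levels."""
        rng = np.random.default_rng(21)
        series = {}
        effects, xs = [], []
        for i in range(8):
            x = np.arange(4.0)
            y = 0.5 + 2.0 * x + rng.normal(0, 0.2, 4)
            series[f"s{i}"] = (x, y, [0.2] * 4, [4] * 4)
            xi = rng.uniform(0, 3)
            effects.append(EffectSize(f"s{i}", float(0.5 + 2.0 * xi + rng.normal(0, 0.2)),
                                      0.2, 4))
            xs.append(xi)
        beta_intra, _, _ = intrastudy_regression(series)
        res = meta_regression(effects, np.array(xs))
        assert np.sign(beta_intra) == np.sign(res.beta[1])
        assert beta_intra == pytest.approx(2.0, abs=0.3)


def test_null_subgroup_p_between_calibrated():
    """Uninformative grouping rejects at ~alpha under the homogeneous null."""
    rej = 0
    n_rep = 500
    for r in range(n_rep):
        ds = simulate_subgrouped(SimulationSpec(tau2=0.0, N=20, seed=40000 + r),
                                 {"A": 0.0, "B": 0.0})
        eff = effects_from_dataset(ds)
        labels = {rec.study_id: rec.covariates["group"] for rec in ds}
        rej += subgroup_analysis(eff, labels).p_between < 0.05
    assert 0.03 <= rej / n_rep <= 0.07
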