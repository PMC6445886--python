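import numpy as np
import pytest

from benchmeta.datatypes import CurveDataset
from benchmeta.modelfit import MODELS, fit_quality, get_model, mc_fit
from benchmeta.simulate import simulate_dose_response


def _noiseless(model_id, beta, x):
    spec = get_model(model_id)
    x = np.asarray(x, dtype=float)
    return CurveDataset(x=x, theta=spec.func(x, *beta),
                        sd=np.zeros_like(x), n=np.ones_like(x, dtype=int))


NOISELESS_CASES = [
    ("linear", (2.0, 1.0), [0, 1, 2]),
    ("quadratic_vertex", (1.5, 2.0, -3.0), np.linspace(0, 4, 7)),
    ("exponential", (3.0, -0.5), np.linspace(0, 5, 8)),
    ("michaelis_menten", (10.0, 2.0), [0.5, 1, 2, 4, 8, 16]),
    ("hill", (1.0, 5.0, 2.0), [0.5, 1, 2, 4, 8, 16, 32]),
]


class TestMcFit:
    @pytest.mark.parametrize("model_id,beta,x", NOISELESS_CASES)
    def test_noiseless_recovery(self, model_id, beta, x):
        res = mc_fit(_noiseless(model_id, beta, x), get_model(model_id), M=3, seed=0)
        assert res.beta_mean == pytest.approx(np.asarray(beta), abs=1e-6)
        assert np.all(res.beta_sd <= 1e-8)
        assert res.converged_fraction == 1.0

    def test_hill_recovery_under_noise(self):
        data = simulate_dose_response("hill", (1.0, 5.0, 2.0),
                                      [0.5, 1, 2, 4, 8, 16], sd=0.05, n=5, seed=3)
        res = mc_fit(data, get_model("hill"), M=400, seed=11)
        for b, mean, sd in zip((1.0, 5.0, 2.0), res.beta_mean, res.beta_sd):
            assert abs(mean - b) <= 3 * sd

    def test_too_few_levels_rejected(self):
        d = CurveDataset(x=[0, 1], theta=[1, 2], sd=[0, 0], n=[1, 1])
        with pytest.raises(ValueError, match="levels"):
            mc_fit(d, get_model("hill"), M=1)

    def test_deterministic_given_seed(self):
        data = simulate_dose_response("linear", (2.0, 1.0), [0, 1, 2, 3],
                                      sd=0.3, n=4, seed=0)
        r1 = mc_fit(data, get_model("linear"), M=50, seed=5)
        r2 = mc_fit(data, get_model("linear"), M=50, seed=5)
        assert np.array_equal(r1.draws, r2.draws)

    def test_extending_M_preserves_earlier_draws(self):
        data = simulate_dose_response("linear", (2.0, 1.0), [0, 1, 2, 3],
                                      sd=0.3, n=4, seed=0)
        r50 = mc_fit(data, get_model("linear"), M=50, seed=5)
        r80 = mc_fit(data, get_model("linear"), M=80, seed=5)
        assert np.array_equal(r80.draws[:50], r50.draws)

    def test_running_mean_stabilizes(self):
        data = simulate_dose_response("linear", (2.0, 1.0), [0, 1, 2, 3],
                                      sd=0.5, n=3, seed=1)
        res = mc_fit(data, get_model("linear"), M=400, seed=7)
        M = len(res.draws)
        half = res.draws[: M // 2].mean(axis=0)
        full = res.draws.mean(axis=0)
        assert np.all(np.abs(half - full) < 2 * res.beta_sd / np.sqrt(M) * np.sqrt(M))
        # tighter form of the same contract on the slope
        assert abs(half[0] - full[0]) < 2 * res.beta_sd[0] / np.sqrt(M // 2)

    def test_larger_n_shrinks_parameter_sd(self):
        small = simulate_dose_response("linear", (2.0, 1.0), [0, 1, 2, 3],
                                       sd=0.5, n=2, seed=2)
        big = CurveDataset(x=small.x, theta=small.theta, sd=small.sd,
                           n=np.full_like(small.n, 50))
        r_small = mc_fit(small, get_model("linear"), M=200, seed=9)
        r_big = mc_fit(big, get_model("linear"), M=200, seed=9)
        assert np.all(r_big.beta_sd < r_small.beta_sd)

    def test_black_box_independent_of_provenance(self):
        """Results depend only on (x, theta, sd, n)."""
        d1 = CurveDataset(x=[0, 1, 2], theta=[1, 3, 5], sd=[0.2] * 3, n=[4] * 3)
        d2 = CurveDataset(x=np.array([0.0, 1.0, 2.0]),
                          theta=np.array([1.0, 3.0, 5.0]),
                          sd=np.full(3, 0.2), n=np.array([4, 4, 4]))
        r1 = mc_fit(d1, get_model("linear"), M=20, seed=3)
        r2 = mc_fit(d2, get_model("linear"), M=20, seed=3)
        assert np.array_equal(r1.draws, r2.draws)


class TestFitQuality:
    def test_noiseless_r2_is_one(self):
        res = mc_fit(_noiseless("linear", (2.0, 1.0), [0, 1, 2]),
                     get_model("linear"), M=3, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_too_few_draws_rejected(self):
        data = _noiseless("linear", (2.0, 1.0), [0, 1, 2])
        res = mc_fit(data, get_model("linear"), M=3, seed=0)
        with pytest.raises(ValueError, match="10 draws"):
            fit_quality(res, data)

    def test_normal_draws_pass_flags(self):
        """Draws sampled from a normal pass the normality flag >=90% of the time."""
        from benchmeta.datatypes import ModelFitResult
        data = _noiseless("linear", (2.0, 1.0), [0, 1, 2])
        passes = 0
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(r)
            draws = rng.normal([2.0, 1.0], 0.1, size=(100, 2))
            res = ModelFitResult("linear", draws.mean(axis=0), draws.std(axis=0, ddof=1),
                                 draws, 100, 1.0)
            _, flags = fit_quality(res, data)
            passes += all(flags)
        assert passes >= 90 * 0.9  # both-parameter pass rate ~0.95^2

    def test_non_normal_draws_raise_flags(self):
        from benchmeta.datatypes import ModelFitResult
        data = _noiseless("linear", (2.0, 1.0), [0, 1, 2])
        rng = np.random.default_rng(1)
        draws = np.column_stack([rng.exponential(1.0, 200), rng.normal(1.0, 0.1, 200)])
        res = ModelFitResult("linear", draws.mean(axis=0), draws.std(axis=0, ddof=1),
                             draws, 200, 1.0)
        _, flags = fit_quality(res, data)
        assert flags[0] is False
        assert flags[1] is True

    def test_flat_noise_vs_hill_degrades(self):
        """Flat truth with large noise fitted by a sigmoid yields unstable fits."""
        rng = np.random.default_rng(4)
        x = np.array([0.5, 1, 2, 4, 8, 16])
        d = CurveDataset(x=x, theta=np.full(6, 1.0) + rng.normal(0, 0.01, 6),
                         sd=np.full(6, 2.0), n=np.full(6, 3))
        res = mc_fit(d, get_model("hill"), M=100, seed=8)
        degraded = (res.converged_fraction < 1.0
                    or not all(res.normality_flags)
                    or res.r2 < 0.5)
        assert degraded
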