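"""Calibration machinery: Gaussian set likelihoods, weighted posterior
summaries, and the nested sampler against closed-form oracles."""

import numpy as np
import pytest
from scipy.special import logsumexp

import soilplant as sp
from soilplant.calibrate import (ObservationSet, ParameterSpace,
                                 log_likelihood_set, posterior_predictive,
                                 sampler_convergence, total_log_likelihood)
from soilplant.nested import run_nested_sampling, weighted_quantile


class TestLogLikelihood:
    def test_zero_residual(self):
        obs = ObservationSet("a", [1.0, 2.0, 3.0], [4.0, 5.0, 6.0], 0.3)
        ll = log_likelihood_set(np.array([4.0, 5.0, 6.0]), obs)
        assert ll == pytest.approx(-1.5 * np.log(2 * np.pi * 0.09))

    def test_unit_standardized_residual(self):
        obs = ObservationSet("a", [0.0], [1.0], 0.7)
        ll = log_likelihood_set(np.array([1.7]), obs)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * 0.49) - 0.5)

    def test_hand_computed_value(self):
        obs = ObservationSet("a", [0.0, 1.0, 2.0], [0.0, 0.0, 0.0], 0.5)
        ll = log_likelihood_set(np.array([0.1, -0.2, 0.3]), obs)
        assert ll == pytest.approx(-0.9573740579341823, rel=1e-12)

    def test_misalignment_rejected(self):
        obs = ObservationSet("a", [0.0, 1.0], [0.0, 0.0], 0.5)
        with pytest.raises(ValueError):
            log_likelihood_set(np.zeros(3), obs)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            ObservationSet("a", [0.0], [0.0], 0.0)


class _DictForward:
    """Forward stub returning preset series."""

    def __init__(self, series):
        self.series_map = series

    def __call__(self, theta):
        return self

    def sample(self, label, times):
        return np.asarray(self.series_map[label], dtype=float)


class TestTotalLogLikelihood:
    def _obs(self):
        return [ObservationSet("s1", [0.0, 1.0], [1.0, 2.0], 0.5),
                ObservationSet("s2", [0.0, 1.0, 2.0], [0.0, 0.1, 0.2], 0.2)]

    def test_additivity_over_sets(self):
        obs = self._obs()
        fwd = _DictForward({"s1": [1.2, 1.9], "s2": [0.0, 0.0, 0.4]})
        total = total_log_likelihood(np.zeros(1), obs, fwd)
        parts = [log_likelihood_set(fwd.sample(o.label, o.times), o)
                 for o in obs]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_single_set_reduces_to_set_likelihood(self):
        obs = self._obs()[:1]
        fwd = _DictForward({"s1": [1.2, 1.9]})
        assert total_log_likelihood(np.zeros(1), obs, fwd) == \
            pytest.approx(log_likelihood_set(np.array([1.2, 1.9]), obs[0]))

    def test_forward_failure_maps_to_minus_inf(self):
        def bad(theta):
            raise RuntimeError("solver blew up")
        assert total_log_likelihood(np.zeros(1), self._obs(), bad) == -np.inf

    def test_order_invariance(self):
        obs = self._obs()
        fwd = _DictForward({"s1": [1.2, 1.9], "s2": [0.0, 0.0, 0.4]})
        a = total_log_likelihood(np.zeros(1), obs, fwd)
        b = total_log_likelihood(np.zeros(1), obs[::-1], fwd)
        assert a == pytest.approx(b, rel=1e-14)


class TestWeightedQuantile:
    def test_point_mass(self):
        q = weighted_quantile(np.full(5, 3.3), (0.05, 0.5, 0.95),
                              np.ones(5))
        np.testing.assert_allclose(q, 3.3)

    def test_midpoint_convention(self):
        x = np.arange(1.0, 101.0)
        q = weighted_quantile(x, (0.5,), np.ones(100))
        assert q[0] == pytest.approx(50.5)

    def test_against_brute_force_cdf_scan(self, rng):
        x = rng.normal(size=400)
        w = rng.uniform(0.1, 1.0, size=400)
        probs = np.array([0.05, 0.25, 0.5, 0.75, 0.95])
        q = weighted_quantile(x, probs, w)
        order = np.argsort(x)
        xs, ws = x[order], w[order] / w.sum()
        pos = np.cumsum(ws) - 0.5 * ws
        for p, qv in zip(probs, q):
            ref = np.interp(p, pos, xs)
            assert qv == pytest.approx(ref, rel=1e-12)
        assert np.all(np.diff(q) >= 0.0)


class TestNestedSampler:
    def test_constant_likelihood_returns_prior(self):
        space = ParameterSpace(("x",), np.array([[0.0, 2.0]]))
        res = run_nested_sampling(lambda v: 1.234, space.prior_transform,
                                  1, n_live=100, seed=3, walk_steps=8)
        assert res.logz == pytest.approx(1.234, abs=0.02)
        assert res.mean()[0] == pytest.approx(1.0, abs=0.1)

    def test_gaussian_evidence_and_mean(self):
        # L = N(0, 0.1) density, uniform prior on [-1, 1]: Z = 1/2
        sig = 0.1

        def loglike(v):
            return float(-0.5 * np.log(2 * np.pi * sig ** 2)
                         - v[0] ** 2 / (2 * sig ** 2))

        space = ParameterSpace(("x",), np.array([[-1.0, 1.0]]))
        res = run_nested_sampling(loglike, space.prior_transform, 1,
                                  n_live=400, seed=11, walk_steps=20)
        assert res.logz == pytest.approx(np.log(0.5), abs=0.2)
        mc_err = 3.0 * sig / np.sqrt(1.0 / np.max(res.weights))
        assert abs(res.mean()[0]) < max(3 * mc_err, 0.02)
        q = res.quantiles((0.05, 0.5, 0.95))
        assert q[1, 0] == pytest.approx(0.0, abs=0.02)
        assert q[2, 0] - q[0, 0] == pytest.approx(2 * 1.6449 * sig,
                                                  rel=0.15)

    def test_seed_reproducibility(self):
        def loglike(v):
            return float(-0.5 * np.sum(v ** 2))
        space = ParameterSpace(("a", "b"),
                               np.array([[-2.0, 2.0], [-2.0, 2.0]]))
        r1 = run_nested_sampling(loglike, space.prior_transform, 2,
                                 n_live=50, seed=42)
        r2 = run_nested_sampling(loglike, space.prior_transform, 2,
                                 n_live=50, seed=42)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert r1.logz == r2.logz

    def test_n_live_validation(self):
        with pytest.raises(ValueError):
            run_nested_sampling(lambda v: 0.0, lambda u: u, 3, n_live=4)

    def test_evidence_of_nested_model_not_above_free_model(self):
        # fixing one parameter at its truth cannot beat the free model's
        # evidence by more than the error bar
        sig = 0.2

        def loglike2(v):
            return float(-np.log(2 * np.pi * sig ** 2)
                         - np.sum(v ** 2) / (2 * sig ** 2))

        free = ParameterSpace(("a", "b"),
                              np.array([[-1.0, 1.0], [-1.0, 1.0]]))
        r_free = run_nested_sampling(loglike2, free.prior_transform, 2,
                                     n_live=200, seed=1)

        def loglike1(v):
            return loglike2(np.array([v[0], 0.0]))

        fixed = ParameterSpace(("a",), np.array([[-1.0, 1.0]]))
        r_fixed = run_nested_sampling(loglike1, fixed.prior_transform, 1,
                                      n_live=200, seed=1)
        # analytically Z_fixed = Z_free * sqrt(2 pi sig^2)/(2) ... just
        # check the ordering with error bars
        assert r_fixed.logz >= r_free.logz - 3 * (r_fixed.logzerr
                                                  + r_free.logzerr)

    def test_weights_normalized_and_quantiles_monotone(self):
        def loglike(v):
            return float(-0.5 * v[0] ** 2)
        space = ParameterSpace(("x",), np.array([[-3.0, 3.0]]))
        res = run_nested_sampling(loglike, space.prior_transform, 1,
                                  n_live=80, seed=0)
        assert res.weights.sum() == pytest.approx(1.0, rel=1e-9)
        q = res.quantiles((0.05, 0.5, 0.95))
        assert q[0, 0] <= q[1, 0] <= q[2, 0]
        assert res.logz == pytest.approx(
            logsumexp(res.log_weights), rel=1e-12)


class TestPosteriorPredictive:
    def _result(self):
        def loglike(v):
            return float(-0.5 * ((v[0] - 0.5) / 0.05) ** 2)
        space = ParameterSpace(("x",), np.array([[0.0, 1.0]]))
        return run_nested_sampling(loglike, space.prior_transform, 1,
                                   n_live=60, seed=2)

    def test_ensemble_shapes_and_envelope(self):
        res = self._result()
        times = {"y": np.array([0.0, 1.0, 2.0])}

        class Fwd:
            def __call__(self, theta):
                self.theta = float(theta[0])
                return self

            def sample(self, label, t):
                return self.theta * np.asarray(t)

        out = posterior_predictive(res, Fwd(), ["y"], times, n_draws=50,
                                   seed=5)
        assert out["trajectories"]["y"].shape == (50, 3)
        assert out["n_failed"] == 0
        env = out["envelope"]["y"]
        assert np.all(env[0] <= env[1] + 1e-12)
        assert np.all(env[1] <= env[2] + 1e-12)

    def test_single_draw_envelope_is_that_trajectory(self):
        res = self._result()
        times = {"y": np.array([1.0, 2.0])}

        class Fwd:
            def __call__(self, theta):
                self.th = float(theta[0])
                return self

            def sample(self, label, t):
                return self.th + 0.0 * np.asarray(t)

        out = posterior_predictive(res, Fwd(), ["y"], times, n_draws=1,
                                   seed=0)
        np.testing.assert_allclose(out["envelope"]["y"][0],
                                   out["envelope"]["y"][2])

    def test_failed_draws_are_skipped_and_counted(self):
        res = self._result()
        times = {"y": np.array([0.0])}
        count = [0]

        class Flaky:
            def __call__(self, theta):
                count[0] += 1
                if count[0] % 3 == 0:
                    raise RuntimeError("boom")
                self.th = float(theta[0])
                return self

            def sample(self, label, t):
                return np.array([self.th])

        out = posterior_predictive(res, Flaky(), ["y"], times, n_draws=9,
                                   seed=1)
        assert out["n_failed"] >= 1
        assert out["trajectories"]["y"].shape[0] == 9 - out["n_failed"]


class TestSamplerConvergence:
    @staticmethod
    def _loglike(v):
        return float(-0.5 * np.sum((v / 0.2) ** 2))

    def test_identical_settings_zero_drift(self):
        space = ParameterSpace(("a",), np.array([[-1.0, 1.0]]))
        rep = sampler_convergence(space, self._loglike, [100], [3, 3])
        assert rep["logz_drift"] == 0.0
        assert rep["median_drift_rel"] == 0.0
        assert not rep["flag"]

    def test_stable_on_analytic_problem(self):
        space = ParameterSpace(("a",), np.array([[-1.0, 1.0]]))
        rep = sampler_convergence(space, self._loglike, [150, 300], [3])
        assert rep["logz_drift"] < 0.3
        assert not rep["flag"]

    def test_tiny_n_live_raises_flag(self):
        space = ParameterSpace(("a", "b"),
                               np.array([[-1.0, 1.0], [-1.0, 1.0]]))

        def sharp(v):
            return float(-0.5 * np.sum(((v - 0.3) / 0.01) ** 2))

        rep = sampler_convergence(space, sharp, [4, 400], [3],
                                  logz_tol=0.5)
        assert rep["flag"]


class TestParameterSpace:
    def test_full_space_has_15_parameters(self):
        space = ParameterSpace.full()
        assert space.ndim == 15
        assert space.names[0] == "alpha1"
        np.testing.assert_allclose(space.bounds[0], [0.001, 0.1])

    def test_prior_transform_bijective_on_bounds(self):
        space = ParameterSpace.subset(("K_RW", "tau_L"))
        u = np.array([0.0, 1.0])
        v = space.prior_transform(u)
        np.testing.assert_allclose(v, [1.0, 0.55])
        mid = space.prior_transform(np.array([0.5, 0.5]))
        assert space.contains(mid)
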