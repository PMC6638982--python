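"""Likelihoods, grid posteriors, marginal likelihood, point estimates."""

import inspect

import numpy as np
import pytest
from scipy.stats import norm

from probtrack import (
    FitGrid,
    ParameterPrior,
    TaskConfig,
    grid_log_posterior,
    marginal_likelihood,
    param_priors,
    point_estimates,
    sequence_log_likelihood,
    simulate_session,
)
from probtrack.fitting import _logtrapz
from probtrack.task import LAPSE_COVERT


@pytest.fixture(scope="module")
def covert_session():
    cfg = TaskConfig(seed=21)
    return simulate_session(cfg, "exp_bias", {"alpha": 0.17, "w": 0.58},
                            "covert", rng_seed=21)


@pytest.fixture(scope="module")
def overt_session():
    cfg = TaskConfig(seed=22)
    return simulate_session(cfg, "exp_bias", {"alpha": 0.22, "w": 0.74},
                            "overt", rng_seed=22)


class TestPriorRegistry:
    def test_noise_parameter_per_task(self):
        for model in ("fixed", "exp_bias", "bayes_r", "wilson"):
            assert param_priors(model, "covert")[0].name == "sigma_v"
            assert param_priors(model, "overt")[0].name == "sigma_a"

    def test_transforms(self):
        names = {p.name: p for p in param_priors("wilson", "covert")}
        assert names["delta1"].transform == "sqrt"
        assert names["nu_p"].transform == "log"
        assert names["nu_p"].natural(5.0) == pytest.approx(np.exp(5.0))
        beta = {p.name: p for p in param_priors("bayes_beta", "covert")}
        assert beta["beta"].natural(10.0) == pytest.approx(100.0)

    def test_default_restart_budget(self):
        sig = inspect.signature(point_estimates)
        assert sig.parameters["n_restarts"].default == 20


class TestSequenceLogLikelihood:
    def test_fixed_model_equals_direct_composition(self, covert_session):
        trials, resp = covert_session
        sv = 9.0
        ll = sequence_log_likelihood(trials, resp, "fixed", {"sigma_v": sv})
        z = trials.config.z_neutral
        pA = (1 - LAPSE_COVERT) * norm.cdf(
            (z - trials.stimulus) / sv) + LAPSE_COVERT / 2
        p = np.where(resp.response == 1, pA, 1 - pA)
        assert ll == pytest.approx(np.log(p).sum(), abs=1e-8)

    def test_likelihood_peaks_near_generating_parameters(self):
        # data simulated at (alpha*, w*) should beat +/-0.2 perturbations
        cfg = TaskConfig()
        wins_a = wins_w = 0
        for seed in range(20):
            trials, resp = simulate_session(
                cfg, "exp_bias", {"alpha": 0.3, "w": 0.6}, "covert",
                rng_seed=100 + seed)
            base = {"sigma_v": cfg.sigma_v, "alpha": 0.3, "w": 0.6}
            ll0 = sequence_log_likelihood(trials, resp, "exp_bias", base)
            for key, cnt in (("alpha", "a"), ("w", "w")):
                worse = all(
                    sequence_log_likelihood(
                        trials, resp, "exp_bias",
                        {**base, key: base[key] + d}) < ll0
                    for d in (-0.2, 0.2))
                if key == "alpha":
                    wins_a += worse
                else:
                    wins_w += worse
        assert wins_a >= 18 and wins_w >= 18

    def test_shape_mismatch_raises(self, covert_session):
        trials, resp = covert_session
        from probtrack import ResponseRecord

        bad = ResponseRecord("covert", resp.response[:-1])
        with pytest.raises(ValueError):
            sequence_log_likelihood(trials, bad, "fixed", {"sigma_v": 10})

    def test_rl_monte_carlo_seed_stability(self):
        cfg = TaskConfig(seed=5)
        trials, resp = simulate_session(cfg, "rl", {"alpha": 0.26},
                                        "covert", rng_seed=5)
        theta = {"alpha": 0.26, "sigma_v": 10.0}
        ll1 = sequence_log_likelihood(trials, resp, "rl", theta, mc_seed=1)
        ll2 = sequence_log_likelihood(trials, resp, "rl", theta, mc_seed=2)
        assert abs(ll1 - ll2) < 0.5

    def test_per_trial_probabilities_bounded(self, covert_session):
        # lapse mixing bounds each covert trial's probability
        trials, resp = covert_session
        T = len(trials)
        ll = sequence_log_likelihood(trials, resp, "exp_bias",
                                     {"sigma_v": 10, "alpha": 0.2, "w": 0.6})
        assert T * np.log(LAPSE_COVERT / 2) <= ll <= 0.0


class TestGridPosterior:
    def test_default_resolutions(self):
        from probtrack.fitting import GRID_POINTS_DEFAULT, GRID_POINTS_WILSON

        assert GRID_POINTS_DEFAULT == 100 and GRID_POINTS_WILSON == 50

    def test_flat_likelihood_offsets_prior(self, covert_session):
        trials, resp = covert_session
        grid = grid_log_posterior(trials, resp, "fixed", n_grid=20)
        diff = grid.log_joint - grid.log_like
        assert np.allclose(diff, diff.flat[0])

    def test_map_against_local_refinement(self, covert_session):
        trials, resp = covert_session
        grid = grid_log_posterior(trials, resp, "exp_bias", n_grid=25)
        mapest = grid.map_estimate()
        best_ll = grid.log_joint.max()
        # dense re-evaluation around the MAP must not beat the grid node
        # by more than the local curvature allows within half a cell
        cell = [float(ax[1] - ax[0]) for ax in grid.axes]
        rng = np.random.default_rng(0)
        for _ in range(10):
            theta = {}
            for p, c in zip(grid.priors, cell):
                center = [v for k, v in mapest.items() if k == p.name][0]
                tr_center = {"identity": center, "sqrt": np.sqrt(center),
                             "log": np.log(center)}[p.transform]
                theta[p.name] = float(p.natural(
                    np.clip(tr_center + rng.uniform(-c, c), p.lo, p.hi)))
            ll = sequence_log_likelihood(trials, resp, "exp_bias", theta) \
                + sum(p.log_density for p in grid.priors)
            assert ll <= best_ll + 2.0

    def test_refuses_high_dimensional_models(self, covert_session):
        trials, resp = covert_session
        with pytest.raises(ValueError, match="maximum likelihood"):
            grid_log_posterior(trials, resp, "bayes_rpb", n_grid=5)

    def test_lml_stable_under_grid_refinement(self):
        cfg = TaskConfig(n_trials=400, seed=31)
        trials, resp = simulate_session(cfg, "exp", {"alpha": 0.1},
                                        "covert", rng_seed=31)
        lml50 = marginal_likelihood(
            grid_log_posterior(trials, resp, "exp", n_grid=50))
        lml100 = marginal_likelihood(
            grid_log_posterior(trials, resp, "exp", n_grid=100))
        assert abs(lml50 - lml100) < 0.1


class TestMarginalLikelihood:
    def _gaussian_grid(self, n=100):
        prior = ParameterPrior("x", -10.0, 10.0)
        ax = prior.axis(n)
        log_joint = norm.logpdf(ax) + prior.log_density
        return FitGrid("toy", "covert", (prior,), (ax,), log_joint, 1)

    def test_constant_likelihood_returns_it(self):
        prior = ParameterPrior("x", 0.0, 2.0)
        ax = prior.axis(50)
        grid = FitGrid("toy", "covert", (prior,), (ax,),
                       np.full(50, -3.0) + prior.log_density, 1)
        assert marginal_likelihood(grid) == pytest.approx(-3.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        # integral of N(0,1) * Unif(-10,10) = 1/20
        grid = self._gaussian_grid(100)
        assert marginal_likelihood(grid) == pytest.approx(
            np.log(1.0 / 20.0), abs=1e-3)

    def test_axis_reversal_invariance(self):
        grid = self._gaussian_grid(101)
        flipped = FitGrid("toy", "covert", grid.priors,
                          (grid.axes[0][::-1].copy(),),
                          grid.log_joint[::-1].copy(), 1)
        assert marginal_likelihood(flipped) == pytest.approx(
            marginal_likelihood(grid), abs=1e-6)

    def test_single_point_axis_errors(self):
        with pytest.raises(ValueError):
            _logtrapz(np.zeros(1), np.zeros(1))


class TestPointEstimates:
    def test_mle_recovers_and_dominates_grid_map(self):
        cfg = TaskConfig(n_trials=400, seed=41)
        trials, resp = simulate_session(cfg, "exp", {"alpha": 0.12},
                                        "covert", rng_seed=41)
        fr = point_estimates(trials, resp, "exp", n_restarts=4, seed=1)
        assert abs(fr.mle_params["alpha"] - 0.12) < 0.1
        grid = grid_log_posterior(trials, resp, "exp", n_grid=30)
        assert fr.max_loglik >= grid.log_like.max() - 1e-6
        # AIC - BIC = 2k - k ln(n)
        k, n = 2, 400
        assert fr.aic - fr.bic == pytest.approx(2 * k - k * np.log(n))

    def test_aic_bic_identity_at_800_trials(self):
        # arithmetic identity for a 2-parameter model on a full session
        k, n = 2, 800
        assert 2 * k - k * np.log(n) == pytest.approx(-9.3692, abs=1e-3)


class TestGridDispatchPaths:
    """Every latent-trajectory family must flow through the grid evaluator."""

    @pytest.mark.parametrize("model,n_grid,truth", [
        ("bayes_r", 8, {"r": 100}),
        ("wilson", 5, {"delta1": 12.0, "delta2": 100.0, "nu_p": 40.0}),
        ("behrens_bias", 6, {"w": 0.4}),
    ])
    def test_small_grid_fits_are_finite(self, model, n_grid, truth):
        cfg = TaskConfig(n_trials=150, seed=81)
        trials, resp = simulate_session(cfg, model, truth, "covert",
                                        rng_seed=81)
        grid = grid_log_posterior(trials, resp, model, n_grid=n_grid)
        assert np.all(np.isfinite(grid.log_joint))
        lml = marginal_likelihood(grid)
        assert np.isfinite(lml)
        mapest = grid.map_estimate()
        assert set(mapest) == {p.name for p in grid.priors}

    def test_rl_grid_uses_common_random_numbers(self):
        cfg = TaskConfig(n_trials=120, seed=82)
        trials, resp = simulate_session(cfg, "rl", {"alpha": 0.25},
                                        "covert", rng_seed=82)
        g1 = grid_log_posterior(trials, resp, "rl", n_grid=4, mc_seed=9)
        g2 = grid_log_posterior(trials, resp, "rl", n_grid=4, mc_seed=9)
        assert np.array_equal(g1.log_joint, g2.log_joint)
        assert np.all(np.isfinite(g1.log_joint))

    def test_overt_grid_fit_recovers_noise_scale(self):
        cfg = TaskConfig(seed=83)
        trials, resp = simulate_session(cfg, "exp", {"alpha": 0.09},
                                        "overt", rng_seed=83)
        grid = grid_log_posterior(trials, resp, "exp", n_grid=30)
        mapest = grid.map_estimate()
        assert abs(mapest["sigma_a"] - cfg.sigma_a) < 3.0
        assert abs(mapest["alpha"] - 0.09) < 0.08
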