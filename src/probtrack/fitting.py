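"""Trial-level likelihoods and Bayesian model fitting on parameter grids.

Each observer model is fitted per subject and task by evaluating the log
unnormalized posterior ``log p*(theta) = log p(data | theta, M) +
log p(theta | M)`` on a regular grid, with priors uniform in a transformed
space (identity, sqrt or log, following the prior registry).  The grid gives
the MAP estimate and — by trapezoidal integration in log space — the log
marginal likelihood used for model comparison.  Models with more than four
parameters (bayes_rpb) are fitted by maximum likelihood with a bounded
multi-start optimizer instead, and scored by AIC/BIC.

Per task the free noise parameter is the sensory noise ``sigma_v`` (covert)
or the criterion-adjustment noise ``sigma_a`` (overt, with ``sigma_v`` fixed
at its known generative value).  Likelihoods separate into a label-driven
probability trajectory (latent parameters) and a per-trial response
probability (noise parameter), which the grid evaluation exploits by
vectorizing over the noise axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, ndtr

from .observers import prob_trajectory
from .observers.heuristics import exp_sequence_grid, wilson_sequence_grid
from .task import ORIENTATION_PERIOD, ResponseRecord, TaskConfig, TrialSequence

__all__ = [
    "ParameterPrior",
    "param_priors",
    "FitGrid",
    "FitResult",
    "sequence_log_likelihood",
    "grid_log_posterior",
    "marginal_likelihood",
    "point_estimates",
]

RL_N_MC = 5000  # Monte-Carlo measurement vectors for the RL likelihood

GRID_POINTS_DEFAULT = 100
GRID_POINTS_WILSON = 50


# ------------------------------------------------------------------- priors

@dataclass(frozen=True)
class ParameterPrior:
    """Uniform prior over ``[lo, hi]`` in the transformed space.

    ``transform`` maps the natural parameter to the space in which both the
    prior and the grid are uniform: identity, sqrt (grid on sqrt(value)) or
    log (grid on ln(value)).
    """

    name: str
    lo: float
    hi: float
    transform: str = "identity"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)
                and self.lo < self.hi):
            raise ValueError("bounds must be finite and ordered")
        if self.transform not in ("identity", "sqrt", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def natural(self, x):
        """Transformed-space value(s) -> natural scale."""
        x = np.asarray(x, dtype=float)
        if self.transform == "sqrt":
            return x**2
        if self.transform == "log":
            return np.exp(x)
        return x

    def axis(self, n: int) -> np.ndarray:
        """n equally spaced grid points in the transformed space."""
        if n < 2:
            raise ValueError("degenerate grid: need at least 2 points per axis")
        return np.linspace(self.lo, self.hi, n)

    @property
    def log_density(self) -> float:
        """Log prior density (constant, in the transformed space)."""
        return -math.log(self.hi - self.lo)


_EPS = 1e-3  # inset applied at open prior bounds

_LATENT_PRIORS: dict[str, tuple[ParameterPrior, ...]] = {
    "fixed": (),
    "behrens": (),
    "exp": (ParameterPrior("alpha", 0.0, 1.0),),
    "rl": (ParameterPrior("alpha", 0.0, 1.0),),
    "behrens_bias": (ParameterPrior("w", 0.0, 1.0),),
    "exp_bias": (ParameterPrior("alpha", 0.0, 1.0),
                 ParameterPrior("w", 0.0, 1.0)),
    "bayes_ideal": (),
    "bayes_r": (ParameterPrior("r", 2.0, 200.0),),
    "bayes_pi": (ParameterPrior("pi_min", _EPS, 0.5 - _EPS),),
    "bayes_beta": (ParameterPrior("beta", _EPS, 10.0, "sqrt"),),
    "bayes_rpb": (ParameterPrior("r", 1.0, 200.0),
                  ParameterPrior("dr", 1.0, 200.0),
                  ParameterPrior("pi_min", _EPS, 0.5 - _EPS),
                  ParameterPrior("pi_max", 0.5 + _EPS, 1.0 - _EPS),
                  ParameterPrior("beta", _EPS, 10.0, "sqrt")),
    "wilson": (ParameterPrior("delta1", 1.01, 5.0, "sqrt"),
               ParameterPrior("delta2", 1.01, 14.0, "sqrt"),
               ParameterPrior("nu_p", 0.0, 5.0, "log")),
}


def param_priors(model_id: str, task: str) -> tuple[ParameterPrior, ...]:
    """Prior registry for one model and task: noise parameter first."""
    if model_id not in _LATENT_PRIORS:
        raise KeyError(f"unknown model id {model_id!r}")
    noise_name = "sigma_v" if task == "covert" else "sigma_a"
    return (ParameterPrior(noise_name, 1.0, 30.0),) + _LATENT_PRIORS[model_id]


# -------------------------------------------------- likelihood building blocks

def _validate(trials: TrialSequence, responses: ResponseRecord) -> None:
    if len(trials) != len(responses):
        raise ValueError("response/trial length mismatch")
    resp = np.asarray(responses.response, dtype=float)
    if np.isnan(resp).any() or np.isnan(trials.stimulus).any():
        raise ValueError("NaN in trial data")


def _log_odds(traj: np.ndarray) -> np.ndarray:
    traj = np.clip(traj, 1e-12, 1.0 - 1e-12)
    return np.log(traj) - np.log1p(-traj)


def _covert_loglik_noise_grid(
    traj: np.ndarray, trials: TrialSequence, responses: ResponseRecord,
    sigma_vs: np.ndarray, config: TaskConfig,
) -> np.ndarray:
    """Covert log likelihood on (latent combos x sigma_v grid).

    ``traj``: (N, T) pre-trial probability estimates.  The criterion gain
    (sigma_s^2 + sigma_v^2)/(mu_B - mu_A) depends on sigma_v, so the whole
    choice probability is recomputed per noise value.
    """
    lam = config.lapse_covert
    s = trials.stimulus
    resp = np.asarray(responses.response, dtype=int)
    L = _log_odds(traj)                                   # (N, T)
    dmu = config.mu_B - config.mu_A
    out = np.empty((traj.shape[0], len(sigma_vs)))
    for m, sv in enumerate(sigma_vs):
        gain = (config.sigma_s**2 + sv**2) / dmu
        z = config.z_neutral + gain * L                   # (N, T)
        pA = ndtr((z - s[None, :]) / sv)
        pA = (1.0 - lam) * pA + lam / 2.0
        p = np.where(resp[None, :] == 1, pA, 1.0 - pA)
        out[:, m] = np.log(p).sum(axis=1)
    return out


def _overt_loglik_noise_grid(
    traj: np.ndarray, trials: TrialSequence, responses: ResponseRecord,
    sigma_as: np.ndarray, config: TaskConfig,
    overt_uses_sensory_noise: bool = False,
) -> np.ndarray:
    """Overt log likelihood on (latent combos x sigma_a grid)."""
    lam = config.lapse_overt
    reports = np.asarray(responses.response, dtype=float)
    dmu = config.mu_B - config.mu_A
    var_dec = config.sigma_s**2 + (config.sigma_v**2
                                   if overt_uses_sensory_noise else 0.0)
    z = config.z_neutral + (var_dec / dmu) * _log_odds(traj)   # (N, T)
    sq = (reports[None, :] - z) ** 2                           # (N, T)
    out = np.empty((traj.shape[0], len(sigma_as)))
    log_lapse = math.log(lam / ORIENTATION_PERIOD) if lam > 0 else -np.inf
    for m, sa in enumerate(sigma_as):
        lg = (-0.5 * sq / sa**2 - math.log(sa)
              - 0.5 * math.log(2.0 * math.pi))
        ll = np.logaddexp(math.log1p(-lam) + lg, log_lapse)
        out[:, m] = ll.sum(axis=1)
    return out


def _rl_criterion_samples(
    trials: TrialSequence, responses: ResponseRecord, alpha: float,
    task: str, config: TaskConfig, n_mc: int, rng: np.random.Generator,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """(n_mc, T) simulated RL criterion paths.

    Feedback correctness on each trial is read from the observed data;
    only the measurement entering the error-driven update is sampled
    (common random numbers across parameter values when ``noise`` is given).
    """
    T = len(trials)
    s = trials.stimulus
    if noise is None:
        noise = rng.standard_normal((n_mc, T))
    x = s[None, :] + config.sigma_v * noise
    if task == "covert":
        correct = np.asarray(responses.response, dtype=int) == trials.category
    else:
        reports = np.asarray(responses.response, dtype=float)
        correct = np.where(trials.category == 1,
                           trials.stimulus < reports,
                           trials.stimulus > reports)
    z = np.full(n_mc, config.z_neutral)
    paths = np.empty((n_mc, T))
    for t in range(T):
        paths[:, t] = z
        if not correct[t]:
            z = z + alpha * (x[:, t] - z)
    return paths


def _rl_loglik(
    trials: TrialSequence, responses: ResponseRecord, alpha: float,
    noise_sd: float, task: str, config: TaskConfig,
    n_mc: int = RL_N_MC, mc_seed: int = 0,
    noise: np.ndarray | None = None,
) -> float:
    """Monte-Carlo RL log likelihood (5000 measurement vectors by default)."""
    rng = np.random.default_rng(mc_seed)
    if task == "covert":
        cfg = config if noise_sd == config.sigma_v else _with(config,
                                                             sigma_v=noise_sd)
        paths = _rl_criterion_samples(trials, responses, alpha, task, cfg,
                                      n_mc, rng, noise)
        lam = config.lapse_covert
        pA = ndtr((paths - trials.stimulus[None, :]) / noise_sd).mean(axis=0)
        pA = (1.0 - lam) * pA + lam / 2.0
        resp = np.asarray(responses.response, dtype=int)
        p = np.where(resp == 1, pA, 1.0 - pA)
        return float(np.log(p).sum())
    paths = _rl_criterion_samples(trials, responses, alpha, task, config,
                                  n_mc, rng, noise)
    lam = config.lapse_overt
    reports = np.asarray(responses.response, dtype=float)
    lg = (-0.5 * ((reports[None, :] - paths) / noise_sd) ** 2
          - math.log(noise_sd) - 0.5 * math.log(2.0 * math.pi))
    log_mix = logsumexp(lg, axis=0) - math.log(paths.shape[0])
    ll = np.logaddexp(math.log1p(-lam) + log_mix,
                      math.log(lam / ORIENTATION_PERIOD))
    return float(ll.sum())


def _with(config: TaskConfig, **kwargs) -> TaskConfig:
    from dataclasses import replace
    return replace(config, delta_theta=config.delta_theta,
                   mu_A=config.mu_A, **kwargs)


def sequence_log_likelihood(
    trials: TrialSequence, responses: ResponseRecord, model_id: str,
    theta: dict, task: str | None = None, config: TaskConfig | None = None,
    n_mc: int = RL_N_MC, mc_seed: int = 0,
) -> float:
    """Total log likelihood of one session under one parameter vector.

    ``theta`` holds natural-scale parameters (noise parameter included:
    ``sigma_v`` covert, ``sigma_a`` overt).
    """
    task = task or responses.task
    config = config or trials.config
    _validate(trials, responses)
    noise_sd = float(theta["sigma_v" if task == "covert" else "sigma_a"])
    if model_id == "rl":
        return _rl_loglik(trials, responses, float(theta["alpha"]), noise_sd,
                          task, config, n_mc=n_mc, mc_seed=mc_seed)
    traj = prob_trajectory(model_id, theta, trials.category, config)[None, :]
    if task == "covert":
        ll = _covert_loglik_noise_grid(traj, trials, responses,
                                       np.array([noise_sd]), config)
    else:
        ll = _overt_loglik_noise_grid(traj, trials, responses,
                                      np.array([noise_sd]), config)
    return float(ll[0, 0])


# ------------------------------------------------------------- grid fitting

@dataclass
class FitGrid:
    """Log unnormalized posterior evaluated on a regular parameter grid.

    ``axes`` are in the transformed space of each prior; ``log_joint`` has
    one dimension per parameter, in ``priors`` order (noise first).
    """

    model: str
    task: str
    priors: tuple[ParameterPrior, ...]
    axes: tuple[np.ndarray, ...]
    log_joint: np.ndarray
    n_trials: int

    @property
    def log_like(self) -> np.ndarray:
        return self.log_joint - sum(p.log_density for p in self.priors)

    def map_estimate(self) -> dict:
        """Natural-scale parameters at the best grid node."""
        idx = np.unravel_index(np.argmax(self.log_joint), self.log_joint.shape)
        return {p.name: float(p.natural(ax[i]))
                for p, ax, i in zip(self.priors, self.axes, idx)}

    def posterior_probs(self) -> np.ndarray:
        w = self.log_joint - self.log_joint.max()
        w = np.exp(w)
        return w / w.sum()


def _latent_trajectories(model_id: str, latent_priors, latent_axes,
                         labels, config: TaskConfig) -> np.ndarray:
    """(N_combos, T) probability trajectories over the latent grid."""
    T = len(labels)
    if not latent_priors:
        return prob_trajectory(model_id, {}, labels, config)[None, :]
    names = [p.name for p in latent_priors]
    nat = [p.natural(ax) for p, ax in zip(latent_priors, latent_axes)]
    mesh = np.meshgrid(*nat, indexing="ij")
    flat = [m.ravel() for m in mesh]
    if model_id in ("exp", "exp_bias"):
        alphas = flat[names.index("alpha")]
        ws = flat[names.index("w")] if "w" in names else np.ones_like(alphas)
        return exp_sequence_grid(labels, alphas, ws)
    if model_id == "behrens_bias":
        base = prob_trajectory("behrens", {}, labels, config)
        ws = flat[names.index("w")]
        return ws[:, None] * base[None, :] + (1.0 - ws[:, None]) / 2.0
    if model_id == "wilson":
        d1 = flat[names.index("delta1")]
        d2 = flat[names.index("delta2")]
        nu = flat[names.index("nu_p")]
        nodes = np.stack([np.ones_like(d1), 1.0 + d1, 1.0 + d1 + d2], axis=1)
        return wilson_sequence_grid(labels, nodes, nu)
    # remaining (Bayesian) models: one forward filter run per combo
    out = np.empty((len(flat[0]), T))
    for i in range(len(flat[0])):
        theta = {n: v[i] for n, v in zip(names, flat)}
        out[i] = prob_trajectory(model_id, theta, labels, config)
    return out


def grid_log_posterior(
    trials: TrialSequence, responses: ResponseRecord, model_id: str,
    task: str | None = None, config: TaskConfig | None = None,
    n_grid: int | None = None, mc_seed: int = 0,
) -> FitGrid:
    """Evaluate log p(data | theta) + log p(theta) on the full prior grid.

    Default resolution is 100 points per axis (50 for the Wilson model).
    Refuses models with more than four parameters (use ``point_estimates``).
    """
    task = task or responses.task
    config = config or trials.config
    _validate(trials, responses)
    priors = param_priors(model_id, task)
    if len(priors) > 4:
        raise ValueError(
            f"{model_id} has {len(priors)} parameters; the grid would be "
            "intractable — fit by maximum likelihood (point_estimates)")
    if n_grid is None:
        n_grid = GRID_POINTS_WILSON if model_id == "wilson" \
            else GRID_POINTS_DEFAULT
    axes = tuple(p.axis(n_grid) for p in priors)
    noise_prior, latent_priors = priors[0], priors[1:]
    noise_vals = noise_prior.natural(axes[0])

    if model_id == "rl":
        loglik = _rl_grid_loglik(trials, responses, latent_priors[0],
                                 axes[1], noise_vals, task, config, mc_seed)
    else:
        traj = _latent_trajectories(model_id, latent_priors, axes[1:],
                                    trials.category, config)
        if task == "covert":
            ll = _covert_loglik_noise_grid(traj, trials, responses,
                                           noise_vals, config)
        else:
            ll = _overt_loglik_noise_grid(traj, trials, responses,
                                          noise_vals, config)
        # (N_combos, noise) -> (noise, latent axes...)
        latent_shape = tuple(len(a) for a in axes[1:])
        loglik = np.moveaxis(ll.reshape(latent_shape + (len(noise_vals),)),
                             -1, 0)
    log_prior = sum(p.log_density for p in priors)
    return FitGrid(model_id, task, priors, axes, loglik + log_prior,
                   len(trials))


def _rl_grid_loglik(trials, responses, alpha_prior, alpha_axis, noise_vals,
                    task, config, mc_seed) -> np.ndarray:
    """RL grid likelihood with common random numbers across grid nodes."""
    rng = np.random.default_rng(mc_seed)
    noise = rng.standard_normal((RL_N_MC, len(trials)))
    out = np.empty((len(noise_vals), len(alpha_axis)))
    for j, a in enumerate(alpha_prior.natural(alpha_axis)):
        for m, sd in enumerate(noise_vals):
            out[m, j] = _rl_loglik(trials, responses, float(a), float(sd),
                                   task, config, noise=noise)
    return out


def _logtrapz(logy: np.ndarray, x: np.ndarray, axis: int = -1) -> np.ndarray:
    """log of the trapezoid-rule integral of exp(logy) along ``axis``."""
    n = logy.shape[axis]
    if n < 2:
        raise ValueError("degenerate grid axis (single point)")
    dx = abs(float(x[1] - x[0]))  # spacing only; axis orientation is free
    w = np.full(n, dx)
    w[0] = w[-1] = dx / 2.0
    shape = [1] * logy.ndim
    shape[axis] = n
    return logsumexp(logy + np.log(w).reshape(shape), axis=axis)


def marginal_likelihood(grid: FitGrid) -> float:
    """Log marginal likelihood by trapezoidal integration over all axes."""
    logy = grid.log_joint
    for ax in reversed(grid.axes):
        logy = _logtrapz(logy, ax, axis=-1)
    return float(logy)


# ----------------------------------------------------------- point estimates

@dataclass
class FitResult:
    """Fit summary for one subject x model x task."""

    model: str
    task: str
    n_trials: int
    lml: float | None = None
    map_params: dict | None = None
    mle_params: dict | None = None
    max_loglik: float | None = None
    aic: float | None = None
    bic: float | None = None
    converged: bool = True
    subject: str | None = None
    grid: FitGrid | None = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        return len(self.map_params or self.mle_params or ())


def point_estimates(
    trials: TrialSequence, responses: ResponseRecord, model_id: str,
    task: str | None = None, config: TaskConfig | None = None,
    n_restarts: int = 20, seed: int = 0, n_mc: int = RL_N_MC,
) -> FitResult:
    """Maximum-likelihood fit with a bounded multi-start optimizer.

    Runs 20 restarts of a bounded Powell search from random starting points
    in the transformed parameter space and keeps the best; reports AIC
    ``2k - 2 log L`` and BIC ``k ln(n) - 2 log L``.
    """
    task = task or responses.task
    config = config or trials.config
    priors = param_priors(model_id, task)
    rng = np.random.default_rng(seed)
    names = [p.name for p in priors]
    bounds = [(p.lo, p.hi) for p in priors]

    # common random numbers for the RL Monte-Carlo likelihood
    mc_seed = int(rng.integers(2**31 - 1))

    def negloglik(x):
        theta = {n: float(p.natural(v))
                 for n, p, v in zip(names, priors, x)}
        try:
            return -sequence_log_likelihood(trials, responses, model_id,
                                            theta, task, config,
                                            n_mc=n_mc, mc_seed=mc_seed)
        except FloatingPointError:
            return np.inf

    best, best_x, any_ok = np.inf, None, False
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(negloglik, x0, method="Powell", bounds=bounds,
                       options={"xtol": 1e-4, "ftol": 1e-6})
        if res.fun < best:
            best, best_x = res.fun, res.x
            any_ok = any_ok or res.success
    mle = {n: float(p.natural(v))
           for n, p, v in zip(names, priors, best_x)}
    k, n = len(priors), len(trials)
    loglik = -best
    return FitResult(model_id, task, n, mle_params=mle, max_loglik=loglik,
                     aic=2 * k - 2 * loglik, bic=k * math.log(n) - 2 * loglik,
                     converged=any_ok)
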