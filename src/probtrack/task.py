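"""Generative model of the orientation-categorization task.

A session is a sequence of trials on which a hidden category-A probability
``pi_t`` follows a sample-and-hold path: it is held constant for a random
number of trials (discrete-uniform segment length) and then jumps to a new
state drawn from a fixed set, excluding the current one.  On each trial a
category label is drawn with ``P(A) = pi_t``, a stimulus orientation is drawn
from that category's Gaussian distribution, and the observer's measurement is
the stimulus corrupted by Gaussian sensory noise.

All orientations are in degrees relative to the neutral criterion
``z_neutral = (mu_A + mu_B) / 2``, with category A clockwise (lower values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialSequence",
    "ResponseRecord",
    "sample_probability_path",
    "category_separation_for_dprime",
    "simulate_session",
]

#: category-A probability states used in the experiment
DEFAULT_STATE_SET = (0.2, 0.35, 0.5, 0.65, 0.8)

#: fixed lapse rates (probability of a fully random response)
LAPSE_COVERT = 1e-4
LAPSE_OVERT = 5e-5

#: period of the orientation space (a criterion line is unoriented)
ORIENTATION_PERIOD = 180.0


def category_separation_for_dprime(
    sigma_s: float, sigma_v: float, target_dprime: float = 1.5
) -> float:
    """Category-mean separation achieving a target discriminability.

    d' is defined on the noisy measurement distribution ``x | C ~
    Normal(mu_C, sigma_s^2 + sigma_v^2)``, so the separation is
    ``delta_theta = d' * sqrt(sigma_s^2 + sigma_v^2)`` (degrees).
    """
    if sigma_s <= 0 or sigma_v < 0:
        raise ValueError("standard deviations must be positive (sigma_v >= 0)")
    if target_dprime <= 0:
        raise ValueError("target_dprime must be positive")
    return target_dprime * math.sqrt(sigma_s**2 + sigma_v**2)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the generative model for one session.

    With the defaults (``sigma_s = sigma_v = 10`` deg, ``target_dprime =
    1.5``) the category separation is 1.5 * sqrt(200) ~= 21.21 deg and an
    ideal observer with equal priors is correct with probability
    Phi(d'/2) ~= 0.77.
    """

    n_trials: int = 800
    state_set: tuple[float, ...] = DEFAULT_STATE_SET
    run_min: int = 80
    run_max: int = 120
    sigma_s: float = 10.0
    sigma_v: float = 10.0
    sigma_a: float = 16.0
    target_dprime: float = 1.5
    delta_theta: float | None = None
    mu_A: float | None = None
    lapse_covert: float = LAPSE_COVERT
    lapse_overt: float = LAPSE_OVERT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.run_min < 1:
            raise ValueError("run_min must be >= 1")
        if self.run_min > self.run_max:
            raise ValueError("run_min must be <= run_max")
        ss = tuple(float(p) for p in self.state_set)
        if len(ss) < 2 or sorted(set(ss)) != list(ss):
            raise ValueError("state_set must be sorted and distinct, length >= 2")
        if not all(0.0 < p < 1.0 for p in ss):
            raise ValueError("state probabilities must lie in (0, 1)")
        if self.sigma_s <= 0 or self.sigma_v <= 0 or self.sigma_a <= 0:
            raise ValueError("all noise SDs must be positive")
        object.__setattr__(self, "state_set", ss)
        if self.delta_theta is None:
            object.__setattr__(
                self,
                "delta_theta",
                category_separation_for_dprime(
                    self.sigma_s, self.sigma_v, self.target_dprime
                ),
            )
        if self.mu_A is None:
            object.__setattr__(self, "mu_A", -self.delta_theta / 2.0)

    @property
    def mu_B(self) -> float:
        return self.mu_A + self.delta_theta

    @property
    def z_neutral(self) -> float:
        return (self.mu_A + self.mu_B) / 2.0

    def lapse(self, task: str) -> float:
        return self.lapse_covert if task == "covert" else self.lapse_overt


@dataclass
class TrialSequence:
    """One simulated session: hidden states, categories and stimuli.

    ``category`` is 1 for category A, 0 for B.  ``stimulus`` and
    ``measurement`` are in degrees relative to the neutral criterion.
    """

    pi: np.ndarray
    change: np.ndarray
    category: np.ndarray
    stimulus: np.ndarray
    measurement: np.ndarray
    config: TaskConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.pi)


@dataclass
class ResponseRecord:
    """Observer responses for one session.

    ``response`` holds covert category choices (1 = A, 0 = B) or overt
    reported criteria (degrees relative to neutral), depending on ``task``.
    """

    task: str
    response: np.ndarray
    model: str | None = None
    params: dict | None = None

    def __len__(self) -> int:
        return len(self.response)


def _sample_segments(rng: np.random.Generator, n_trials: int, run_min: int,
                     run_max: int) -> np.ndarray:
    """Draw iid discrete-uniform segment lengths covering n_trials."""
    lengths = []
    total = 0
    while total < n_trials:
        length = int(rng.integers(run_min, run_max + 1))
        lengths.append(length)
        total += length
    return np.asarray(lengths, dtype=int)


def sample_probability_path(
    config: TaskConfig, rng_seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the hidden sample-and-hold probability path.

    Returns ``(pi, change)``: per-trial category-A probability and a boolean
    flag marking the first trial of each new segment (the first trial is not
    flagged).  The final segment is truncated at ``n_trials``.
    """
    rng = np.random.default_rng(
        config.seed if rng_seed is None else rng_seed
    ) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    states = np.asarray(config.state_set)
    lengths = _sample_segments(rng, config.n_trials, config.run_min, config.run_max)

    pi = np.empty(config.n_trials)
    change = np.zeros(config.n_trials, dtype=bool)
    current = states[rng.integers(len(states))]
    t = 0
    for i, length in enumerate(lengths):
        if i > 0:
            others = states[states != current]
            current = others[rng.integers(len(others))]
            if t < config.n_trials:
                change[t] = True
        stop = min(t + length, config.n_trials)
        pi[t:stop] = current
        t = stop
    return pi, change


def simulate_session(
    config: TaskConfig,
    model_id: str = "bayes_ideal",
    model_params: dict | None = None,
    task: str = "covert",
    rng_seed: int | None = None,
) -> tuple[TrialSequence, ResponseRecord]:
    """Simulate a full session: world plus an observer model's responses.

    The observer receives veridical category feedback ``C_1:t`` after every
    trial (both tasks).  Covert choices apply the model's criterion to the
    noisy measurement, with a fixed lapse rate mixing in a random choice.
    Overt reports are the model criterion plus Gaussian adjustment noise,
    with lapses uniform over the 180-degree orientation space.
    """
    from .observers import criterion_sequence  # deferred: avoids import cycle

    if task not in ("covert", "overt"):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)

    pi, change = sample_probability_path(config, rng)
    category = (rng.random(config.n_trials) < pi).astype(int)
    mu = np.where(category == 1, config.mu_A, config.mu_B)
    stimulus = rng.normal(mu, config.sigma_s)
    measurement = rng.normal(stimulus, config.sigma_v)
    trials = TrialSequence(pi, change, category, stimulus, measurement, config)

    params = dict(model_params or {})
    lam = config.lapse(task)

    if model_id == "rl":
        response = _simulate_rl(trials, params, task, rng, lam)
    else:
        z = criterion_sequence(model_id, params, category, config, task)
        if task == "covert":
            choice = (measurement < z).astype(int)
            lapse_mask = rng.random(config.n_trials) < lam
            choice[lapse_mask] = rng.integers(0, 2, lapse_mask.sum())
            response = choice
        else:
            report = z + rng.normal(0.0, config.sigma_a, config.n_trials)
            lapse_mask = rng.random(config.n_trials) < lam
            report[lapse_mask] = rng.uniform(
                -ORIENTATION_PERIOD / 2, ORIENTATION_PERIOD / 2, lapse_mask.sum()
            )
            response = report
    record = ResponseRecord(task=task, response=response, model=model_id,
                            params=params)
    return trials, record


def _simulate_rl(trials: TrialSequence, params: dict, task: str,
                 rng: np.random.Generator, lam: float) -> np.ndarray:
    """Forward-simulate the reinforcement-learning criterion observer.

    The internal criterion starts neutral and moves toward the measurement
    after error trials only; correctness is scored from the emitted
    response, as in the experiment.
    """
    config = trials.config
    alpha = float(params.get("alpha", 0.2))
    n = len(trials)
    z = config.z_neutral
    response = np.empty(n)
    for t in range(n):
        x = trials.measurement[t]
        if task == "covert":
            choice = 1 if x < z else 0
            if rng.random() < lam:
                choice = int(rng.integers(0, 2))
            correct = choice == trials.category[t]
            response[t] = choice
        else:
            report = z + rng.normal(0.0, config.sigma_a)
            if rng.random() < lam:
                report = rng.uniform(-ORIENTATION_PERIOD / 2,
                                     ORIENTATION_PERIOD / 2)
            response[t] = report
            s = trials.stimulus[t]
            correct = (s < report) if trials.category[t] == 1 else (s > report)
        if not correct:
            z = z + alpha * (x - z)
    if task == "covert":
        response = response.astype(int)
    return response
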