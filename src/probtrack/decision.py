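"""Criterion setting and response models.

Maps a category-probability estimate to a decision criterion for two
equal-variance Gaussian categories, and gives the trial-level response
probabilities: the covert choice probability (Gaussian CDF of the
criterion-stimulus distance in sensory-noise units, mixed with a lapse) and
the overt report density (Gaussian adjustment noise around the model
criterion, mixed with a lapse uniform over the 180-degree orientation space).

Sign convention: category A lies clockwise (below) the criterion, so the
observer responds A whenever the measurement falls below the criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .task import ORIENTATION_PERIOD, TaskConfig

__all__ = [
    "CategoryModel",
    "optimal_criterion",
    "covert_choice_prob",
    "overt_report_logdensity",
]


@dataclass(frozen=True)
class CategoryModel:
    """Gaussian category pair plus the task's decision variance.

    The decision variance is the variance of the quantity the criterion is
    scored against: the noisy measurement in the covert task
    (``sigma_s^2 + sigma_v^2``) and the true stimulus in the overt task
    (``sigma_s^2``), switchable via ``overt_uses_sensory_noise``.
    """

    mu_A: float
    mu_B: float
    sigma_s: float
    sigma_v: float
    sigma_a: float = 16.0
    overt_uses_sensory_noise: bool = False

    def __post_init__(self) -> None:
        if self.mu_A >= self.mu_B:
            raise ValueError("internal convention requires mu_A < mu_B")
        if min(self.sigma_s, self.sigma_v, self.sigma_a) <= 0:
            raise ValueError("variances must be positive")

    @classmethod
    def from_config(cls, config: TaskConfig, **kwargs) -> "CategoryModel":
        return cls(config.mu_A, config.mu_B, config.sigma_s, config.sigma_v,
                   config.sigma_a, **kwargs)

    @property
    def z_neutral(self) -> float:
        return (self.mu_A + self.mu_B) / 2.0

    def decision_variance(self, task: str) -> float:
        if task == "covert" or self.overt_uses_sensory_noise:
            return self.sigma_s**2 + self.sigma_v**2
        return self.sigma_s**2


def optimal_criterion(pi_A, cat: CategoryModel, task: str = "covert"):
    """Criterion of posterior equality for category-A probability ``pi_A``.

    z = z_neutral + (sigma_dec^2 / (mu_B - mu_A)) * ln(pi_A / (1 - pi_A));
    the respond-A region is below z.  Accepts scalars or arrays.
    """
    pi_A = np.asarray(pi_A, dtype=float)
    if np.any(pi_A <= 0.0) or np.any(pi_A >= 1.0):
        raise ValueError("pi_A must lie strictly inside (0, 1)")
    gain = cat.decision_variance(task) / (cat.mu_B - cat.mu_A)
    z = cat.z_neutral + gain * np.log(pi_A / (1.0 - pi_A))
    return z if z.ndim else float(z)


def covert_choice_prob(stimulus, criterion, sigma_v: float, lapse: float):
    """Probability of responding A given the stimulus and the criterion.

    The measurement is Normal(stimulus, sigma_v^2) and the observer responds
    A when it falls below the criterion, so the choice probability is
    Phi((z - s) / sigma_v), mixed with a lapse: (1 - lambda) p + lambda / 2.
    """
    p = ndtr((np.asarray(criterion) - np.asarray(stimulus)) / sigma_v)
    return (1.0 - lapse) * p + lapse / 2.0


def overt_report_logdensity(reported, criterion, sigma_a: float, lapse: float):
    """Log density (per degree) of a reported criterion orientation.

    Mixture of a Gaussian centred on the model criterion (adjustment noise)
    and a lapse component uniform over one 180-degree period.
    """
    reported = np.asarray(reported, dtype=float)
    criterion = np.asarray(criterion, dtype=float)
    if lapse >= 1.0:  # pure-lapse limit: uniform over one period
        out = np.full(np.broadcast_shapes(reported.shape, criterion.shape),
                      -math.log(ORIENTATION_PERIOD))
        return out if out.ndim else float(out)
    resid = (reported - criterion) / sigma_a
    log_gauss = (
        -0.5 * resid**2 - math.log(sigma_a) - 0.5 * math.log(2.0 * math.pi)
    )
    log_lapse = math.log(lapse / ORIENTATION_PERIOD) if lapse > 0 else -np.inf
    out = np.logaddexp(np.log1p(-lapse) + log_gauss, log_lapse)
    return out if out.ndim else float(out)
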