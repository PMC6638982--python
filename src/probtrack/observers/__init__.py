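"""Observer model registry.

Every observer (except RL, whose criterion depends on latent measurements)
reduces to a mapping from the category-label history to a per-trial
probability estimate; the decision layer turns that estimate into a
criterion.  ``prob_trajectory`` dispatches on a model id:

``fixed, exp, exp_bias, wilson, behrens, behrens_bias,
bayes_ideal, bayes_r, bayes_pi, bayes_beta, bayes_rpb``
"""

from __future__ import annotations

import numpy as np

from ..task import TaskConfig
from .changepoint import (
    ChangepointBeliefSpec,
    JointBelief,
    belief_spec_for,
    conditional_state_posterior,
    hazard,
    predictive_category_prob,
    run_bayes_sequence,
    update_joint_belief,
)
from .heuristics import (
    BehrensGrid,
    ExpState,
    RLState,
    WilsonState,
    behrens_sequence,
    behrens_update,
    bias_blend,
    exp_sequence,
    exp_update,
    rl_update,
    wilson_sequence,
    wilson_update,
)

__all__ = [
    "MODEL_IDS", "BAYES_IDS", "prob_trajectory", "criterion_sequence",
    "ChangepointBeliefSpec", "JointBelief", "belief_spec_for",
    "conditional_state_posterior", "hazard", "predictive_category_prob",
    "run_bayes_sequence", "update_joint_belief",
    "BehrensGrid", "ExpState", "RLState", "WilsonState",
    "behrens_sequence", "behrens_update", "bias_blend", "exp_sequence",
    "exp_update", "rl_update", "wilson_sequence", "wilson_update",
]

BAYES_IDS = ("bayes_ideal", "bayes_r", "bayes_pi", "bayes_beta", "bayes_rpb")
MODEL_IDS = BAYES_IDS + (
    "fixed", "exp", "exp_bias", "wilson", "rl", "behrens", "behrens_bias",
)


def prob_trajectory(model_id: str, params: dict, labels,
                    config: TaskConfig) -> np.ndarray:
    """Pre-trial category-A probability estimates, length ``len(labels)``.

    Entry ``t`` is the estimate in force when trial ``t`` is presented,
    i.e. computed from ``labels[:t]`` only.
    """
    labels = np.asarray(labels, dtype=int)
    if model_id in BAYES_IDS:
        spec = belief_spec_for(model_id, params, config)
        return run_bayes_sequence(labels, spec)
    if model_id == "fixed":
        return np.full(len(labels), 0.5)
    if model_id == "exp":
        return exp_sequence(labels, float(params["alpha"]))
    if model_id == "exp_bias":
        return exp_sequence(labels, float(params["alpha"]),
                            float(params["w"]))
    if model_id == "wilson":
        l1 = 1.0
        l2 = l1 + float(params["delta1"])
        l3 = l2 + float(params["delta2"])
        return wilson_sequence(labels, (l1, l2, l3), float(params["nu_p"]),
                               hazard=float(params.get("hazard", 0.01)))
    if model_id == "behrens":
        return behrens_sequence(labels)
    if model_id == "behrens_bias":
        return behrens_sequence(labels, w=float(params["w"]))
    if model_id == "rl":
        raise ValueError("the RL observer has no label-only probability "
                         "trajectory; its criterion depends on measurements")
    raise KeyError(f"unknown model id {model_id!r}")


def criterion_sequence(model_id: str, params: dict, labels,
                       config: TaskConfig, task: str) -> np.ndarray:
    """Per-trial decision criteria implied by a model's estimates."""
    from ..decision import CategoryModel, optimal_criterion

    traj = prob_trajectory(model_id, params, labels, config)
    sigma_v = float(params.get("sigma_v", config.sigma_v))
    cat = CategoryModel(config.mu_A, config.mu_B, config.sigma_s, sigma_v,
                        config.sigma_a)
    traj = np.clip(traj, 1e-12, 1.0 - 1e-12)
    return optimal_criterion(traj, cat, task)
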