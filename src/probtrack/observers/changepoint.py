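"""Bayesian change-point detection observers.

The observer assumes the world follows the sample-and-hold generative model:
the category-A probability is drawn from a discrete state set, held for a
segment whose length is discrete-uniform on [L_min, L_max], and resampled at
each change point excluding the current state.  After each trial it updates
an exact joint posterior over the current run length ``r_t`` (labels seen
since the last change) and the state that governed the run *before* the last
change, ``xi_t``.  Conditioned on ``(r_t, xi_t)``, the labels of the current
run are a sufficient statistic for the current state, so the joint weight
table plus the label history carries the full posterior.

The filter is exact for this generative model (validated against exhaustive
enumeration over all segmentations in the test suite).  Within one trial the
update is: (i) weight each ``(r, xi)`` hypothesis by its predictive
probability of the new label; (ii) grow every run by one to absorb the
label; (iii) apply the hazard at the grown length, routing change mass to
``r = 0`` with the new "previous state" distributed as the posterior of the
run that just ended; (iv) renormalize.  A change after trial t therefore
leaves ``r_t = 0`` with an empty current run.

Belief variants differ only in the believed state set, run-length support and
the Beta(beta, beta) hyperprior reweighting applied to each fresh state draw:

=============  ==========================================================
bayes_ideal    veridical beliefs (states 0.2..0.8, L ~ Unif[80, 120])
bayes_r        L ~ Unif[floor(2r/3), r]; r = 120 reproduces the ideal
bayes_pi       5 states evenly spaced on [pi_min, 1 - pi_min]
bayes_beta     Beta(beta, beta) weighting of the state prior; beta = 1 ideal
bayes_rpb      L ~ Unif[r, r + dr], states on [pi_min, pi_max], beta free
=============  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..task import TaskConfig

__all__ = [
    "ChangepointBeliefSpec",
    "JointBelief",
    "hazard",
    "conditional_state_posterior",
    "update_joint_belief",
    "predictive_category_prob",
    "run_bayes_sequence",
    "belief_spec_for",
]


@dataclass(frozen=True)
class ChangepointBeliefSpec:
    """Believed generative model of a change-point observer."""

    state_set: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8)
    run_min: int = 80
    run_max: int = 120
    beta: float = 1.0
    variant: str = "bayes_ideal"

    def __post_init__(self) -> None:
        ss = tuple(float(p) for p in self.state_set)
        if len(ss) < 2 or sorted(set(ss)) != list(ss):
            raise ValueError("state_set must be sorted, distinct, length >= 2")
        if not all(0.0 < p < 1.0 for p in ss):
            raise ValueError("states must lie in (0, 1)")
        if self.run_min < 1 or self.run_min > self.run_max:
            raise ValueError("need 1 <= run_min <= run_max")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        object.__setattr__(self, "state_set", ss)


def belief_spec_for(model_id: str, params: dict,
                    config: TaskConfig) -> ChangepointBeliefSpec:
    """Bind a Bayesian variant's free parameters into a belief spec."""
    truth_states = tuple(config.state_set)
    run_min, run_max = config.run_min, config.run_max
    if model_id == "bayes_ideal":
        return ChangepointBeliefSpec(truth_states, run_min, run_max, 1.0,
                                     "bayes_ideal")
    if model_id == "bayes_r":
        r = int(round(params["r"]))
        return ChangepointBeliefSpec(truth_states, max(1, (2 * r) // 3), r,
                                     1.0, "bayes_r")
    if model_id == "bayes_pi":
        lo = float(params["pi_min"])
        states = tuple(np.linspace(lo, 1.0 - lo, 5))
        return ChangepointBeliefSpec(states, run_min, run_max, 1.0, "bayes_pi")
    if model_id == "bayes_beta":
        return ChangepointBeliefSpec(truth_states, run_min, run_max,
                                     float(params["beta"]), "bayes_beta")
    if model_id == "bayes_rpb":
        r = int(round(params["r"]))
        dr = int(round(params["dr"]))
        states = tuple(np.linspace(float(params["pi_min"]),
                                   float(params["pi_max"]), 5))
        return ChangepointBeliefSpec(states, r, r + dr,
                                     float(params["beta"]), "bayes_rpb")
    raise KeyError(f"unknown Bayesian variant {model_id!r}")


def hazard(run_length, spec: ChangepointBeliefSpec):
    """P(run ends at length r | it lasted r) under Unif[run_min, run_max].

    Zero below the support, 1/(run_max - r + 1) inside it, clamped to 1 at
    and above ``run_max`` (forced change keeps the weight table finite).
    """
    r = np.asarray(run_length, dtype=float)
    h = np.zeros_like(r)
    inside = (r >= spec.run_min) & (r < spec.run_max)
    h[inside] = 1.0 / (spec.run_max - r[inside] + 1.0)
    h[r >= spec.run_max] = 1.0
    return h if h.ndim else float(h)


class _FilterCore:
    """Precomputed tables shared by all filter entry points."""

    def __init__(self, spec: ChangepointBeliefSpec):
        self.spec = spec
        s = np.asarray(spec.state_set)
        self.states = s
        self.K = len(s)
        self.R = spec.run_max
        self.log_s = np.log(s)
        self.log_1ms = np.log1p(-s)
        # Beta(beta, beta) weighting of the discrete state set
        logw = (spec.beta - 1.0) * (self.log_s + self.log_1ms)
        logw -= logw.max()
        bw = np.exp(logw)
        # prior over fresh states given previous state xi (rows) with
        # exclusion; final row: no previous change yet (no exclusion)
        P0 = np.tile(bw, (self.K + 1, 1))
        np.fill_diagonal(P0[: self.K], 0.0)
        self.P0 = P0 / P0.sum(axis=1, keepdims=True)
        # hazard at run lengths 0..R+1
        self.h_all = hazard(np.arange(self.R + 2), spec)

    def state_posteriors(self, n_A, n_B):
        """Posterior over the current state for count vectors ``n_A, n_B``.

        Returns an array of shape ``(*counts, K+1, K)``: for each count row,
        the posterior under each previous-state hypothesis (last row: no
        change has yet occurred).
        """
        n_A = np.atleast_1d(np.asarray(n_A, dtype=float))
        n_B = np.atleast_1d(np.asarray(n_B, dtype=float))
        loglik = n_A[..., None] * self.log_s + n_B[..., None] * self.log_1ms
        loglik -= loglik.max(axis=-1, keepdims=True)
        lik = np.exp(loglik)
        un = self.P0[None, ...] * lik[..., None, :]
        return un / un.sum(axis=-1, keepdims=True)

    def step(self, W: np.ndarray, cum_A: np.ndarray, t: int, label: int):
        """One filtering update in place; returns the updated table.

        ``W`` is the (R+1, K+1) weight table after ``t`` labels; ``cum_A``
        holds cumulative A-counts with ``cum_A[t+1]`` already filled in for
        the new label.
        """
        R, K = self.R, self.K
        r_arr = np.arange(R + 1)
        # (i) observation: predictive probability of the new label
        n_A = cum_A[t] - cum_A[np.clip(t - r_arr, 0, t)]
        n_B = np.minimum(r_arr, t) - n_A
        post = self.state_posteriors(n_A, n_B)            # (R+1, K+1, K)
        e = post @ self.states                            # (R+1, K+1)
        W = W * (e if label == 1 else 1.0 - e)
        # (ii) grow runs by one, (iii) hazard at the grown length
        g = r_arr + 1
        n_A2 = cum_A[t + 1] - cum_A[np.clip(t + 1 - g, 0, t + 1)]
        n_B2 = np.minimum(g, t + 1) - n_A2
        post2 = self.state_posteriors(n_A2, n_B2)         # ending-run state
        hg = self.h_all[g]
        Wnew = np.zeros_like(W)
        Wnew[1:, :] = W[:-1, :] * (1.0 - hg[:-1, None])
        Wnew[0, :K] = np.einsum("rx,rxp->p", W * hg[:, None], post2)
        total = Wnew.sum()
        if not total > 0:
            raise FloatingPointError("belief weights underflowed to zero")
        return Wnew / total

    def predictive(self, W: np.ndarray, cum_A: np.ndarray, t: int) -> float:
        """P(next label = A | labels so far) = posterior mean state."""
        r_arr = np.arange(self.R + 1)
        n_A = cum_A[t] - cum_A[np.clip(t - r_arr, 0, t)]
        n_B = np.minimum(r_arr, t) - n_A
        post = self.state_posteriors(n_A, n_B)
        e = post @ self.states
        return float((W * e).sum() / W.sum())


@dataclass
class JointBelief:
    """Posterior over (run length, previous state) plus the label history.

    Row ``r`` of ``weights`` is the hypothesis that the current run holds the
    trailing ``r`` labels; column ``K`` (the last one) is the hypothesis that
    no change has occurred yet.
    """

    spec: ChangepointBeliefSpec
    weights: np.ndarray
    labels: list = field(default_factory=list)

    @classmethod
    def fresh(cls, spec: ChangepointBeliefSpec) -> "JointBelief":
        K = len(spec.state_set)
        W = np.zeros((spec.run_max + 1, K + 1))
        W[0, K] = 1.0  # empty run, no previous change
        return cls(spec, W, [])

    @property
    def _core(self) -> _FilterCore:
        core = getattr(self, "_core_cache", None)
        if core is None or core.spec is not self.spec:
            core = _FilterCore(self.spec)
            object.__setattr__(self, "_core_cache", core)
        return core

    def _cum_A(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.labels)]).astype(int)


def conditional_state_posterior(run_counts, xi, spec: ChangepointBeliefSpec):
    """Posterior over the current state given run counts and previous state.

    ``P(pi | r, xi, C) ~ Beta(pi; beta, beta) 1[pi != xi] pi^nA (1-pi)^nB``
    normalized over the believed state set.  ``xi=None`` means no change has
    occurred yet (no exclusion).
    """
    n_A, n_B = run_counts
    if n_A < 0 or n_B < 0:
        raise ValueError("counts must be nonnegative")
    core = _FilterCore(spec)
    if xi is None:
        row = core.K
    else:
        matches = np.nonzero(np.isclose(core.states, xi))[0]
        if len(matches) == 0:
            raise ValueError(f"xi={xi} not in believed state set")
        row = int(matches[0])
    return core.state_posteriors(n_A, n_B)[0, row]


def update_joint_belief(belief: JointBelief, new_label,
                        spec: ChangepointBeliefSpec | None = None) -> JointBelief:
    """Absorb one category label (1 = A, 0 = B) into the joint belief."""
    spec = spec or belief.spec
    label = int(new_label)
    if label not in (0, 1):
        raise ValueError("labels must be 0 (category B) or 1 (category A)")
    core = belief._core
    labels = belief.labels + [label]
    cum_A = np.concatenate([[0], np.cumsum(labels)]).astype(int)
    t = len(belief.labels)
    W = core.step(belief.weights.copy(), cum_A, t, label)
    return JointBelief(spec, W, labels)


def predictive_category_prob(belief: JointBelief,
                             spec: ChangepointBeliefSpec | None = None) -> float:
    """P(C_{t+1} = A | C_1:t): expected current state under the belief."""
    core = belief._core
    return core.predictive(belief.weights, belief._cum_A(), len(belief.labels))


def run_bayes_sequence(labels, spec: ChangepointBeliefSpec) -> np.ndarray:
    """Pre-trial predictive probabilities P(C_t = A | C_1:t-1) for t = 1..T.

    Entry ``t`` is the probability assigned to category A before trial ``t``
    is observed; entry 0 is the prior mean of the believed state set.
    """
    labels = np.asarray(labels, dtype=int)
    T = len(labels)
    out = np.empty(T)
    if T == 0:
        return out
    core = _FilterCore(spec)
    K, R = core.K, core.R
    W = np.zeros((R + 1, K + 1))
    W[0, K] = 1.0
    cum_A = np.zeros(T + 1, dtype=int)
    np.cumsum(labels, out=cum_A[1:])
    r_arr = np.arange(R + 1)
    g = r_arr + 1
    hg = core.h_all[g]
    # current-state posterior per (r, xi); the ending-run table computed in
    # the hazard step doubles as next trial's table shifted by one run length
    post = np.broadcast_to(core.P0, (R + 1, K + 1, K)).copy()
    for t in range(T):
        e = post @ core.states
        out[t] = (W * e).sum()
        W = W * (e if labels[t] == 1 else 1.0 - e)
        n_A2 = cum_A[t + 1] - cum_A[np.clip(t + 1 - g, 0, t + 1)]
        n_B2 = np.minimum(g, t + 1) - n_A2
        post2 = core.state_posteriors(n_A2, n_B2)
        Wnew = np.zeros_like(W)
        Wnew[1:, :] = W[:-1, :] * (1.0 - hg[:-1, None])
        Wnew[0, :K] = np.einsum("rx,rxp->p", W * hg[:, None], post2)
        W = Wnew / Wnew.sum()
        post[1:] = post2[:-1]
        post[0] = core.P0
    return out
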