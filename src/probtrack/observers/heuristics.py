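"""Heuristic (non-change-point) probability and criterion learners.

Fixed         criterion pinned to neutral (assumes equal probability).
Exp           exponential averaging of category labels (delta rule).
Exp_bias      Exp estimate shrunk toward 0.5 by a conservatism weight w.
Wilson        three-node mixture of delta rules approximating the run-length
              posterior (nodes l1 < l2 < l3, prior strength nu_p, hazard h).
RL            criterion moved toward the measurement after errors only.
Behrens       grid-based Bayesian learner over (probability, volatility,
              volatility rate of change), with an optional bias blend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import beta as beta_dist

__all__ = [
    "ExpState", "exp_update", "bias_blend", "exp_sequence",
    "WilsonState", "wilson_update", "wilson_sequence",
    "RLState", "rl_update",
    "BehrensGrid", "behrens_update", "behrens_sequence",
]


# ---------------------------------------------------------------- Exp family

@dataclass(frozen=True)
class ExpState:
    """Exponential-averaging estimator state.

    ``tau = -1 / log(1 - alpha)`` is the memory time constant in trials.
    """

    alpha: float
    estimate: float = 0.5
    w: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.estimate <= 1.0:
            raise ValueError("estimate must be in [0, 1]")

    @property
    def tau(self) -> float:
        return -1.0 / np.log1p(-self.alpha)

    @property
    def biased_estimate(self) -> float:
        return bias_blend(self.estimate, self.w)


def exp_update(state: ExpState, label: int) -> ExpState:
    """Delta-rule update: estimate += alpha * (label - estimate)."""
    est = state.estimate + state.alpha * (int(label) - state.estimate)
    return replace(state, estimate=est)


def bias_blend(estimate, w):
    """Conservatism: blend an estimate with the equal-probability prior.

    ``pi_tilde = w * pi_hat + (1 - w) / 2``; w = 1 is no bias, w = 0 pins the
    effective estimate at 0.5.
    """
    return w * np.asarray(estimate) + (1.0 - w) / 2.0


def exp_sequence(labels, alpha: float, w: float = 1.0) -> np.ndarray:
    """Pre-trial biased estimates pi_tilde_A for t = 1..T (entry 0 = 0.5)."""
    labels = np.asarray(labels, dtype=float)
    out = np.empty(len(labels))
    est = 0.5
    for t in range(len(labels)):
        out[t] = est
        est += alpha * (labels[t] - est)
    return bias_blend(out, w)


def exp_sequence_grid(labels, alphas, ws) -> np.ndarray:
    """Vectorised ``exp_sequence`` over a grid of (alpha, w) pairs.

    ``alphas`` and ``ws`` are broadcast-compatible arrays; returns an array
    of shape ``(*grid_shape, T)`` of pre-trial biased estimates.
    """
    labels = np.asarray(labels, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    ws = np.asarray(ws, dtype=float)
    shape = np.broadcast_shapes(alphas.shape, ws.shape)
    est = np.full(shape, 0.5)
    out = np.empty(shape + (len(labels),))
    for t in range(len(labels)):
        out[..., t] = est
        est = est + alphas * (labels[t] - est)
    return ws[..., None] * out + (1.0 - ws[..., None]) / 2.0


# -------------------------------------------------------------------- Wilson

@dataclass(frozen=True)
class WilsonState:
    """Mixture-of-delta-rules state (Wilson et al. 2013 reduced model).

    Each node ``l_i`` runs a delta rule with learning rate ``1/(l_i + nu_p)``;
    node weights approximate the posterior over run lengths, with hazard mass
    routed to the fastest node ``l1`` and growth mass split between adjacent
    nodes so the represented mean run length advances by one per trial.
    """

    nodes: tuple[float, ...] = (1.0, 13.0, 119.0)
    nu_p: float = 2.0
    hazard: float = 0.01
    estimates: tuple[float, ...] | None = None
    node_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        nodes = tuple(float(l) for l in self.nodes)
        if sorted(nodes) != list(nodes) or len(set(nodes)) != len(nodes):
            raise ValueError("nodes must be strictly increasing")
        if self.nu_p < 0:
            raise ValueError("nu_p must be nonnegative")
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard must be in [0, 1]")
        object.__setattr__(self, "nodes", nodes)
        if self.estimates is None:
            object.__setattr__(self, "estimates", (0.5,) * len(nodes))
        if self.node_weights is None:
            w = np.zeros(len(nodes))
            w[0] = 1.0  # a change is assumed to occur at t = 1
            object.__setattr__(self, "node_weights", tuple(w))
        wsum = sum(self.node_weights)
        if abs(wsum - 1.0) > 1e-9 or min(self.node_weights) < -1e-12:
            raise ValueError("node weights must form a simplex")

    @property
    def learning_rates(self) -> np.ndarray:
        return 1.0 / (np.asarray(self.nodes) + self.nu_p)

    @property
    def estimate(self) -> float:
        return float(np.dot(self.node_weights, self.estimates))


def _wilson_growth_matrix(nodes: np.ndarray) -> np.ndarray:
    """Column-stochastic growth matrix G with mean-preserving splitting.

    Node i keeps ``1 - 1/(l_{i+1} - l_i)`` of its mass and passes the rest to
    node i+1, so the represented run-length mean advances by exactly one
    trial; the top node maps to itself.
    """
    n = len(nodes)
    G = np.zeros((n, n))
    for i in range(n):
        if i == n - 1:
            G[i, i] = 1.0
        else:
            frac = 1.0 / (nodes[i + 1] - nodes[i])
            G[i, i] = 1.0 - frac
            G[i + 1, i] = frac
    return G


def wilson_update(state: WilsonState, label: int) -> WilsonState:
    """One trial of the Wilson et al. mixture-of-delta-rules model.

    Node weights are likelihood-weighted by each node's predictive
    probability of the label, hazard mass is routed to l1 and growth mass
    spread between adjacent nodes; then every node's estimate takes its
    delta-rule step.
    """
    label = int(label)
    w = np.asarray(state.node_weights)
    est = np.asarray(state.estimates)
    pred = est if label == 1 else 1.0 - est
    w = w * pred
    w = w / w.sum()
    G = _wilson_growth_matrix(np.asarray(state.nodes))
    w = (1.0 - state.hazard) * (G @ w)
    w[0] += state.hazard
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    est = est + state.learning_rates * (label - est)
    return replace(state, estimates=tuple(est), node_weights=tuple(w))


def wilson_sequence(labels, nodes=(1.0, 13.0, 119.0), nu_p: float = 2.0,
                    hazard: float = 0.01) -> np.ndarray:
    """Pre-trial overall estimates of the Wilson model for t = 1..T."""
    labels = np.asarray(labels, dtype=int)
    nodes = np.asarray(nodes, dtype=float)
    rates = 1.0 / (nodes + nu_p)
    G = _wilson_growth_matrix(nodes)
    w = np.zeros(len(nodes))
    w[0] = 1.0
    est = np.full(len(nodes), 0.5)
    out = np.empty(len(labels))
    for t, label in enumerate(labels):
        out[t] = w @ est
        pred = est if label == 1 else 1.0 - est
        w = w * pred
        w /= w.sum()
        w = (1.0 - hazard) * (G @ w)
        w[0] += hazard
        w /= w.sum()
        est = est + rates * (label - est)
    return out


def wilson_sequence_grid(labels, nodes, nu_p, hazard: float = 0.01) -> np.ndarray:
    """Vectorised ``wilson_sequence`` over N parameter combinations.

    ``nodes``: (N, 3) strictly increasing node run lengths; ``nu_p``: (N,).
    Returns (N, T) pre-trial overall estimates.
    """
    labels = np.asarray(labels, dtype=int)
    nodes = np.asarray(nodes, dtype=float)
    nu_p = np.asarray(nu_p, dtype=float)
    N, n_nodes = nodes.shape
    rates = 1.0 / (nodes + nu_p[:, None])
    frac = 1.0 / np.diff(nodes, axis=1)          # (N, n_nodes-1)
    w = np.zeros((N, n_nodes))
    w[:, 0] = 1.0
    est = np.full((N, n_nodes), 0.5)
    out = np.empty((N, len(labels)))
    for t, label in enumerate(labels):
        out[:, t] = np.einsum("ij,ij->i", w, est)
        pred = est if label == 1 else 1.0 - est
        w = w * pred
        w /= w.sum(axis=1, keepdims=True)
        moved = w[:, :-1] * frac
        w2 = w.copy()
        w2[:, :-1] -= moved
        w2[:, 1:] += moved
        w = (1.0 - hazard) * w2
        w[:, 0] += hazard
        w /= w.sum(axis=1, keepdims=True)
        est = est + rates * (label - est)
    return out


# ------------------------------------------------------------------------ RL

@dataclass(frozen=True)
class RLState:
    """Reinforcement-learning criterion state (degrees)."""

    criterion: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def rl_update(state: RLState, measurement: float,
              feedback_correct: bool) -> RLState:
    """Criterion unchanged when correct; moved toward the measurement when
    incorrect: z += alpha * (x - z)."""
    if feedback_correct:
        return state
    z = state.criterion + state.alpha * (measurement - state.criterion)
    return replace(state, criterion=z)


# ------------------------------------------------------------------- Behrens

@dataclass
class BehrensGrid:
    """Joint grid density over (probability pi, volatility v, rate k).

    ``v = log`` concentration of the Beta transition on pi, ``k = log``
    variance of the Gaussian random walk on v.  Bin ranges follow positive
    parameters of unknown scale: pi linear, exp(v) and exp(k) log-spaced.
    """

    n_bins: int = 30
    pi_range: tuple[float, float] = (0.01, 0.99)
    conc_range: tuple[float, float] = (2.0, 1e4)
    diff_range: tuple[float, float] = (1e-4, 10.0)
    density: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.n_bins
        self.pi_grid = np.linspace(*self.pi_range, n)
        self.v_grid = np.linspace(*np.log(self.conc_range), n)
        self.k_grid = np.linspace(*np.log(self.diff_range), n)
        if self.density is None:
            self.density = np.full((n, n, n), 1.0 / n**3)
        self._v_kernels = self._volatility_kernels()
        self._pi_kernels = self._probability_kernels()

    def _volatility_kernels(self) -> np.ndarray:
        """T[k, v, v'] = P(v' | v, k), Gaussian with variance exp(k),
        column-normalised on the v grid."""
        v = self.v_grid
        dv2 = (v[None, :, None] - v[None, None, :]) ** 2
        var = np.exp(self.k_grid)[:, None, None]
        T = np.exp(-0.5 * dv2 / var)
        return T / T.sum(axis=2, keepdims=True)

    def _probability_kernels(self) -> np.ndarray:
        """T[v', pi, pi'] = P(pi' | pi, v'), Beta with mean pi and
        concentration exp(v'), normalised on the pi grid."""
        pi = self.pi_grid
        conc = np.exp(self.v_grid)
        a = pi[None, :, None] * conc[:, None, None]
        b = (1.0 - pi[None, :, None]) * conc[:, None, None]
        logpdf = beta_dist.logpdf(pi[None, None, :], a, b)
        logpdf -= logpdf.max(axis=2, keepdims=True)
        T = np.exp(logpdf)
        return T / T.sum(axis=2, keepdims=True)

    @property
    def pi_marginal(self) -> np.ndarray:
        return self.density.sum(axis=(1, 2))

    @property
    def estimate(self) -> float:
        """Mean of the probability marginal."""
        return float(self.pi_marginal @ self.pi_grid)


def behrens_update(grid: BehrensGrid, label: int) -> BehrensGrid:
    """One trial of the volatility learner.

    Propagates volatility by its Gaussian random walk, then probability by
    the Beta transition with concentration exp(v'), multiplies in the
    Bernoulli likelihood of the label and renormalizes.  The nested
    five-dimensional integral factorises into these two sequential 1-D
    convolutions on the grid.
    """
    label = int(label)
    p = grid.density
    # v -> v' per k slice: p[pi, v, k] * T[k, v, v'] summed over v
    p = np.einsum("pvk,kvw->pwk", p, grid._v_kernels)
    # pi -> pi' per v' slice
    p = np.einsum("pwk,wpq->qwk", p, grid._pi_kernels)
    lik = grid.pi_grid if label == 1 else 1.0 - grid.pi_grid
    p = p * lik[:, None, None]
    total = p.sum()
    if not total > 0:
        raise FloatingPointError("Behrens grid mass underflowed")
    new = BehrensGrid(grid.n_bins, grid.pi_range, grid.conc_range,
                      grid.diff_range, density=p / total)
    return new


def behrens_sequence(labels, w: float = 1.0, n_bins: int = 30,
                     **grid_kwargs) -> np.ndarray:
    """Pre-trial (optionally bias-blended) estimates for t = 1..T."""
    labels = np.asarray(labels, dtype=int)
    grid = BehrensGrid(n_bins=n_bins, **grid_kwargs)
    pi = grid.pi_grid
    vk, pk = grid._v_kernels, grid._pi_kernels
    p = grid.density
    out = np.empty(len(labels))
    for t, label in enumerate(labels):
        out[t] = p.sum(axis=(1, 2)) @ pi
        p = np.einsum("pvk,kvw->pwk", p, vk)
        p = np.einsum("pwk,wpq->qwk", p, pk)
        p = p * (pi if label == 1 else 1.0 - pi)[:, None, None]
        p /= p.sum()
    return bias_blend(out, w)
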