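"""Independent brute-force oracles used by the test suite.

``enumerate_joint_posterior`` computes the exact posterior over (run length,
previous state) for the sample-and-hold generative model by summing over
*all* change-point configurations and state assignments — exponential-time,
usable only for tiny problems, and deliberately independent of the filtering
recursion it validates.
"""

from __future__ import annotations

import numpy as np


def enumerate_joint_posterior(labels, spec):
    """Exact P(r_T, xi_T | C_1:T) for a small change-point problem.

    Returns a dict mapping ``(r, xi_index_or_None)`` to probability, where
    ``xi_index`` indexes ``spec.state_set`` and ``None`` marks the
    hypothesis that no change has occurred yet.
    """
    labels = list(int(l) for l in labels)
    T = len(labels)
    S = np.asarray(spec.state_set)
    K = len(S)
    Lmin, Lmax = spec.run_min, spec.run_max
    span = Lmax - Lmin + 1

    bw = (S * (1 - S)) ** (spec.beta - 1.0)

    def state_prior(prev):
        w = bw.copy()
        if prev is not None:
            w[prev] = 0.0
        return w / w.sum()

    def p_len(length):          # completed segment
        return 1.0 / span if Lmin <= length <= Lmax else 0.0

    def p_len_gt(m):            # ongoing segment survived m trials
        return max(0, Lmax - max(m, Lmin - 1)) / span

    # all change-time configurations (changes strictly after trials 1..T)
    configs: list[list[int]] = []

    def build(pos, times):
        configs.append(list(times))
        for length in range(Lmin, Lmax + 1):
            if pos + length <= T:
                build(pos + length, times + [pos + length])

    build(0, [])

    out: dict = {}
    total = 0.0
    for times in configs:
        prev_end = times[-1] if times else 0
        m = T - prev_end
        p_cfg = 1.0
        start = 0
        for c in times:
            p_cfg *= p_len(c - start)
            start = c
        if m > 0:
            p_cfg *= p_len_gt(m)
        if p_cfg == 0.0:
            continue
        k = len(times)
        # sum over state sequences rho_0 .. rho_k with exclusion
        assignment = [0] * (k + 1)

        def states_rec(i, prev_idx, weight):
            if i == k + 1:
                yield list(assignment), weight
                return
            pri = state_prior(prev_idx)
            for j in range(K):
                if pri[j] > 0.0:
                    assignment[i] = j
                    yield from states_rec(i + 1, j, weight * pri[j])

        bounds = [0] + times + [T]
        for assign, w in states_rec(0, None, 1.0):
            lik = 1.0
            for seg in range(k + 1):
                pi = S[assign[seg]]
                for t in range(bounds[seg], bounds[seg + 1]):
                    lik *= pi if labels[t] == 1 else 1.0 - pi
            joint = p_cfg * w * lik
            r_T = T - prev_end
            xi = assign[k - 1] if k >= 1 else None
            out[(r_T, xi)] = out.get((r_T, xi), 0.0) + joint
            total += joint
    return {key: v / total for key, v in out.items()}


def joint_table_from_dict(post: dict, spec) -> np.ndarray:
    """Arrange the enumeration output as an (R+1, K+1) weight table."""
    K = len(spec.state_set)
    table = np.zeros((spec.run_max + 1, K + 1))
    for (r, xi), p in post.items():
        table[r, K if xi is None else xi] = p
    return table
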