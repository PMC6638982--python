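"""Change-point observer: hazard, conditional posterior, exact filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import enumerate_joint_posterior, joint_table_from_dict
from probtrack import ChangepointBeliefSpec, JointBelief
from probtrack.observers import (
    belief_spec_for,
    conditional_state_posterior,
    hazard,
    predictive_category_prob,
    run_bayes_sequence,
    update_joint_belief,
)

SMALL_SPEC = ChangepointBeliefSpec(state_set=(0.2, 0.5, 0.8), run_min=2,
                                   run_max=4)


class TestHazard:
    @pytest.mark.parametrize("r,expected", [
        (79, 0.0),          # below the believed support
        (80, 1.0 / 41.0),   # 1 / #{80..120}
        (100, 1.0 / 21.0),
        (120, 1.0),         # forced change at the max run length
        (150, 1.0),         # clamped above the support
    ])
    def test_uniform_support(self, r, expected):
        spec = ChangepointBeliefSpec()
        assert hazard(r, spec) == pytest.approx(expected)

    def test_vectorized(self):
        spec = ChangepointBeliefSpec()
        h = hazard(np.arange(130), spec)
        assert np.all(h[:80] == 0) and h[-1] == 1.0
        assert np.all(np.diff(h[80:121]) > 0)  # hazard grows toward the max


class TestConditionalStatePosterior:
    def test_flat_prior_no_data(self):
        spec = ChangepointBeliefSpec()
        post = conditional_state_posterior((0, 0), 0.5, spec)
        # uniform over the four states that differ from xi = 0.5
        expected = np.array([0.25, 0.25, 0.0, 0.25, 0.25])
        assert np.allclose(post, expected)

    def test_two_a_labels(self):
        spec = ChangepointBeliefSpec()
        post = conditional_state_posterior((2, 0), 0.5, spec)
        # weights proportional to pi^2 over {0.2, 0.35, 0.65, 0.8}
        assert post[4] == pytest.approx(0.64 / 1.225)
        assert post[2] == 0.0

    def test_large_beta_concentrates_near_half(self):
        spec = ChangepointBeliefSpec(beta=50.0)
        post = conditional_state_posterior((0, 0), 0.2, spec)
        states = np.asarray(spec.state_set)
        # mass ordered by closeness to 0.5 among the allowed states
        allowed = states != 0.2
        best = np.argmin(np.abs(states[allowed] - 0.5))
        assert np.argmax(post[allowed]) == best
        assert post[allowed][best] > 0.9

    def test_xi_not_in_state_set(self):
        with pytest.raises(ValueError):
            conditional_state_posterior((0, 0), 0.3, ChangepointBeliefSpec())


class TestFilterExactness:
    """The filter must agree with exhaustive enumeration over segmentations."""

    @pytest.mark.parametrize("beta", [1.0, 3.0])
    @pytest.mark.parametrize("label_seed", [1, 2])
    def test_matches_enumeration(self, beta, label_seed):
        spec = ChangepointBeliefSpec(state_set=(0.2, 0.5, 0.8), run_min=2,
                                     run_max=4, beta=beta)
        rng = np.random.default_rng(label_seed)
        labels = (rng.random(10) < 0.6).astype(int)
        belief = JointBelief.fresh(spec)
        for lab in labels:
            belief = update_joint_belief(belief, int(lab))
        exact = joint_table_from_dict(
            enumerate_joint_posterior(labels, spec), spec)
        assert np.abs(belief.weights - exact).max() < 1e-10

    def test_hazard_free_run_length_is_deterministic(self):
        spec = ChangepointBeliefSpec(state_set=(0.3, 0.7), run_min=50,
                                     run_max=60)
        belief = JointBelief.fresh(spec)
        for t, lab in enumerate([1, 0, 1, 1, 0], start=1):
            belief = update_joint_belief(belief, lab)
            nz = np.nonzero(belief.weights)
            assert list(np.unique(nz[0])) == [t]

    def test_weights_normalized_after_every_update(self):
        belief = JointBelief.fresh(SMALL_SPEC)
        rng = np.random.default_rng(0)
        for lab in (rng.random(30) < 0.5).astype(int):
            belief = update_joint_belief(belief, int(lab))
            assert belief.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(belief.weights >= 0)


class TestPredictive:
    def test_fresh_belief_is_half(self):
        assert predictive_category_prob(
            JointBelief.fresh(ChangepointBeliefSpec())) == pytest.approx(0.5)

    def test_all_weight_on_neutral_previous_state(self):
        spec = ChangepointBeliefSpec()
        belief = JointBelief.fresh(spec)
        W = np.zeros_like(belief.weights)
        W[0, 2] = 1.0  # (r=0, xi=0.5): remaining states average to 0.5
        belief.weights = W
        assert predictive_category_prob(belief) == pytest.approx(0.5)

    def test_long_a_run_converges_to_top_state(self, config):
        spec = belief_spec_for("bayes_ideal", {}, config)
        traj = run_bayes_sequence(np.ones(200, dtype=int), spec)
        # within the first run window (no change point possible before
        # trial 80) the posterior concentrates on the largest state
        assert traj[79] > 0.799
        # once a change is forced, the exclusion rule bars an immediate
        # return to 0.8, so the predictive dips (to ~0.51 right at the
        # forced change) and then re-concentrates without reaching 0.8
        assert np.all(traj[80:] > 0.5)
        assert 0.6 < traj[-1] < 0.8

    def test_predictive_bounded_by_state_set(self, labels_800, config):
        spec = belief_spec_for("bayes_ideal", {}, config)
        traj = run_bayes_sequence(labels_800, spec)
        assert np.all(traj >= min(spec.state_set) - 1e-12)
        assert np.all(traj <= max(spec.state_set) + 1e-12)


class TestReductionIdentities:
    def test_variants_reduce_to_ideal(self, labels_800, config):
        ideal = run_bayes_sequence(labels_800,
                                   belief_spec_for("bayes_ideal", {}, config))
        for model, params in [("bayes_r", {"r": 120}),
                              ("bayes_pi", {"pi_min": 0.2}),
                              ("bayes_beta", {"beta": 1.0})]:
            spec = belief_spec_for(model, params, config)
            traj = run_bayes_sequence(labels_800, spec)
            assert np.allclose(traj, ideal, atol=1e-12), model

    def test_rpb_binding(self, config):
        spec = belief_spec_for(
            "bayes_rpb",
            {"r": 80, "dr": 40, "pi_min": 0.2, "pi_max": 0.8, "beta": 1.0},
            config)
        assert (spec.run_min, spec.run_max) == (80, 120)
        assert spec.state_set == pytest.approx((0.2, 0.35, 0.5, 0.65, 0.8))


class TestCountSufficiency:
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=8),
           st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_label_permutation_in_hazard_free_window(self, labels, rnd):
        # with no possible change point, only label counts matter
        spec = ChangepointBeliefSpec(state_set=(0.3, 0.7), run_min=50,
                                     run_max=60)
        shuffled = list(labels)
        rnd.shuffle(shuffled)
        a = run_bayes_sequence(labels, spec)
        b = run_bayes_sequence(shuffled, spec)
        # compare the *post-window* predictive by appending a probe label
        a_end = run_bayes_sequence(labels + [1], spec)[-1]
        b_end = run_bayes_sequence(shuffled + [1], spec)[-1]
        assert a_end == pytest.approx(b_end, abs=1e-12)
        assert a[0] == b[0] == pytest.approx(0.5)
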