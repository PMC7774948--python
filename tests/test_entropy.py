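"""Binning, state assignment, transition model and conditional entropy."""

from dataclasses import replace

import numpy as np
import pytest

import gazescan as gs
from gazescan.entropy import INVALID_STATE, _xlogx

from conftest import make_trace


def entropy_of(states, mode="standard"):
    return gs.conditional_entropy(gs.transition_model(states), mode=mode)


class TestBinSeries:
    def test_bin_count_full_session(self):
        n = 390 * 120
        trace = make_trace("eye", "head_frame", np.zeros(n), np.zeros(n))
        bins = gs.bin_series(trace, bin_ms=120.0)
        assert len(bins) == 3250  # 390 s / 0.120 s

    def test_trailing_partial_bin_dropped(self):
        trace = make_trace("eye", "head_frame", np.zeros(20), np.zeros(20))
        # 20 samples at 120 Hz cover 1/6 s: one 120 ms bin plus a remainder
        assert len(gs.bin_series(trace, bin_ms=120.0)) == 1

    def test_net_displacement_is_euclidean_first_to_last(self):
        yaw = np.array([0.0] + [50.0] * 13 + [3.0])
        pitch = np.array([0.0] + [-50.0] * 13 + [4.0])
        trace = make_trace("eye", "head_frame", yaw, pitch)
        bins = gs.bin_series(trace, bin_ms=120.0)
        # first sample (0, 0), last valid sample in bin (3, 4): 3-4-5 triangle,
        # regardless of the wild excursion in between (net, not arc length)
        assert bins.displacement[0] == pytest.approx(5.0, abs=1e-12)

    def test_displacement_uses_valid_samples_only(self):
        yaw = np.array([99.0] + [1.0] * 13 + [6.0])
        valid = np.ones(15, dtype=bool)
        valid[0] = False  # the outlier is flagged invalid
        trace = make_trace("eye", "head_frame", yaw, np.zeros(15), valid=valid)
        bins = gs.bin_series(trace, bin_ms=120.0)
        # first *valid* sample has yaw 1, last has yaw 6
        assert bins.displacement[0] == pytest.approx(5.0, abs=1e-12)

    def test_mostly_invalid_bin_flagged(self):
        valid = np.ones(30, dtype=bool)
        valid[0:10] = False  # 10 of the first bin's 15 samples invalid
        trace = make_trace("eye", "head_frame", np.zeros(30), np.zeros(30), valid=valid)
        bins = gs.bin_series(trace, bin_ms=120.0)
        assert not bins.valid[0]
        assert bins.valid[1]

    def test_bad_bin_width_rejected(self):
        trace = make_trace("eye", "head_frame", [0.0], [0.0])
        with pytest.raises(ValueError):
            gs.bin_series(trace, bin_ms=0.0)


class TestStatePolicies:
    def bins(self, disps, valid=None):
        disps = np.asarray(disps, dtype=float)
        if valid is None:
            valid = np.ones(disps.size, dtype=bool)
        return gs.BinSeries(120.0, np.arange(disps.size) * 0.12, disps, valid)

    def test_threshold_shift_stay(self):
        b = self.bins([0.0, 0.5, 1.0, 1.01, 30.0])
        states = gs.assign_states(b, gs.DisplacementThreshold(theta=1.0))
        # strictly-greater-than threshold: 1.0 deg itself is a stay
        assert list(states) == [0, 0, 0, 1, 1]

    def test_invalid_bins_get_sentinel(self):
        b = self.bins([0.0, 5.0, 0.0], valid=np.array([True, False, True]))
        states = gs.assign_states(b, gs.DisplacementThreshold())
        assert states[1] == INVALID_STATE

    def test_quantile_states_balanced(self):
        rng = np.random.default_rng(0)
        b = self.bins(rng.exponential(size=9000))
        states = gs.assign_states(b, gs.DisplacementQuantiles(k=3))
        _, counts = np.unique(states, return_counts=True)
        assert counts.size == 3
        assert counts.max() - counts.min() <= 2

    def test_quantile_tie_goes_to_lower_state(self):
        b = self.bins([1.0, 1.0, 1.0, 2.0])
        states = gs.assign_states(b, gs.DisplacementQuantiles(k=2))
        # the median is 1.0; values equal to the edge stay in the lower state
        assert list(states) == [0, 0, 0, 1]

    def test_quantile_k_validation(self):
        with pytest.raises(ValueError):
            gs.assign_states(self.bins([1.0, 2.0]), gs.DisplacementQuantiles(k=1))

    def test_aoi_policy_requires_labels(self):
        with pytest.raises(ValueError, match="gaze"):
            gs.assign_states(self.bins([0.0, 1.0]), gs.AoiLabels())


class TestTransitionModel:
    def test_hand_counted_example(self):
        """A,B,A,B,A -> 4 pairs: A->B twice, B->A twice."""
        m = gs.transition_model([0, 1, 0, 1, 0])
        assert m.n_pairs == 4
        assert m.counts.tolist() == [[0, 2], [2, 0]]
        assert np.allclose(m.p_joint, [[0, 0.5], [0.5, 0]])
        assert np.allclose(m.p_i, [0.5, 0.5])
        assert np.allclose(m.p_cond, [[0, 1], [1, 0]])

    def test_marginal_and_row_invariants(self):
        rng = np.random.default_rng(3)
        m = gs.transition_model(rng.integers(0, 4, size=500))
        assert m.p_joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert m.p_i.sum() == pytest.approx(1.0, abs=1e-12)
        rows = m.p_cond.sum(axis=1)
        assert np.all((np.abs(rows - 1) < 1e-12) | (rows == 0))

    def test_pairs_spanning_invalid_bins_dropped(self):
        m = gs.transition_model([0, INVALID_STATE, 1, 1])
        # only the (1, 1) pair survives; 0 is never part of a valid pair
        assert m.n_pairs == 1
        assert m.states.tolist() == [1]

    def test_too_few_valid_bins_rejected(self):
        with pytest.raises(ValueError):
            gs.transition_model([0, INVALID_STATE, 1])


class TestConditionalEntropy:
    def test_deterministic_alternation_is_zero(self):
        r = entropy_of([0, 1] * 200)
        assert r.raw_bits == pytest.approx(0.0, abs=1e-12)
        assert r.normalized == 0.0

    def test_constant_sequence_is_zero(self):
        r = entropy_of([0] * 100)
        assert r.n_states == 1
        assert r.normalized == 0.0

    def test_iid_uniform_approaches_one(self):
        rng = np.random.default_rng(11)
        r = entropy_of(rng.integers(0, 2, size=200_000))
        assert r.normalized == pytest.approx(1.0, abs=0.001)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.integers(0, 3, size=2000)
        relabeled = np.array([7, 2, 5])[s]
        for mode in ("standard", "literal"):
            assert entropy_of(s, mode).raw_bits == pytest.approx(
                entropy_of(relabeled, mode).raw_bits, abs=1e-12
            )

    def test_conditional_not_above_stationary_entropy(self):
        """Conditioning never increases entropy: H(X_t+1 | X_t) <= H(pi)."""
        rng = np.random.default_rng(9)
        # a sticky chain, far from iid
        s = [0]
        for _ in range(5000):
            s.append(s[-1] if rng.random() < 0.8 else rng.integers(0, 3))
        m = gs.transition_model(s)
        h_cond = gs.conditional_entropy(m).raw_bits
        h_marg = float(-_xlogx(m.p_i).sum())
        assert h_cond <= h_marg + 1e-12

    def test_literal_mode_differs_and_uses_joint(self):
        rng = np.random.default_rng(2)
        s = rng.integers(0, 2, size=5000)
        m = gs.transition_model(s)
        lit = gs.conditional_entropy(m, mode="literal").raw_bits
        oracle = float(-np.sum(m.p_i[:, None] * _xlogx(m.p_joint)))
        assert lit == pytest.approx(oracle, abs=1e-12)
        assert lit != pytest.approx(gs.conditional_entropy(m).raw_bits, abs=1e-6)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="standard"):
            entropy_of([0, 1, 0, 1], mode="joint")

    def test_brute_force_oracle_equivalence(self):
        """Dictionary-of-pairs oracle matches the vectorized pipeline."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            s = rng.integers(0, rng.integers(2, 5), size=rng.integers(10, 60))
            m = gs.transition_model(s)
            pair_counts = {}
            for a, b in zip(s[:-1], s[1:]):
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
            total = sum(pair_counts.values())
            p_i = {}
            for (a, _), c in pair_counts.items():
                p_i[a] = p_i.get(a, 0) + c / total
            h = 0.0
            for (a, b), c in pair_counts.items():
                pj = c / total
                pc = pj / p_i[a]
                h -= p_i[a] * pc * np.log2(pc)
            assert gs.conditional_entropy(m).raw_bits == pytest.approx(h, abs=1e-12)


class TestSessionEntropy:
    def test_gaze_equals_eye_when_head_is_still(self, noise_free_params):
        p = replace(noise_free_params, head_gain_yaw=0.0, head_gain_pitch=0.0,
                    fixation_jitter_sd=0.5)
        s = gs.simulate_session(p)
        e = gs.session_entropy(s, "eye")
        g = gs.session_entropy(s, "gaze")
        assert g.normalized == pytest.approx(e.normalized, abs=1e-9)

    def test_normalized_in_unit_interval(self, short_session):
        for eff in ("eye", "head", "gaze"):
            r = gs.session_entropy(short_session, eff)
            assert 0.0 <= r.normalized <= 1.0
            assert r.n_bins == 500  # 60 s / 0.120 s

    def test_entropy_increases_with_state_randomness(self, short_params):
        """Averaged over seeds, eye entropy rises monotonically along a
        state_randomness sweep (the generator's complexity dial)."""
        levels = [0.30, 0.45, 0.60]
        means = []
        for sr in levels:
            vals = []
            for seed in range(8):
                p = replace(short_params, state_randomness=sr, seed=seed,
                            duration_s=120.0, n_trials=3)
                vals.append(gs.session_entropy(gs.simulate_session(p), "eye").normalized)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_unknown_effector_rejected(self, short_session):
        with pytest.raises(ValueError):
            gs.session_entropy(short_session, "torso")

    def test_aoi_policy_on_gaze(self, short_session):
        r = gs.session_entropy(short_session, "gaze", policy=gs.AoiLabels())
        assert r.policy == "aoi_labels"
        assert 0.0 <= r.normalized <= 1.0

    def test_aoi_policy_rejected_for_eye(self, short_session):
        with pytest.raises(ValueError, match="gaze"):
            gs.session_entropy(short_session, "eye", policy=gs.AoiLabels())
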