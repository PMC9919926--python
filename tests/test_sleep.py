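"""Movement counting and sleep/awake classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bedsense as bs
from bedsense.simulate import AWAKE, OFF_BED, SLEEP


def brute_force_counts(states, prev=None):
    """Independent recount: compare every frame with its predecessor."""
    states = np.asarray(states, bool)
    n_ep = len(states) // 30
    counts = []
    for e in range(n_ep):
        c = 0
        for i in range(e * 30, (e + 1) * 30):
            if i == 0:
                ref = prev
            else:
                ref = states[i - 1]
            if ref is not None and np.any(states[i] != ref):
                c += 1
        counts.append(c)
    return np.array(counts)


class TestMovementCounts:
    def test_identical_frames_count_zero(self):
        assert bs.count_movements(np.zeros((30, 30), bool)) == 0

    def test_alternating_frames_count_thirty(self):
        states = np.zeros((30, 30), bool)
        states[::2, 0] = True  # area 1 toggles every second
        prev = np.zeros(30, bool)  # differs from the block's first frame too
        assert bs.count_movements(states, prev_frame=prev) == 30

    def test_first_frame_ever_counts_no_movement(self):
        states = np.zeros((30, 30), bool)
        states[0, 5] = True
        assert bs.count_movements(states) == 1  # only the return transition

    def test_wrong_epoch_length_rejected(self):
        with pytest.raises(ValueError):
            bs.count_movements(np.zeros((29, 30), bool))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_matches_brute_force_on_random_streams(self, seed, n_epochs):
        rng = np.random.default_rng(seed)
        states = rng.random((n_epochs * 30, 30)) < 0.3
        assert np.array_equal(bs.movement_counts(states), brute_force_counts(states))

    def test_block_boundary_uses_previous_block_last_frame(self):
        states = np.zeros((60, 30), bool)
        states[29, 3] = True   # last frame of block 1 differs from block 2 start
        counts = bs.movement_counts(states)
        assert counts.tolist() == [1, 1]


class TestMovementPercentage:
    @pytest.mark.parametrize("value,expected", [(30, 100.0), (3, 10.0), (0, 0.0)])
    def test_uniform_counts(self, value, expected):
        assert bs.movement_percentage([value] * 20) == expected

    def test_needs_exactly_twenty_counts(self):
        with pytest.raises(ValueError):
            bs.movement_percentage([0] * 19)

    def test_series_percentages(self):
        ms = bs.MovementSeries(np.full(40, 6))
        assert np.allclose(ms.percentages(), [20.0, 20.0])


class _ThresholdModel:
    """Stub staging rule: awake iff the window's last count exceeds 5."""

    def predict(self, windows):
        w = np.asarray(windows)
        return np.where(w[:, -1] > 5, AWAKE, SLEEP).astype(np.int8)


class TestClassifySleep:
    def test_efficiency_arithmetic(self):
        # 500 in-bed epochs, 70 awake -> 430/500 = 86.0%
        counts = np.zeros(500, int)
        counts[100:170] = 10
        rec = bs.classify_sleep(_ThresholdModel(), counts, np.ones(500, bool))
        assert rec.sleep_efficiency == pytest.approx(86.0)
        assert rec.total_sleep_s == 430 * 30
        assert rec.total_in_bed_s == 500 * 30

    def test_zero_in_bed_time_is_degenerate(self):
        rec = bs.classify_sleep(_ThresholdModel(), np.zeros(100, int),
                                np.zeros(100, bool))
        assert rec.sleep_efficiency is None
        assert rec.total_sleep_s == 0
        assert (rec.epoch_states == OFF_BED).all()

    def test_all_sleep_gives_full_efficiency(self):
        rec = bs.classify_sleep(_ThresholdModel(), np.zeros(50, int),
                                np.ones(50, bool))
        assert rec.sleep_efficiency == 100.0

    def test_sleep_plus_awake_equals_in_bed_exactly(self, sleep_cv):
        model, _, _ = sleep_cv
        rng = np.random.default_rng(0)
        occ = np.zeros(400, bool)
        occ[20:200] = True
        occ[250:390] = True
        counts = rng.integers(0, 10, size=400)
        rec = bs.classify_sleep(model, counts, occ)
        assert rec.total_sleep_s + rec.total_awake_s == rec.total_in_bed_s
        assert rec.total_in_bed_s == occ.sum() * 30

    def test_short_bout_is_still_staged(self):
        counts = np.zeros(10, int)
        occ = np.zeros(10, bool)
        occ[2:6] = True  # 4-epoch bout, shorter than a window
        rec = bs.classify_sleep(_ThresholdModel(), counts, occ)
        assert (rec.epoch_states[2:6] != OFF_BED).all()

    def test_raising_counts_never_increases_sleep_under_threshold_rule(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 12, size=200)
        occ = np.ones(200, bool)
        low = bs.classify_sleep(_ThresholdModel(), counts, occ)
        high = bs.classify_sleep(_ThresholdModel(), counts + 3, occ)
        assert high.total_sleep_s <= low.total_sleep_s


class TestTraining:
    def test_single_class_data_rejected(self):
        X = np.zeros((50, 8))
        y = np.full(50, SLEEP)
        with pytest.raises(ValueError):
            bs.train_sleep_model(X, y, n_folds=3, seed=0)

    def test_wrong_window_width_rejected(self):
        with pytest.raises(ValueError):
            bs.train_sleep_model(np.zeros((50, 5)), np.arange(50) % 2, seed=0)

    def test_training_is_deterministic(self, sleep_nights):
        X, y = bs.windows_from_nights(sleep_nights[:2])
        _, a1, s1 = bs.train_sleep_model(X, y, n_folds=3, seed=2)
        _, a2, s2 = bs.train_sleep_model(X, y, n_folds=3, seed=2)
        assert (a1, s1) == (a2, s2)

    def test_indistinguishable_rates_give_majority_accuracy(self):
        # near-equal movement rates carry no class signal
        nights = [bs.simulate_night(4.0, seed=50 + i, sleep_movement_rate=3.0,
                                    wake_movement_rate=3.000001) for i in range(2)]
        X, y = bs.windows_from_nights(nights)
        _, acc, _ = bs.train_sleep_model(X, y, n_folds=3, seed=0)
        majority = max((y == SLEEP).mean(), (y == AWAKE).mean()) * 100
        assert acc == pytest.approx(majority, abs=6.0)

    def test_model_round_trip(self, sleep_cv, tmp_path):
        model, _, _ = sleep_cv
        path = model.save(tmp_path / "sleep.joblib")
        back = bs.SleepModel.load(path)
        X = np.arange(16, dtype=float).reshape(2, 8)
        assert np.array_equal(back.predict(X), model.predict(X))


def test_window_builder_shapes():
    counts = np.arange(20)
    stages = np.arange(20) % 2
    X, y = bs.build_windows(counts, stages)
    assert X.shape == (13, 8)
    assert np.array_equal(X[0], np.arange(8, dtype=float))
    assert len(y) == 13
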