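import numpy as np
import pytest

from axonav.behavior import MotionOnsetEvent, segment_laps
from axonav.tuning import (
    align_to_motion_onset,
    align_to_transition,
    bin_aligned,
    bin_by_position,
    bin_by_reward_proximity,
    bin_by_velocity,
)

FS = 30.0


def brute_force_curve(values, covariate, lap_index, lap_ids, edges):
    """Loop over frames, accumulate per (lap, bin); last bin right-closed."""
    n_bins = len(edges) - 1
    sums = {}
    counts = {}
    for v, c, lap in zip(values, covariate, lap_index):
        if lap not in lap_ids or not np.isfinite(v):
            continue
        if c < edges[0] or c > edges[-1]:
            continue
        b = n_bins - 1 if c == edges[-1] else int(np.searchsorted(edges, c, "right")) - 1
        if not 0 <= b < n_bins:
            continue
        sums[(lap, b)] = sums.get((lap, b), 0.0) + v
        counts[(lap, b)] = counts.get((lap, b), 0) + 1
    per_lap = np.full((len(lap_ids), n_bins), np.nan)
    for i, lap in enumerate(lap_ids):
        for b in range(n_bins):
            if (lap, b) in counts:
                per_lap[i, b] = sums[(lap, b)] / counts[(lap, b)]
    return per_lap


def make_toy_session(rng, n=600, track=100.0, n_laps=4):
    """Sawtooth position over n_laps laps, all familiar."""
    lap_len = n // n_laps
    pos = np.tile(np.linspace(0, track, lap_len, endpoint=False), n_laps)[:n]
    teleports = np.arange(1, n_laps) * lap_len
    laps = segment_laps(pos, teleports)
    env = np.full(n, "familiar", dtype=object)
    return pos, teleports, laps, env


class TestBinByPosition:
    def test_identity_signal_oracle(self):
        rng = np.random.default_rng(0)
        pos, _, laps, env = make_toy_session(rng)
        norm_q = pos / 100.0
        curve = bin_by_position(norm_q, pos, laps, env, "familiar", 100.0, bin_cm=5.0)
        centers = curve.bin_centers
        ok = np.isfinite(curve.mean)
        assert np.all(np.abs(curve.mean[ok] - centers[ok] / 100.0) <= 2.5 / 100.0)

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(100, 400))
            track = float(rng.choice([100.0, 200.0]))
            pos = rng.uniform(0, track, n)
            teleports = np.sort(rng.choice(np.arange(10, n - 10), size=3, replace=False))
            laps = segment_laps(pos, teleports)
            env = np.full(n, "familiar", dtype=object)
            vals = rng.normal(0, 1, n)
            curve = bin_by_position(vals, pos, laps, env, "familiar", track)
            lap_ids = curve.lap_ids
            oracle = brute_force_curve(vals, pos, laps.index, set(lap_ids.tolist()),
                                       curve.bin_edges)
            np.testing.assert_allclose(curve.per_lap, oracle, atol=1e-12)

    def test_constant_trace_flat_sem_zero(self):
        rng = np.random.default_rng(2)
        pos, _, laps, env = make_toy_session(rng)
        curve = bin_by_position(np.full(600, 0.7), pos, laps, env, "familiar", 100.0)
        ok = np.isfinite(curve.mean)
        np.testing.assert_allclose(curve.mean[ok], 0.7)
        np.testing.assert_allclose(curve.sem[curve.n_laps_per_bin > 1], 0.0, atol=1e-12)

    def test_missing_bin_is_nan_and_excluded(self):
        # lap 0 never visits positions > 50; its row must be NaN there
        pos = np.concatenate([np.linspace(0, 49, 100), np.linspace(0, 99, 100)])
        laps = segment_laps(pos, np.array([100]))
        env = np.full(200, "familiar", dtype=object)
        vals = np.ones(200)
        vals[100:] = 2.0
        curve = bin_by_position(vals, pos, laps, env, "familiar", 100.0)
        assert np.isnan(curve.per_lap[0, -1])
        # lap 1 is incomplete (no trailing teleport) -> actually lap 1 IS
        # terminated only by trace end; completed mask excludes it
        assert curve.per_lap.shape[0] == 1

    def test_no_laps_in_env_raises(self):
        rng = np.random.default_rng(3)
        pos, _, laps, env = make_toy_session(rng)
        with pytest.raises(ValueError, match="novel"):
            bin_by_position(pos / 100.0, pos, laps, env, "novel", 100.0)

    def test_reward_pause_frames_in_final_bin(self):
        pos = np.concatenate([np.linspace(0, 100, 80), np.full(20, 100.0),
                              np.linspace(0, 90, 100)])
        laps = segment_laps(pos, np.array([100]))
        env = np.full(200, "familiar", dtype=object)
        vals = np.zeros(200)
        vals[80:100] = 1.0  # only the frozen frames carry signal
        curve = bin_by_position(vals, pos, laps, env, "familiar", 100.0)
        assert curve.per_lap[0, -1] > 0  # frozen frames landed in the last bin


class TestBinByVelocity:
    def test_identity_signal(self):
        rng = np.random.default_rng(4)
        n = 800
        v = rng.uniform(0, 35, n)
        laps = segment_laps(np.zeros(n), np.array([400]))
        env = np.full(n, "familiar", dtype=object)
        curve = bin_by_velocity(v / 30.0, v, laps, env, "familiar")
        ok = np.isfinite(curve.mean)
        assert np.all(np.abs(curve.mean[ok] - curve.bin_centers[ok] / 30.0) <= 0.5 / 30.0)
        assert curve.population_complete is not None
        assert not curve.population_complete[-1]  # >14 cm/s flagged

    def test_out_of_range_excluded(self):
        n = 200
        v = np.full(n, 0.5)  # everything below 1 cm/s
        laps = segment_laps(np.zeros(n), np.array([100]))
        env = np.full(n, "familiar", dtype=object)
        with pytest.raises(ValueError, match="velocity"):
            bin_by_velocity(np.ones(n), v, laps, env, "familiar")

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n = 500
        v = rng.uniform(0, 35, n)
        vals = rng.normal(size=n)
        laps = segment_laps(np.zeros(n), np.array([250]))
        env = np.full(n, "familiar", dtype=object)
        curve = bin_by_velocity(vals, v, laps, env, "familiar")
        keep = (v >= 1.0) & (v <= 30.0)
        oracle = brute_force_curve(vals[keep], v[keep], laps.index[keep],
                                   set(curve.lap_ids.tolist()), curve.bin_edges)
        np.testing.assert_allclose(curve.per_lap, oracle, atol=1e-12)


class TestRewardProximity:
    def test_distance_mode_monotone(self):
        rng = np.random.default_rng(6)
        pos, _, laps, env = make_toy_session(rng)
        curve = bin_by_reward_proximity(pos / 100.0, pos, laps, env, "familiar",
                                        100.0, np.array([], int), mode="distance")
        ok = np.isfinite(curve.mean)
        d = np.diff(curve.mean[ok])
        assert np.all(d < 0)  # activity falls as distance-to-reward grows

    def test_time_mode_jump_at_reward(self):
        n = 400
        pos = np.tile(np.linspace(0, 99, 200), 2)
        rewards = np.array([199, 399])
        laps = segment_laps(pos, np.array([200]))
        env = np.full(n, "familiar", dtype=object)
        vals = np.zeros(n)
        vals[rewards] = 1.0
        curve = bin_by_reward_proximity(vals, pos, laps, env, "familiar", 100.0,
                                        rewards, frame_rate_hz=FS, mode="time")
        assert curve.covariate == "time_to_reward"
        assert np.nanargmax(curve.mean) == 0  # bin ending at 0 s holds the jump

    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="mode"):
            bin_by_reward_proximity(np.zeros(10), np.zeros(10), None,
                                    np.full(10, "familiar", object), "familiar",
                                    100.0, np.array([], int), mode="banana")


class TestAlignToMotionOnset:
    def test_linear_ramp_recovered(self):
        n = 3000
        trace = np.zeros(n)
        onsets = [500, 1500, 2500]
        ramp = np.linspace(0, 1, 60)
        for f in onsets:
            trace[f - 60:f] = ramp
        events = [MotionOnsetEvent(f, True, True) for f in onsets]
        mat = align_to_motion_onset(trace, events, FS, window_s=(-2.0, 3.0))
        assert mat.values.shape == (3, 150)
        mean = mat.values.mean(axis=0)
        pre = mat.time_axis_s < 0
        np.testing.assert_allclose(mean[pre], ramp, atol=1e-12)

    def test_constant_trace_flat(self):
        events = [MotionOnsetEvent(100, True, True)]
        mat = align_to_motion_onset(np.full(400, 0.5), events, FS)
        np.testing.assert_allclose(mat.values, 0.5)

    def test_incomplete_window_dropped(self):
        events = [MotionOnsetEvent(10, True, True), MotionOnsetEvent(100, True, True)]
        mat = align_to_motion_onset(np.zeros(400), events, FS)
        assert mat.values.shape[0] == 1

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no motion-onset"):
            align_to_motion_onset(np.zeros(400), [MotionOnsetEvent(5, True, True)], FS)


class TestAlignToTransition:
    def test_all_ones(self):
        traces = np.ones((3, 600))
        mat = align_to_transition(traces, 300, FS, (-5.0, 5.0))
        np.testing.assert_allclose(mat.values[mat.valid], 1.0)
        assert mat.time_axis_s[mat.event_index] == 0.0

    def test_step_in_one_roi(self):
        traces = np.ones((4, 600))
        traces[0, 300:] += 1.0
        mat = align_to_transition(traces, 300, FS, (-5.0, 5.0))
        pm = mat.population_mean
        pre = pm[mat.event_index - 10]
        post = pm[mat.event_index + 10]
        assert post - pre == pytest.approx(1.0 / 4.0)

    def test_mask_applied_before_alignment(self):
        traces = np.arange(600, dtype=float)[None, :]
        mask = np.zeros(600, bool)
        mask[::2] = True  # keep even frames
        mat = align_to_transition(traces, 301, FS, (-1.0, 1.0), frame_mask=mask)
        # first retained frame >= 301 is 302; aligned timeline is even frames
        assert mat.values[0, mat.event_index] == 302.0
        assert mat.values[0, mat.event_index - 1] == 300.0

    def test_empty_pre_window_raises(self):
        traces = np.ones((2, 600))
        mask = np.zeros(600, bool)
        mask[300:] = True
        with pytest.raises(ValueError, match="before"):
            align_to_transition(traces, 300, FS, (-5.0, 5.0), frame_mask=mask)


class TestBinAligned:
    def test_500_frames_ten_bins(self):
        traces = np.arange(500, dtype=float)[None, :].repeat(2, axis=0)
        mat = align_to_transition(traces, 250, FS, (-250 / FS, 250 / FS))
        binned = bin_aligned(mat, "frames", bin_frames=50)
        assert binned.values.shape[1] == 10
        assert binned.event_bin == 5
        # each bin mean is the midpoint of its 50 source frames
        np.testing.assert_allclose(binned.values[0], np.arange(10) * 50 + 24.5)

    def test_remainder_dropped(self):
        traces = np.ones((1, 400))
        mat = align_to_transition(traces, 130, FS, (-130 / FS, 270 / FS))
        binned = bin_aligned(mat, "frames", bin_frames=50)
        # 130 pre frames -> 2 bins (30 dropped); 270 post -> 5 bins (20 dropped)
        assert binned.values.shape[1] == 7

    def test_lap_mode(self):
        n = 600
        lap_index = np.repeat(np.arange(6), 100)
        traces = np.repeat(np.arange(6.0), 100)[None, :]
        mat = align_to_transition(traces, 300, FS, (-300 / FS, 300 / FS))
        binned = bin_aligned(mat, "lap", lap_index=lap_index)
        np.testing.assert_array_equal(binned.bin_labels, [-3, -2, -1, 0, 1, 2])
        np.testing.assert_allclose(binned.values[0], np.arange(6.0))
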