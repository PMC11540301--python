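"""Covariate-binned tuning curves and event-aligned activity matrices.

Binning convention: half-open bins ``[edge_i, edge_i+1)`` except the last,
which is closed so the frozen reward-pause frames (position held at the
track end) land in the final position bin. Across-lap means and s.e.m.
ignore NaN cells; a bin's across-lap mean uses exactly the laps that have
at least one sample in that bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuningCurve",
    "AlignedMatrix",
    "BinnedAligned",
    "bin_by_position",
    "bin_by_velocity",
    "bin_by_reward_proximity",
    "align_to_motion_onset",
    "align_to_transition",
    "bin_aligned",
]

log = logging.getLogger(__name__)

POSITION_BIN_CM = 5.0
VELOCITY_BIN_CM_S = 1.0
VELOCITY_RANGE_CM_S = (1.0, 30.0)
VELOCITY_POPULATION_MAX_CM_S = 14.0
NORMALIZED_GRID_BINS = 40


@dataclass
class TuningCurve:
    covariate: str
    bin_edges: np.ndarray
    per_lap: np.ndarray            # laps x bins, NaN where a lap lacks samples
    lap_ids: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_laps_per_bin: np.ndarray
    population_complete: np.ndarray | None = None
    env: str | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalized_positions(self, track_length_cm: float) -> np.ndarray:
        """Bin centers mapped to normalized [0, 1] track position."""
        return self.bin_centers / track_length_cm

    def to_common_grid(self, track_length_cm: float,
                       n_bins: int = NORMALIZED_GRID_BINS) -> tuple:
        """Interpolate the mean curve onto an n-bin normalized-position grid."""
        grid = (np.arange(n_bins) + 0.5) / n_bins
        x = self.normalized_positions(track_length_cm)
        ok = np.isfinite(self.mean)
        return grid, np.interp(grid, x[ok], self.mean[ok])


def _curve_from_samples(values: np.ndarray, covariate: np.ndarray,
                        lap_of_sample: np.ndarray, lap_ids: np.ndarray,
                        bin_edges: np.ndarray, covariate_name: str,
                        env: str | None) -> TuningCurve:
    """Accumulate per-(lap, bin) means. Last bin is closed on the right."""
    n_bins = bin_edges.shape[0] - 1
    n_laps = lap_ids.shape[0]
    lap_pos = {lap: i for i, lap in enumerate(lap_ids)}

    idx = np.digitize(covariate, bin_edges) - 1
    idx[covariate == bin_edges[-1]] = n_bins - 1
    keep = (idx >= 0) & (idx < n_bins) & np.isfinite(values)

    sums = np.zeros((n_laps, n_bins))
    counts = np.zeros((n_laps, n_bins))
    rows = np.fromiter((lap_pos[l] for l in lap_of_sample[keep]), dtype=np.int64,
                       count=int(keep.sum()))
    np.add.at(sums, (rows, idx[keep]), values[keep])
    np.add.at(counts, (rows, idx[keep]), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        per_lap = np.where(counts > 0, sums / counts, np.nan)
        n_per_bin = np.sum(counts > 0, axis=0)
        mean = np.where(n_per_bin > 0, np.nansum(per_lap, axis=0) / np.maximum(n_per_bin, 1),
                        np.nan)
        dev = (per_lap - mean) ** 2
        var = np.where(n_per_bin > 1,
                       np.nansum(np.where(counts > 0, dev, 0.0), axis=0)
                       / np.maximum(n_per_bin - 1, 1),
                       np.nan)
        sem = np.sqrt(var / np.maximum(n_per_bin, 1))
        sem = np.where(n_per_bin > 1, sem, np.where(n_per_bin == 1, 0.0, np.nan))

    return TuningCurve(
        covariate=covariate_name,
        bin_edges=bin_edges,
        per_lap=per_lap,
        lap_ids=lap_ids,
        mean=mean,
        sem=sem,
        n_laps_per_bin=n_per_bin,
        env=env,
    )


def _env_lap_frames(laps, env_per_frame: np.ndarray, env: str) -> tuple:
    """Frames in completed laps of the requested environment."""
    frame_env = np.asarray(env_per_frame) == env
    lap_ids = [
        k for k, ((a, b), comp) in enumerate(zip(laps.bounds, laps.completed))
        if comp and frame_env[a:b].any()
    ]
    if not lap_ids:
        raise ValueError(f"no completed laps in environment {env!r}")
    in_lap = np.isin(laps.index, lap_ids)
    mask = in_lap & frame_env
    return np.asarray(lap_ids, dtype=np.int64), mask


def bin_by_position(norm_q: np.ndarray, position_cm: np.ndarray, laps,
                    env_per_frame: np.ndarray, env: str,
                    track_length_cm: float, bin_cm: float = POSITION_BIN_CM) -> TuningCurve:
    """Per-lap mean activity in 5 cm position bins, then across-lap mean/sem."""
    lap_ids, mask = _env_lap_frames(laps, env_per_frame, env)
    n_bins = int(np.ceil(track_length_cm / bin_cm))
    edges = np.arange(n_bins + 1) * bin_cm
    edges[-1] = track_length_cm
    return _curve_from_samples(
        np.asarray(norm_q, float)[mask], np.asarray(position_cm, float)[mask],
        laps.index[mask], lap_ids, edges, "position", env,
    )


def bin_by_velocity(norm_q: np.ndarray, velocity_cm_s: np.ndarray, laps,
                    env_per_frame: np.ndarray, env: str,
                    bin_cm_s: float = VELOCITY_BIN_CM_S,
                    vrange: tuple = VELOCITY_RANGE_CM_S,
                    population_max: float = VELOCITY_POPULATION_MAX_CM_S) -> TuningCurve:
    """Per-lap mean activity in 1 cm/s velocity bins over [1, 30] cm/s.

    Frames outside the range are excluded. Bins above ``population_max``
    are flagged not population-complete (not all animals reach them).
    """
    lap_ids, mask = _env_lap_frames(laps, env_per_frame, env)
    v = np.asarray(velocity_cm_s, float)
    lo, hi = vrange
    in_range = (v >= lo) & (v <= hi)
    mask = mask & in_range
    if not mask.any():
        raise ValueError(f"no frames with velocity inside [{lo}, {hi}] cm/s")
    edges = lo + np.arange(int(round((hi - lo) / bin_cm_s)) + 1) * bin_cm_s
    curve = _curve_from_samples(
        np.asarray(norm_q, float)[mask], v[mask], laps.index[mask],
        lap_ids, edges, "velocity", env,
    )
    curve.population_complete = curve.bin_centers <= population_max
    return curve


def bin_by_reward_proximity(norm_q: np.ndarray, position_cm: np.ndarray, laps,
                            env_per_frame: np.ndarray, env: str,
                            track_length_cm: float,
                            reward_frames: np.ndarray,
                            frame_rate_hz: float | None = None,
                            mode: str = "distance",
                            bin_size: float | None = None,
                            time_horizon_s: float = 10.0) -> TuningCurve:
    """Activity binned by distance (cm) or time (s) to the lap's reward.

    ``distance``: covariate = track_length - position, 5 cm bins.
    ``time``: covariate = (t_reward - t)/fs within each rewarded lap,
    0.5 s bins over the final ``time_horizon_s`` seconds.
    """
    if mode == "distance":
        bin_size = POSITION_BIN_CM if bin_size is None else bin_size
        lap_ids, mask = _env_lap_frames(laps, env_per_frame, env)
        n_bins = int(np.ceil(track_length_cm / bin_size))
        edges = np.arange(n_bins + 1) * bin_size
        edges[-1] = track_length_cm
        cov = track_length_cm - np.asarray(position_cm, float)
        return _curve_from_samples(
            np.asarray(norm_q, float)[mask], cov[mask], laps.index[mask],
            lap_ids, edges, "distance_to_reward", env,
        )
    if mode == "time":
        if frame_rate_hz is None:
            raise ValueError("time mode requires frame_rate_hz")
        bin_size = 0.5 if bin_size is None else bin_size
        lap_ids, mask = _env_lap_frames(laps, env_per_frame, env)
        n = np.asarray(position_cm).shape[0]
        reward_of_lap = {}
        for r in np.asarray(reward_frames, dtype=np.int64):
            lap = laps.index[r]
            if lap >= 0 and lap not in reward_of_lap:
                reward_of_lap[int(lap)] = int(r)
        lap_ids = np.asarray([l for l in lap_ids if l in reward_of_lap], dtype=np.int64)
        if lap_ids.size == 0:
            raise ValueError(f"no rewarded laps in environment {env!r}")
        t_idx = np.arange(n)
        cov = np.full(n, np.nan)
        for lap, r in reward_of_lap.items():
            sel = (laps.index == lap) & (t_idx <= r)
            cov[sel] = (r - t_idx[sel]) / frame_rate_hz
        mask = mask & np.isfinite(cov) & (cov <= time_horizon_s) \
            & np.isin(laps.index, lap_ids)
        edges = np.arange(int(round(time_horizon_s / bin_size)) + 1) * bin_size
        return _curve_from_samples(
            np.asarray(norm_q, float)[mask], cov[mask], laps.index[mask],
            lap_ids, edges, "time_to_reward", env,
        )
    raise ValueError(f"mode must be 'distance' or 'time', got {mode!r}")


@dataclass
class AlignedMatrix:
    align_kind: str                  # motion_onset | env_switch | vr_onset
    time_axis_s: np.ndarray
    values: np.ndarray               # rows x time (events or ROIs), NaN-padded
    valid: np.ndarray                # bool mask, same shape
    event_index: int                 # column of time 0
    source_frames: np.ndarray | None = None  # original frame per column, -1 pad
    row_ids: list = field(default_factory=list)

    @property
    def population_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(np.where(self.valid, self.values, np.nan), axis=0)

    @property
    def population_sem(self) -> np.ndarray:
        vals = np.where(self.valid, self.values, np.nan)
        n = np.sum(self.valid, axis=0)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(vals, axis=0, ddof=1)
        return np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)

    def segment(self, t0: float, t1: float) -> tuple:
        """(time, values) columns with t0 < time <= t1 — e.g. the pre-onset
        regression window (-2, 0]."""
        sel = (self.time_axis_s > t0) & (self.time_axis_s <= t1)
        return self.time_axis_s[sel], self.values[:, sel]


def align_to_motion_onset(norm_q: np.ndarray, events: list, frame_rate_hz: float,
                          window_s: tuple = (-2.0, 3.0)) -> AlignedMatrix:
    """One row per qualifying motion-onset event; incomplete windows dropped."""
    trace = np.asarray(norm_q, float)
    n = trace.shape[0]
    n_pre = int(round(-window_s[0] * frame_rate_hz))
    n_post = int(round(window_s[1] * frame_rate_hz))
    rows = []
    kept = []
    for ev in events:
        f = ev.onset_frame if hasattr(ev, "onset_frame") else int(ev)
        if f - n_pre < 0 or f + n_post > n:
            log.info("motion-onset event at frame %d dropped: incomplete window", f)
            continue
        rows.append(trace[f - n_pre:f + n_post])
        kept.append(f)
    if not rows:
        raise ValueError("no motion-onset events with a complete window")
    values = np.vstack(rows)
    time_axis = (np.arange(-n_pre, n_post)) / frame_rate_hz
    return AlignedMatrix(
        align_kind="motion_onset",
        time_axis_s=time_axis,
        values=values,
        valid=np.ones_like(values, dtype=bool),
        event_index=n_pre,
        row_ids=[f"event@{f}" for f in kept],
    )


def align_to_transition(traces: np.ndarray, event_frame: int, frame_rate_hz: float,
                        window_s: tuple, frame_mask: np.ndarray | None = None,
                        align_kind: str = "env_switch",
                        row_ids: list | None = None) -> AlignedMatrix:
    """ROI x time matrix of mean-normalized traces around a transition.

    If ``frame_mask`` is given (e.g. running-only frames), masked-out frames
    are removed and the concatenated timeline is aligned at the first
    retained frame at or after ``event_frame``. Edges are NaN-padded with a
    validity mask rather than dropped.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    n_roi, n = traces.shape
    if not 0 <= event_frame < n:
        raise ValueError(f"event_frame {event_frame} outside trace of length {n}")

    if frame_mask is not None:
        retained = np.flatnonzero(np.asarray(frame_mask, bool))
        if retained.size == 0:
            raise ValueError("frame_mask retains no frames")
        timeline = traces[:, retained]
        event_pos = int(np.searchsorted(retained, event_frame))
        frames = retained
    else:
        timeline = traces
        event_pos = int(event_frame)
        frames = np.arange(n)

    m = timeline.shape[1]
    n_pre = int(round(-window_s[0] * frame_rate_hz))
    n_post = int(round(window_s[1] * frame_rate_hz))
    if event_pos == 0 or n_pre == 0:
        raise ValueError("no frames available before the alignment event")
    if event_pos >= m or n_post == 0:
        raise ValueError("no frames available after the alignment event")

    width = n_pre + n_post
    values = np.full((n_roi, width), np.nan)
    valid = np.zeros((n_roi, width), dtype=bool)
    src = np.full(width, -1, dtype=np.int64)

    a = max(0, event_pos - n_pre)
    b = min(m, event_pos + n_post)
    col0 = n_pre - (event_pos - a)
    values[:, col0:col0 + (b - a)] = timeline[:, a:b]
    valid[:, col0:col0 + (b - a)] = True
    src[col0:col0 + (b - a)] = frames[a:b]

    time_axis = np.arange(-n_pre, n_post) / frame_rate_hz
    return AlignedMatrix(
        align_kind=align_kind,
        time_axis_s=time_axis,
        values=values,
        valid=valid,
        event_index=n_pre,
        source_frames=src,
        row_ids=row_ids or [f"roi{i}" for i in range(n_roi)],
    )


@dataclass
class BinnedAligned:
    mode: str                         # "frames" | "lap"
    bin_labels: np.ndarray            # bin index (frames mode) or lap offset
    values: np.ndarray                # rows x bins
    event_bin: int                    # first post-event bin position

    @property
    def population_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)


def bin_aligned(matrix: AlignedMatrix, mode: str = "frames",
                bin_frames: int = 50, lap_index: np.ndarray | None = None) -> BinnedAligned:
    """Reduce an aligned matrix to 50-frame or per-lap bins around the event.

    Frames mode: non-overlapping ``bin_frames`` bins counted away from the
    event on both sides; remainder frames (< one full bin) are dropped.
    Lap mode: columns grouped by the lap of their source frame, ordered,
    labelled by lap offset relative to the event lap.
    """
    vals = np.where(matrix.valid, matrix.values, np.nan)
    e = matrix.event_index
    width = matrix.time_axis_s.shape[0]

    if mode == "frames":
        n_post_bins = (width - e) // bin_frames
        n_pre_bins = e // bin_frames
        cols, labels = [], []
        for b in range(n_pre_bins, 0, -1):
            cols.append((e - b * bin_frames, e - (b - 1) * bin_frames))
            labels.append(-b)
        for b in range(n_post_bins):
            cols.append((e + b * bin_frames, e + (b + 1) * bin_frames))
            labels.append(b)
        out = np.full((vals.shape[0], len(cols)), np.nan)
        for j, (a, b) in enumerate(cols):
            with np.errstate(invalid="ignore"):
                out[:, j] = np.nanmean(vals[:, a:b], axis=1)
        return BinnedAligned(mode="frames", bin_labels=np.asarray(labels),
                             values=out, event_bin=n_pre_bins)

    if mode == "lap":
        if lap_index is None:
            raise ValueError("lap mode requires lap_index")
        if matrix.source_frames is None:
            raise ValueError("aligned matrix lacks source frame provenance")
        src = matrix.source_frames
        ok = src >= 0
        col_lap = np.full(width, -10**9, dtype=np.int64)
        col_lap[ok] = np.asarray(lap_index)[src[ok]]
        event_lap = col_lap[matrix.event_index]
        laps_present = np.unique(col_lap[ok & (col_lap >= 0)])
        out = np.full((vals.shape[0], laps_present.shape[0]), np.nan)
        for j, lap in enumerate(laps_present):
            sel = col_lap == lap
            with np.errstate(invalid="ignore"):
                out[:, j] = np.nanmean(vals[:, sel], axis=1)
        labels = laps_present - event_lap
        return BinnedAligned(mode="lap", bin_labels=labels, values=out,
                             event_bin=int(np.searchsorted(labels, 0)))

    raise ValueError(f"mode must be 'frames' or 'lap', got {mode!r}")
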