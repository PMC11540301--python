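"""Velocity, laps, immobility and motion-onset events from raw behavior.

Velocity is the backward difference of track position scaled to cm/s and
smoothed with a Savitzky-Golay filter (7-frame window, 5th-order
polynomial). Transitions that span a teleport are excluded from the
differencing (and marked) so the position reset never produces a spurious
negative velocity spike.

Two immobility thresholds coexist deliberately: ``< 5 cm/s`` defines
freezing and motion-onset eligibility, ``<= 0.2 cm/s`` defines the stricter
"good behavior" frame filter used by the novelty analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "BehaviorDerived",
    "Laps",
    "LapSummary",
    "MotionOnsetEvent",
    "compute_velocity",
    "segment_laps",
    "lap_metrics",
    "detect_motion_onsets",
    "filter_frames_by_motion",
    "derive_behavior",
]

log = logging.getLogger(__name__)

IMMOBILE_CM_S = 5.0
STATIONARY_CM_S = 0.2
SAVGOL_WINDOW = 7
SAVGOL_ORDER = 5


@dataclass
class Laps:
    """Per-frame lap assignment plus lap interval bookkeeping."""

    index: np.ndarray          # per-frame lap number, -1 if unassigned
    bounds: list               # [(start, end), ...] half-open
    completed: np.ndarray      # bool per lap: ends at a teleport

    @property
    def n_laps(self) -> int:
        return len(self.bounds)


@dataclass
class BehaviorDerived:
    velocity_cm_s: np.ndarray
    teleport_exclusion: np.ndarray
    laps: Laps
    immobile_5: np.ndarray
    stationary_02: np.ndarray

    @property
    def lap_index(self) -> np.ndarray:
        return self.laps.index


@dataclass
class LapSummary:
    lap: int
    env: str
    start_frame: int
    end_frame: int
    n_frames: int
    mean_moving_velocity_cm_s: float   # NaN when the lap has no moving frames
    freezing_ratio: float


@dataclass
class MotionOnsetEvent:
    onset_frame: int
    pre_ok: bool
    post_ok: bool


def compute_velocity(
    position_cm: np.ndarray,
    teleport_frames: np.ndarray,
    frame_rate_hz: float,
    window: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_ORDER,
) -> tuple:
    """Backward-difference velocity in cm/s, Savitzky-Golay smoothed.

    Returns ``(velocity_cm_s, teleport_exclusion)``. Excluded transitions
    (frame 0 and any frame whose backward difference spans a teleport) are
    filled by interpolating between the neighbouring valid differences
    before smoothing, so they cannot inject reset artifacts.
    """
    position_cm = np.asarray(position_cm, dtype=float)
    n = position_cm.shape[0]
    if n < window:
        raise ValueError(f"need at least {window} frames, got {n}")

    v_raw = np.empty(n)
    v_raw[1:] = np.diff(position_cm) * frame_rate_hz
    v_raw[0] = np.nan

    excl = np.zeros(n, dtype=bool)
    excl[0] = True
    tel = np.asarray(teleport_frames, dtype=np.int64)
    excl[tel[(tel >= 0) & (tel < n)]] = True

    good = ~excl
    if not good.any():
        raise ValueError("all velocity transitions excluded")
    idx = np.arange(n)
    v_filled = v_raw.copy()
    v_filled[excl] = np.interp(idx[excl], idx[good], v_raw[good])

    velocity = savgol_filter(v_filled, window_length=window, polyorder=polyorder)
    return velocity, excl


def segment_laps(position_cm: np.ndarray, teleport_frames: np.ndarray) -> Laps:
    """Split frames into laps at teleports; lap 0 starts at frame 0.

    The reward-pause frames (position frozen at the track end before the
    teleport) belong to the lap they terminate. Empty laps produced by
    consecutive or frame-0 teleports are dropped with a log line. The final
    partial lap (no terminating teleport) is kept but marked incomplete.
    """
    n = np.asarray(position_cm).shape[0]
    tel = np.asarray(teleport_frames, dtype=np.int64)
    cuts = [0] + [int(t) for t in tel if 0 <= t < n] + [n]

    teleport_cuts = set(cuts[1:-1])
    bounds = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            log.info("dropping empty lap between frames %d and %d", a, b)
            continue
        bounds.append((a, b))
    # a lap is completed iff its right edge is a teleport
    completed = [b in teleport_cuts for (_, b) in bounds]

    index = np.full(n, -1, dtype=np.int64)
    for k, (a, b) in enumerate(bounds):
        index[a:b] = k
    return Laps(index=index, bounds=bounds, completed=np.asarray(completed, dtype=bool))


def lap_metrics(
    velocity_cm_s: np.ndarray,
    laps: Laps,
    env_per_frame: np.ndarray | None = None,
    immobile_threshold: float = IMMOBILE_CM_S,
) -> list:
    """Per-lap moving-mean velocity and freezing ratio.

    Moving mean uses only frames with velocity >= threshold; a lap with no
    moving frames gets ``NaN`` there and freezing ratio 1.
    """
    velocity_cm_s = np.asarray(velocity_cm_s, dtype=float)
    out = []
    for k, (a, b) in enumerate(laps.bounds):
        v = velocity_cm_s[a:b]
        moving = v >= immobile_threshold
        n_frames = b - a
        freezing = float(np.sum(~moving) / n_frames)
        mean_moving = float(np.mean(v[moving])) if moving.any() else float("nan")
        env = "?"
        if env_per_frame is not None:
            env = str(env_per_frame[a])
        out.append(
            LapSummary(
                lap=k,
                env=env,
                start_frame=a,
                end_frame=b,
                n_frames=n_frames,
                mean_moving_velocity_cm_s=mean_moving,
                freezing_ratio=freezing,
            )
        )
    return out


def detect_motion_onsets(
    velocity_cm_s: np.ndarray,
    frame_rate_hz: float,
    threshold_cm_s: float = IMMOBILE_CM_S,
    min_still_s: float = 1.5,
    min_run_s: float = 3.0,
) -> list:
    """Frames where velocity crosses above threshold after a qualifying pause.

    An onset at frame ``t`` requires velocity >= threshold at ``t``,
    velocity < threshold for every frame of the preceding ``min_still_s``,
    and velocity >= threshold for every frame of the following ``min_run_s``
    (including ``t``).
    """
    v = np.asarray(velocity_cm_s, dtype=float)
    n = v.shape[0]
    n_pre = int(round(min_still_s * frame_rate_hz))
    n_post = int(round(min_run_s * frame_rate_hz))

    below = (v < threshold_cm_s).astype(np.int64)
    above = 1 - below

    cs_below = np.concatenate([[0], np.cumsum(below)])
    cs_above = np.concatenate([[0], np.cumsum(above)])

    events = []
    for t in range(n_pre, n - n_post + 1):
        if above[t] and cs_below[t] - cs_below[t - n_pre] == n_pre \
                and cs_above[t + n_post] - cs_above[t] == n_post:
            events.append(MotionOnsetEvent(onset_frame=t, pre_ok=True, post_ok=True))
    return events


def filter_frames_by_motion(
    arrays: list,
    velocity_cm_s: np.ndarray,
    state: str = "running",
    threshold_cm_s: float = STATIONARY_CM_S,
) -> tuple:
    """Concatenate frames in the requested motion state, keeping an index map.

    ``state="running"`` keeps frames with velocity > threshold;
    ``state="immobile"`` keeps the complement. Returns
    ``(filtered_arrays, index_map)`` where ``index_map[i]`` is the original
    frame of retained sample ``i``. An empty selection returns empty arrays
    (flagged with a log line), never raises.
    """
    v = np.asarray(velocity_cm_s, dtype=float)
    if state == "running":
        mask = v > threshold_cm_s
    elif state == "immobile":
        mask = ~(v > threshold_cm_s)
    else:
        raise ValueError(f"state must be 'running' or 'immobile', got {state!r}")
    index_map = np.flatnonzero(mask)
    if index_map.size == 0:
        log.warning("filter_frames_by_motion: no frames match state %s", state)
    return [np.asarray(a)[mask] for a in arrays], index_map


def derive_behavior(session, immobile_threshold: float = IMMOBILE_CM_S,
                    stationary_threshold: float = STATIONARY_CM_S) -> BehaviorDerived:
    """Convenience: full derived-behavior bundle for a Session."""
    velocity, excl = compute_velocity(
        session.behavior.position_cm,
        session.behavior.teleport_frames,
        session.frame_rate_hz,
    )
    laps = segment_laps(session.behavior.position_cm, session.behavior.teleport_frames)
    return BehaviorDerived(
        velocity_cm_s=velocity,
        teleport_exclusion=excl,
        laps=laps,
        immobile_5=velocity < immobile_threshold,
        stationary_02=velocity <= stationary_threshold,
    )
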