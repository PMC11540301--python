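"""Session data model and on-disk round-trip.

A session directory holds four text files:

``behavior.csv``
    frame, position_cm, reward (0/1), teleport (0/1), env_label, valid (0/1)
``traces.csv``
    frame plus one raw-fluorescence column per ROI id
``derived.csv`` (optional)
    computed per-ROI traces, columns named ``<roi_id>:<field>``
``rois.json``
    per-ROI kind / merged_from
``session.json``
    scalar metadata, environment schedule and free-form ``meta``

All frame indices are 0-based and intervals are half-open ``[start, end)``.
Floats are written with 17 significant digits so float64 values round-trip
bit-exactly and the writer is deterministic byte-for-byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorRaw",
    "RoiTrace",
    "Session",
    "ValidationError",
    "read_session",
    "write_session",
    "validate_session",
]

_FLOAT_FMT = "%.17g"
_DERIVED_FIELDS = ("dff_short", "dff_long", "norm_q", "norm_mean")

ENV_LABELS = ("dark", "familiar", "novel")


class ValidationError(ValueError):
    """A session violated one of its structural invariants."""


@dataclass
class BehaviorRaw:
    """Frame-synchronized raw behavior channels."""

    position_cm: np.ndarray
    reward_frames: np.ndarray
    teleport_frames: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.position_cm = np.asarray(self.position_cm, dtype=float)
        self.reward_frames = np.asarray(self.reward_frames, dtype=np.int64)
        self.teleport_frames = np.asarray(self.teleport_frames, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.position_cm.shape[0]


@dataclass
class RoiTrace:
    """Raw fluorescence and derived traces for one ROI.

    Derived arrays are ``None`` until computed by :mod:`axonav.trace_qc`.
    """

    roi_id: str
    kind: str  # "axon" | "bleb"
    raw_f: np.ndarray
    dff_short: np.ndarray | None = None
    dff_long: np.ndarray | None = None
    norm_q: np.ndarray | None = None
    norm_mean: np.ndarray | None = None
    merged_from: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.raw_f = np.asarray(self.raw_f, dtype=float)
        for name in _DERIVED_FIELDS:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))


@dataclass
class Session:
    """One imaging session: behavior + ROI traces + metadata."""

    session_id: str
    source: str  # "VTA" | "LC"
    frame_rate_hz: float
    track_length_cm: float
    env_schedule: list  # [(env_label, start_frame), ...]
    behavior: BehaviorRaw
    rois: list  # list[RoiTrace]
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.behavior.n_frames

    def env_per_frame(self) -> np.ndarray:
        """Environment label for every frame, from ``env_schedule``."""
        n = self.n_frames
        labels = np.empty(n, dtype=object)
        sched = list(self.env_schedule) + [(None, n)]
        for (label, start), (_, end) in zip(sched[:-1], sched[1:]):
            labels[start:end] = label
        return labels

    def axons(self) -> list:
        return [r for r in self.rois if r.kind == "axon"]

    def blebs(self) -> list:
        return [r for r in self.rois if r.kind == "bleb"]


def validate_session(s: Session) -> list:
    """Check every structural invariant; return ``[(code, message), ...]``.

    An empty report means the session is valid. Never raises.
    """
    report: list = []
    n = s.behavior.position_cm.shape[0]

    if s.frame_rate_hz <= 0:
        report.append(("frame_rate", f"frame_rate_hz must be > 0, got {s.frame_rate_hz}"))
    if s.track_length_cm <= 0:
        report.append(("track_length", f"track_length_cm must be > 0, got {s.track_length_cm}"))
    if s.source not in ("VTA", "LC"):
        report.append(("source", f"source must be VTA or LC, got {s.source!r}"))

    if s.behavior.valid.shape[0] != n:
        report.append(
            ("length_mismatch", f"valid has length {s.behavior.valid.shape[0]}, expected {n}")
        )
    for r in s.rois:
        if r.raw_f.shape[0] != n:
            report.append(
                ("length_mismatch", f"roi {r.roi_id} raw_f has length {r.raw_f.shape[0]}, behavior has {n}")
            )
        if not np.all(np.isfinite(r.raw_f)):
            report.append(("nonfinite_trace", f"roi {r.roi_id} raw_f contains non-finite values"))
        if r.kind not in ("axon", "bleb"):
            report.append(("roi_kind", f"roi {r.roi_id} kind must be axon or bleb, got {r.kind!r}"))
        for fname in _DERIVED_FIELDS:
            v = getattr(r, fname)
            if v is not None and v.shape[0] != n:
                report.append(
                    ("length_mismatch", f"roi {r.roi_id} {fname} has length {v.shape[0]}, expected {n}")
                )

    pos = s.behavior.position_cm
    if pos.size and (np.nanmin(pos) < 0 or np.nanmax(pos) > s.track_length_cm):
        report.append(
            ("position_range", f"position_cm outside [0, {s.track_length_cm}]: "
             f"min {np.nanmin(pos)}, max {np.nanmax(pos)}")
        )
    for name, ev in (("reward", s.behavior.reward_frames), ("teleport", s.behavior.teleport_frames)):
        if ev.size and (ev.min() < 0 or ev.max() >= n):
            report.append(("event_range", f"{name} frame outside [0, {n})"))
        if ev.size > 1 and np.any(np.diff(ev) <= 0):
            report.append(("event_order", f"{name} frames not strictly increasing"))

    sched = list(s.env_schedule)
    if not sched:
        report.append(("env_schedule", "env_schedule is empty"))
    else:
        if sched[0][1] != 0:
            report.append(("env_schedule", f"first env segment must start at frame 0, got {sched[0][1]}"))
        starts = [int(f) for _, f in sched]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            report.append(("env_schedule", "env start_frames not strictly increasing"))
        for label, _ in sched:
            if label not in ENV_LABELS:
                report.append(("env_schedule", f"unknown env label {label!r}"))
    return report


def _require_valid(s: Session) -> None:
    report = validate_session(s)
    if report:
        lines = "; ".join(f"[{c}] {m}" for c, m in report)
        raise ValidationError(lines)


def write_session(s: Session, path: str) -> None:
    """Write ``s`` under directory ``path`` (created if needed).

    Refuses to write an invalid session. Output bytes are a pure function
    of the session contents.
    """
    _require_valid(s)
    os.makedirs(path, exist_ok=True)
    n = s.n_frames

    reward = np.zeros(n, dtype=int)
    reward[s.behavior.reward_frames] = 1
    teleport = np.zeros(n, dtype=int)
    teleport[s.behavior.teleport_frames] = 1
    behav = pd.DataFrame(
        {
            "frame": np.arange(n),
            "position_cm": s.behavior.position_cm,
            "reward": reward,
            "teleport": teleport,
            "env_label": s.env_per_frame(),
            "valid": s.behavior.valid.astype(int),
        }
    )
    behav.to_csv(os.path.join(path, "behavior.csv"), index=False,
                 float_format=_FLOAT_FMT, lineterminator="\n")

    traces = pd.DataFrame({"frame": np.arange(n)})
    for r in s.rois:
        traces[r.roi_id] = r.raw_f
    traces.to_csv(os.path.join(path, "traces.csv"), index=False,
                  float_format=_FLOAT_FMT, lineterminator="\n")

    derived_cols = {}
    for r in s.rois:
        for fname in _DERIVED_FIELDS:
            v = getattr(r, fname)
            if v is not None:
                derived_cols[f"{r.roi_id}:{fname}"] = v
    derived_path = os.path.join(path, "derived.csv")
    if derived_cols:
        derived = pd.DataFrame({"frame": np.arange(n), **derived_cols})
        derived.to_csv(derived_path, index=False, float_format=_FLOAT_FMT,
                       lineterminator="\n")
    elif os.path.exists(derived_path):
        os.remove(derived_path)

    rois_doc = {
        r.roi_id: {"kind": r.kind, "merged_from": list(r.merged_from)} for r in s.rois
    }
    with open(os.path.join(path, "rois.json"), "w", encoding="utf-8") as fh:
        json.dump(rois_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")

    session_doc = {
        "session_id": s.session_id,
        "source": s.source,
        "frame_rate_hz": s.frame_rate_hz,
        "track_length_cm": s.track_length_cm,
        "env_schedule": [[label, int(start)] for label, start in s.env_schedule],
        "meta": s.meta,
    }
    with open(os.path.join(path, "session.json"), "w", encoding="utf-8") as fh:
        json.dump(session_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_session(path: str) -> Session:
    """Load and validate a session directory written by :func:`write_session`."""
    for fname in ("behavior.csv", "traces.csv", "rois.json", "session.json"):
        if not os.path.exists(os.path.join(path, fname)):
            raise FileNotFoundError(f"session directory {path!r} is missing {fname}")

    with open(os.path.join(path, "session.json"), encoding="utf-8") as fh:
        doc = json.load(fh)
    with open(os.path.join(path, "rois.json"), encoding="utf-8") as fh:
        rois_doc = json.load(fh)

    behav = pd.read_csv(os.path.join(path, "behavior.csv"), float_precision="round_trip")
    traces = pd.read_csv(os.path.join(path, "traces.csv"), float_precision="round_trip")
    if len(behav) != len(traces):
        raise ValidationError(
            f"behavior.csv has {len(behav)} rows but traces.csv has {len(traces)}"
        )

    derived_path = os.path.join(path, "derived.csv")
    derived = (pd.read_csv(derived_path, float_precision="round_trip")
               if os.path.exists(derived_path) else None)

    behavior = BehaviorRaw(
        position_cm=behav["position_cm"].to_numpy(float),
        reward_frames=np.flatnonzero(behav["reward"].to_numpy(int)),
        teleport_frames=np.flatnonzero(behav["teleport"].to_numpy(int)),
        valid=behav["valid"].to_numpy(int).astype(bool),
    )

    rois = []
    for roi_id in traces.columns[1:]:
        info = rois_doc.get(roi_id, {})
        kwargs = {}
        if derived is not None:
            for fname in _DERIVED_FIELDS:
                col = f"{roi_id}:{fname}"
                if col in derived.columns:
                    kwargs[fname] = derived[col].to_numpy(float)
        rois.append(
            RoiTrace(
                roi_id=roi_id,
                kind=info.get("kind", "axon"),
                raw_f=traces[roi_id].to_numpy(float),
                merged_from=list(info.get("merged_from", [])),
                **kwargs,
            )
        )

    s = Session(
        session_id=doc["session_id"],
        source=doc["source"],
        frame_rate_hz=float(doc["frame_rate_hz"]),
        track_length_cm=float(doc["track_length_cm"]),
        env_schedule=[(label, int(start)) for label, start in doc["env_schedule"]],
        behavior=behavior,
        rois=rois,
        meta=dict(doc.get("meta", {})),
    )
    _require_valid(s)
    return s


def copy_session(s: Session) -> Session:
    """Deep copy (arrays copied)."""
    return replace(
        s,
        behavior=BehaviorRaw(
            s.behavior.position_cm.copy(),
            s.behavior.reward_frames.copy(),
            s.behavior.teleport_frames.copy(),
            s.behavior.valid.copy(),
        ),
        env_schedule=list(s.env_schedule),
        rois=[
            RoiTrace(
                r.roi_id,
                r.kind,
                r.raw_f.copy(),
                None if r.dff_short is None else r.dff_short.copy(),
                None if r.dff_long is None else r.dff_long.copy(),
                None if r.norm_q is None else r.norm_q.copy(),
                None if r.norm_mean is None else r.norm_mean.copy(),
                list(r.merged_from),
            )
            for r in s.rois
        ],
        meta=dict(s.meta),
    )
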