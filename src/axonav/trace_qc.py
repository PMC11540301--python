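"""Trace quality control: dF/F, ROI merging, SNR filtering, shift exclusion.

The baseline for dF/F is a rolling low percentile (8th by default) over a
centered window truncated at the trace edges — 300 frames for lap-by-lap
analysis, 2000 frames for slow signals.

SNR is the peak Welch power in [0.5, 1] Hz over the mean power in (1, 3] Hz
of the long-window dF/F; axons must exceed the cohort bleb threshold
(bleb mean + 1.5 * bleb sample sd, strict inequality) to be kept.

Sustained upward mean shifts ("unhealthy" axons filling with calcium) are
flagged with a one-sided CUSUM scan confirmed by a run-length rule:
elevated >= 2000 frames anywhere, or >= 500 frames reaching the trace end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import welch

__all__ = [
    "QcRow",
    "QcReport",
    "compute_dff",
    "merge_correlated_rois",
    "compute_snr",
    "snr_filter",
    "detect_sustained_shift",
    "normalize_quantile",
    "normalize_mean",
    "run_qc",
]

log = logging.getLogger(__name__)

DFF_SHORT_WINDOW = 300
DFF_LONG_WINDOW = 2000
BASELINE_PERCENTILE = 8.0
MERGE_R_MIN = 0.7
SNR_SD_FACTOR = 1.5
SHIFT_MIN_RUN = 2000
SHIFT_END_RUN = 500


def compute_dff(raw_f: np.ndarray, window_frames: int,
                percentile: float = BASELINE_PERCENTILE) -> np.ndarray:
    """dF/F against a rolling lower-percentile baseline.

    ``F0[t]`` is the given percentile of ``raw_f`` over a centered window of
    ``window_frames`` frames, truncated at the edges (linear interpolation
    between order statistics). For even window lengths the extra frame is
    taken from the past: the window covers ``[t - w//2, t + w - w//2 - 1]``.
    Raises if the baseline is not positive everywhere, which signals a units
    problem.
    """
    raw_f = np.asarray(raw_f, dtype=float)
    if raw_f.shape[0] < window_frames:
        raise ValueError(
            f"trace length {raw_f.shape[0]} shorter than baseline window {window_frames}"
        )
    f0 = (
        pd.Series(raw_f)
        .rolling(window_frames, center=True, min_periods=1)
        .quantile(percentile / 100.0, interpolation="linear")
        .to_numpy()
    )
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"non-positive baseline at frame {bad[0]} (F0={f0[bad[0]]})")
    return (raw_f - f0) / f0


def merge_correlated_rois(rois: list, r_min: float = MERGE_R_MIN,
                          dff_window: int = DFF_LONG_WINDOW) -> list:
    """Merge duplicated axon ROIs by trace correlation.

    Builds a graph with an edge for every axon pair whose long-window dF/F
    Pearson correlation is >= ``r_min`` and merges each connected component
    into one ROI whose raw fluorescence is the unweighted mean of its
    members (dF/F dropped, to be recomputed). Blebs never merge.
    Returns a new ROI list; ``merged_from`` records provenance.
    """
    from .session import RoiTrace

    axons = [r for r in rois if r.kind == "axon"]
    others = [r for r in rois if r.kind != "axon"]
    if len(axons) <= 1:
        return list(rois)

    dffs = []
    for r in axons:
        d = r.dff_long
        if d is None:
            d = compute_dff(r.raw_f, min(dff_window, r.raw_f.shape[0]))
        dffs.append(d)
    dmat = np.vstack(dffs)
    corr = np.corrcoef(dmat)

    # union-find over the r >= r_min graph
    parent = list(range(len(axons)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(axons)):
        for j in range(i + 1, len(axons)):
            if corr[i, j] >= r_min:
                parent[find(i)] = find(j)

    groups: dict = {}
    for i in range(len(axons)):
        groups.setdefault(find(i), []).append(i)

    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(axons[members[0]])
            continue
        member_rois = [axons[i] for i in members]
        raw = np.mean([r.raw_f for r in member_rois], axis=0)
        roi_id = "+".join(r.roi_id for r in member_rois)
        merged.append(
            RoiTrace(
                roi_id=roi_id,
                kind="axon",
                raw_f=raw,
                merged_from=[r.roi_id for r in member_rois],
            )
        )
        log.info("merged ROIs %s -> %s", [r.roi_id for r in member_rois], roi_id)
    merged.sort(key=lambda r: r.roi_id)
    return merged + others


def compute_snr(dff: np.ndarray, frame_rate_hz: float,
                segment_s: float = 60.0) -> float:
    """Spectral SNR: peak PSD on [0.5, 1] Hz over mean PSD on (1, 3] Hz.

    Welch estimate with ~60 s segments and 50% overlap (frequency
    resolution <= 0.05 Hz at 30 Hz sampling).
    """
    dff = np.asarray(dff, dtype=float)
    nperseg = int(round(segment_s * frame_rate_hz))
    if dff.shape[0] < nperseg // 2:
        raise ValueError(
            f"trace length {dff.shape[0]} too short for one {segment_s:.0f}s segment"
        )
    nperseg = min(nperseg, dff.shape[0])
    freqs, psd = welch(dff, fs=frame_rate_hz, nperseg=nperseg)
    sig_band = (freqs >= 0.5) & (freqs <= 1.0)
    noise_band = (freqs > 1.0) & (freqs <= 3.0)
    if not sig_band.any() or not noise_band.any():
        raise ValueError("frequency resolution too coarse for SNR bands")
    return float(np.max(psd[sig_band]) / np.mean(psd[noise_band]))


def snr_filter(axon_snrs: np.ndarray, bleb_snrs: np.ndarray,
               sd_factor: float = SNR_SD_FACTOR) -> tuple:
    """Pass mask for axons against the bleb-derived threshold.

    threshold = mean(blebs) + sd_factor * sd(blebs, ddof=1); an axon passes
    iff its SNR is strictly greater than the threshold.
    """
    bleb_snrs = np.asarray(bleb_snrs, dtype=float)
    if bleb_snrs.shape[0] < 2:
        raise ValueError("need at least 2 bleb SNRs to define a threshold")
    threshold = float(np.mean(bleb_snrs) + sd_factor * np.std(bleb_snrs, ddof=1))
    passed = np.asarray(axon_snrs, dtype=float) > threshold
    return passed, threshold


@dataclass
class ShiftFlag:
    flagged: bool
    change_frame: int | None = None
    run_length: int | None = None


def detect_sustained_shift(
    dff: np.ndarray,
    min_run: int = SHIFT_MIN_RUN,
    end_run: int = SHIFT_END_RUN,
    k_sd: float = 0.5,
    h_sd: float = 5.0,
    mean_window: int = 100,
) -> ShiftFlag:
    """Flag a sustained upward shift in mean activity.

    A one-sided CUSUM on the (robustly) standardized trace proposes upward
    change points (slack ``k_sd`` sd, decision threshold ``h_sd`` sd). A
    candidate is confirmed iff a rolling mean stays above the pre-change
    mean + 1 pre-change sd for at least ``min_run`` consecutive frames, or
    for at least ``end_run`` frames reaching the end of the trace.
    """
    x = np.asarray(dff, dtype=float)
    n = x.shape[0]
    if n <= end_run:
        raise ValueError(f"trace length {n} must exceed end_run {end_run}")

    med = np.median(x)
    sigma = 1.4826 * np.median(np.abs(x - med))
    if sigma <= 0:
        sigma = np.std(x)
    if sigma <= 0:
        return ShiftFlag(False)
    z = (x - med) / sigma

    roll = pd.Series(x).rolling(mean_window, min_periods=1).mean().to_numpy()

    start = 0
    while start < n:
        zs = z[start:]
        c = np.cumsum(zs - k_sd)
        prefix = np.minimum.accumulate(np.concatenate([[0.0], c]))[:-1]
        s = c - prefix
        crossings = np.flatnonzero(s > h_sd)
        if crossings.size == 0:
            return ShiftFlag(False)
        t_cross = int(crossings[0])
        # change point: frame after the prefix minimum preceding the crossing
        pre = np.concatenate([[0.0], c])[: t_cross + 1]
        change = start + int(np.argmin(pre))

        pre_seg = x[:change] if change > 0 else x[: max(1, mean_window)]
        mu0 = float(np.mean(pre_seg))
        sd0 = float(np.std(pre_seg, ddof=1)) if pre_seg.size > 1 else sigma
        if sd0 <= 0:
            sd0 = sigma
        elevated = roll > mu0 + sd0

        t = max(change, start)
        run = 0
        while t + run < n and elevated[t + run]:
            run += 1
        if run >= min_run or (t + run == n and run >= end_run):
            return ShiftFlag(True, change_frame=change, run_length=run)
        start = start + t_cross + 1
    return ShiftFlag(False)


def normalize_quantile(dff: np.ndarray, q_lo: float = 0.01, q_hi: float = 0.99) -> np.ndarray:
    """Scale by the 1st/99th quantile span: (x - q01) / (q99 - q01).

    Values outside [0, 1] are permitted (no clipping). Quantiles use linear
    interpolation between order statistics.
    """
    x = np.asarray(dff, dtype=float)
    lo, hi = np.quantile(x, [q_lo, q_hi])
    if hi == lo:
        raise ValueError("degenerate trace: 1st and 99th quantiles coincide")
    return (x - lo) / (hi - lo)


def normalize_mean(dff: np.ndarray) -> np.ndarray:
    """Scale by the trace mean; the output averages to exactly 1."""
    x = np.asarray(dff, dtype=float)
    m = np.mean(x)
    if m == 0:
        raise ValueError("trace mean is zero; cannot mean-normalize")
    return x / m


@dataclass
class QcRow:
    roi_id: str
    kind: str
    snr: float
    passed_snr: bool
    shift_flag: bool
    change_frame: int | None
    run_length: int | None
    merged_into: str | None
    included_final: bool


@dataclass
class QcReport:
    rows: list
    snr_threshold: float
    params: dict = field(default_factory=dict)

    def included_ids(self) -> list:
        return [r.roi_id for r in self.rows if r.included_final]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def run_qc(session, short_window: int = DFF_SHORT_WINDOW,
           long_window: int = DFF_LONG_WINDOW,
           percentile: float = BASELINE_PERCENTILE,
           r_min: float = MERGE_R_MIN,
           sd_factor: float = SNR_SD_FACTOR,
           min_run: int = SHIFT_MIN_RUN,
           end_run: int = SHIFT_END_RUN) -> QcReport:
    """Full QC pass over a session, in place.

    Merges correlated axons, computes both dF/F variants and the
    normalized traces, applies the bleb SNR threshold and the sustained
    shift exclusion. ``session.rois`` is replaced by the merged set.
    """
    n = session.n_frames
    sw = min(short_window, n)
    lw = min(long_window, n)

    merged_into: dict = {}
    merged = merge_correlated_rois(session.rois, r_min=r_min, dff_window=lw)
    for r in merged:
        for src in r.merged_from:
            merged_into[src] = r.roi_id
    session.rois = merged

    for r in session.rois:
        r.dff_short = compute_dff(r.raw_f, sw, percentile)
        r.dff_long = compute_dff(r.raw_f, lw, percentile)

    snrs = {r.roi_id: compute_snr(r.dff_long, session.frame_rate_hz) for r in session.rois}
    bleb_snrs = np.array([snrs[r.roi_id] for r in session.blebs()])
    axons = session.axons()
    axon_snrs = np.array([snrs[r.roi_id] for r in axons])
    passed, threshold = snr_filter(axon_snrs, bleb_snrs, sd_factor)
    passed_map = {r.roi_id: bool(p) for r, p in zip(axons, passed)}

    rows = []
    for r in session.rois:
        is_axon = r.kind == "axon"
        p = passed_map.get(r.roi_id, False)
        flag = ShiftFlag(False)
        if is_axon and p:
            flag = detect_sustained_shift(r.dff_long, min_run=min_run, end_run=end_run)
        included = is_axon and p and not flag.flagged
        if included:
            r.norm_q = normalize_quantile(r.dff_short)
            r.norm_mean = normalize_mean(r.dff_long)
        rows.append(
            QcRow(
                roi_id=r.roi_id,
                kind=r.kind,
                snr=snrs[r.roi_id],
                passed_snr=p,
                shift_flag=flag.flagged,
                change_frame=flag.change_frame,
                run_length=flag.run_length,
                merged_into=merged_into.get(r.roi_id),
                included_final=included,
            )
        )
    return QcReport(
        rows=rows,
        snr_threshold=threshold,
        params={
            "short_window": sw,
            "long_window": lw,
            "percentile": percentile,
            "r_min": r_min,
            "sd_factor": sd_factor,
            "min_run": min_run,
            "end_run": end_run,
        },
    )
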