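"""Statistical machinery: OLS with F tests, resampling comparison,
ANCOVA/ANOVA with Tukey HSD, and the shuffle-bootstrap null band.

The shuffle null circularly rotates each full-session trace by a uniform
random offset (at least 30 s), which preserves the marginal distribution
and autocorrelation while destroying event alignment. Each subsample
repetition averages a without-replacement draw of shuffled traces; the band
is the empirical 2.5-97.5 percentile across repetitions, per point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RegressionFit",
    "ResampleCloud",
    "ShuffleBaseline",
    "SignificantRuns",
    "GroupComparison",
    "fit_linear",
    "classify_roi_fits",
    "resample_comparison",
    "ancova_slopes",
    "anova_tukey",
    "shuffle_baseline",
    "detect_significant_runs",
]

log = logging.getLogger(__name__)

N_SHUFFLES = 1000
N_SUBSAMPLE_REPS = 1000
MIN_SHIFT_S = 30.0
ALPHA = 0.05


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    F_stat: float
    p_value: float
    n_points: int
    dof_resid: int


def fit_linear(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares y = a + b*x with an F test of b = 0.

    NaN pairs are dropped first; requires >= 3 finite pairs and non-zero
    variance in x. F has (1, n-2) degrees of freedom.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 finite points, got {n}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("zero variance in x")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    ssr = float(slope * sxy)
    dof = n - 2
    if sse <= 0:
        f_stat, p = float("inf"), 0.0
        if ssr == 0:  # y constant: no effect at all
            f_stat, p = 0.0, 1.0
    else:
        f_stat = ssr / (sse / dof)
        p = float(stats.f.sf(f_stat, 1, dof))
    return RegressionFit(float(slope), float(intercept), float(f_stat), p, n, dof)


def classify_roi_fits(fits: list, alpha: float = ALPHA) -> dict:
    """Count per-ROI regressions as positive / negative / ns at ``alpha``."""
    counts = {"positive": 0, "negative": 0, "ns": 0}
    labels = []
    for f in fits:
        if f.p_value < alpha and f.slope > 0:
            lab = "positive"
        elif f.p_value < alpha and f.slope < 0:
            lab = "negative"
        else:
            lab = "ns"
        counts[lab] += 1
        labels.append(lab)
    counts["labels"] = labels
    return counts


@dataclass
class ResampleCloud:
    subsample_n: int
    n_reps: int
    slopes: np.ndarray
    intercepts: np.ndarray
    reference_slope: float
    reference_intercept: float
    contained: bool
    slope_interval: tuple
    intercept_interval: tuple


def resample_comparison(roi_points: list, subsample_n: int,
                        reference_fit: RegressionFit, n_reps: int = N_SUBSAMPLE_REPS,
                        seed: int = 0) -> ResampleCloud:
    """Down-sampled regression cloud versus a reference fit.

    ``roi_points`` is a list of ``(x, y)`` arrays, one per ROI of the larger
    population. Each repetition draws ``subsample_n`` ROIs without
    replacement, pools their points, and fits one regression. Containment:
    the reference (slope, intercept) falls inside the per-axis 2.5-97.5
    percentile box of the cloud.
    """
    n_pop = len(roi_points)
    if subsample_n >= n_pop:
        raise ValueError(f"subsample_n {subsample_n} must be < population size {n_pop}")
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_reps)
    intercepts = np.empty(n_reps)
    for rep in range(n_reps):
        pick = rng.choice(n_pop, size=subsample_n, replace=False)
        xs = np.concatenate([np.asarray(roi_points[i][0], float).ravel() for i in pick])
        ys = np.concatenate([np.asarray(roi_points[i][1], float).ravel() for i in pick])
        fit = fit_linear(xs, ys)
        slopes[rep] = fit.slope
        intercepts[rep] = fit.intercept
    s_lo, s_hi = np.percentile(slopes, [2.5, 97.5])
    i_lo, i_hi = np.percentile(intercepts, [2.5, 97.5])
    contained = bool(
        s_lo <= reference_fit.slope <= s_hi and i_lo <= reference_fit.intercept <= i_hi
    )
    return ResampleCloud(
        subsample_n=subsample_n,
        n_reps=n_reps,
        slopes=slopes,
        intercepts=intercepts,
        reference_slope=reference_fit.slope,
        reference_intercept=reference_fit.intercept,
        contained=contained,
        slope_interval=(float(s_lo), float(s_hi)),
        intercept_interval=(float(i_lo), float(i_hi)),
    )


@dataclass
class GroupComparison:
    kind: str                       # "ancova_slopes" | "anova_means"
    omnibus_F: float
    omnibus_p: float
    pairwise: list                  # [(a, b, estimate, adjusted_p), ...]
    group_stats: dict = field(default_factory=dict)


def ancova_slopes(groups: list) -> GroupComparison:
    """Compare regression slopes across groups (one-way ANCOVA).

    ``groups`` is ``[(label, x, y), ...]``. Omnibus: F test of the
    group-by-covariate interaction (full model with per-group slopes versus
    common slope). Pairwise slope differences use Tukey HSD via the
    studentized range on the per-group slope estimates with pooled residual
    variance from the full model.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels, xs, ys = [], [], []
    for label, x, y in groups:
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.shape[0] < 3:
            raise ValueError(f"group {label!r} has fewer than 3 finite points")
        if np.sum((x - x.mean()) ** 2) == 0:
            raise ValueError(f"group {label!r} has zero covariate variance")
        labels.append(label)
        xs.append(x)
        ys.append(y)

    k = len(labels)
    n_total = sum(x.shape[0] for x in xs)

    # full model: separate intercept and slope per group
    sse_full = 0.0
    slopes, slope_vars_sxx = [], []
    for x, y in zip(xs, ys):
        fit = np.polyfit(x, y, 1)
        resid = y - (fit[0] * x + fit[1])
        sse_full += float(np.sum(resid**2))
        slopes.append(float(fit[0]))
        slope_vars_sxx.append(float(np.sum((x - x.mean()) ** 2)))

    # reduced model: per-group intercepts, one common slope
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    g_all = np.concatenate([np.full(x.shape[0], i) for i, x in enumerate(xs)])
    design_r = np.zeros((n_total, k + 1))
    for i in range(k):
        design_r[g_all == i, i] = 1.0
    design_r[:, k] = x_all
    beta_r, _, _, _ = np.linalg.lstsq(design_r, y_all, rcond=None)
    sse_red = float(np.sum((y_all - design_r @ beta_r) ** 2))

    dof_full = n_total - 2 * k
    if dof_full <= 0:
        raise ValueError("not enough points for the full interaction model")
    num = (sse_red - sse_full) / (k - 1)
    den = sse_full / dof_full
    if den <= 0:
        omnibus_f, omnibus_p = float("inf"), 0.0
    else:
        omnibus_f = num / den
        omnibus_p = float(stats.f.sf(omnibus_f, k - 1, dof_full))

    s2 = sse_full / dof_full
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = slopes[i] - slopes[j]
            se2 = s2 / slope_vars_sxx[i] + s2 / slope_vars_sxx[j]
            if se2 <= 0:
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / np.sqrt(se2 / 2.0)
                p_adj = float(stats.studentized_range.sf(q, k, dof_full))
            pairwise.append((labels[i], labels[j], float(diff), min(1.0, p_adj)))

    return GroupComparison(
        kind="ancova_slopes",
        omnibus_F=float(omnibus_f),
        omnibus_p=omnibus_p,
        pairwise=pairwise,
        group_stats={lab: {"slope": s, "n": x.shape[0]}
                     for lab, s, x in zip(labels, slopes, xs)},
    )


def anova_tukey(groups: dict, reference=None) -> GroupComparison:
    """One-way ANOVA across groups with Tukey HSD pairwise comparisons.

    ``groups`` maps label -> observations (e.g. one lap metric per mouse).
    Groups with fewer than 2 observations are dropped with a log line. If
    ``reference`` is given, pairwise results are restricted to comparisons
    against it.
    """
    clean = {}
    for lab, vals in groups.items():
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        if v.shape[0] < 2:
            log.info("anova_tukey: dropping group %r with %d observations", lab, v.shape[0])
            continue
        clean[lab] = v
    if len(clean) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")

    labels = list(clean)
    k = len(labels)
    all_vals = np.concatenate([clean[lab] for lab in labels])
    n_total = all_vals.shape[0]
    grand = all_vals.mean()

    ss_between = sum(
        clean[lab].shape[0] * (clean[lab].mean() - grand) ** 2 for lab in labels
    )
    ss_within = sum(np.sum((clean[lab] - clean[lab].mean()) ** 2) for lab in labels)
    df_b, df_w = k - 1, n_total - k
    msw = ss_within / df_w
    if msw <= 0:
        omnibus_f = float("inf") if ss_between > 0 else 0.0
        omnibus_p = 0.0 if ss_between > 0 else 1.0
    else:
        omnibus_f = (ss_between / df_b) / msw
        omnibus_p = float(stats.f.sf(omnibus_f, df_b, df_w))

    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            if reference is not None and reference not in (a, b):
                continue
            diff = clean[a].mean() - clean[b].mean()
            if msw <= 0:
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / clean[a].shape[0] + 1.0 / clean[b].shape[0]))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
            pairwise.append((a, b, float(diff), min(1.0, p_adj)))

    return GroupComparison(
        kind="anova_means",
        omnibus_F=float(omnibus_f),
        omnibus_p=float(omnibus_p),
        pairwise=pairwise,
        group_stats={lab: {"mean": float(clean[lab].mean()), "n": clean[lab].shape[0]}
                     for lab in labels},
    )


@dataclass
class ShuffleBaseline:
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_shuffles: int
    n_subsample_reps: int
    subsample_n: int


def shuffle_baseline(traces: np.ndarray, subsample_n: int,
                     frame_rate_hz: float,
                     n_shuffles: int = N_SHUFFLES,
                     n_subsample_reps: int = N_SUBSAMPLE_REPS,
                     seed: int = 0,
                     min_shift_s: float = MIN_SHIFT_S,
                     transform=None) -> ShuffleBaseline:
    """Shuffle-bootstrap null band for a population-mean series.

    Builds a pool of ``n_shuffles`` circularly rotated traces (random ROI,
    random offset >= ``min_shift_s``), optionally maps each through
    ``transform`` (e.g. alignment slicing and binning — any linear
    per-trace reduction), then for each of ``n_subsample_reps`` repetitions
    averages a without-replacement draw of ``subsample_n`` pool entries.
    The band is the per-point 2.5/97.5 percentile across repetitions.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    n_traces, n = traces.shape
    if subsample_n > n_traces:
        raise ValueError(f"subsample_n {subsample_n} exceeds available traces {n_traces}")
    if subsample_n > n_shuffles:
        raise ValueError("subsample_n exceeds the shuffle pool size")
    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * frame_rate_hz))
    if 2 * min_shift >= n:
        min_shift = max(1, n // 4)

    pool = np.empty((n_shuffles, n))
    roi_pick = rng.integers(0, n_traces, size=n_shuffles)
    offsets = rng.integers(min_shift, n - min_shift, size=n_shuffles)
    for i in range(n_shuffles):
        pool[i] = np.roll(traces[roi_pick[i]], offsets[i])

    if transform is not None:
        pool = np.vstack([np.asarray(transform(row), float) for row in pool])

    width = pool.shape[1]
    rep_means = np.empty((n_subsample_reps, width))
    for rep in range(n_subsample_reps):
        pick = rng.choice(n_shuffles, size=subsample_n, replace=False)
        with np.errstate(invalid="ignore"):
            rep_means[rep] = np.nanmean(pool[pick], axis=0)

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(rep_means, axis=0)
        # median-unbiased percentile estimator: extreme quantiles from a
        # finite rep set are otherwise biased toward the bulk
        ci_lo, ci_hi = np.nanpercentile(rep_means, [2.5, 97.5], axis=0,
                                        method="median_unbiased")
    return ShuffleBaseline(
        mean=mean, ci_lo=ci_lo, ci_hi=ci_hi,
        n_shuffles=n_shuffles, n_subsample_reps=n_subsample_reps,
        subsample_n=subsample_n,
    )


@dataclass
class SignificantRuns:
    segments: list                  # [(start, end), ...] half-open
    min_run: int
    durations: list                 # same units as the series sampling

    def durations_s(self, frame_rate_hz: float) -> list:
        return [d / frame_rate_hz for d in self.durations]


def detect_significant_runs(series: np.ndarray, baseline: ShuffleBaseline,
                            min_run: int = 2) -> SignificantRuns:
    """Maximal runs of consecutive points above the upper CI, length >= min_run."""
    series = np.asarray(series, float)
    if series.shape[0] != baseline.ci_hi.shape[0]:
        raise ValueError("series and baseline are not aligned")
    above = np.isfinite(series) & (series > baseline.ci_hi)
    segments = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                segments.append((start, i))
            start = None
    if start is not None and above.shape[0] - start >= min_run:
        segments.append((start, above.shape[0]))
    return SignificantRuns(
        segments=segments,
        min_run=min_run,
        durations=[b - a for a, b in segments],
    )
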