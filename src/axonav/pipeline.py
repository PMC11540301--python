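"""End-to-end pipeline: simulate/load -> QC -> behavior -> tuning -> stats.

Every analysis constant lives in :class:`PipelineConfig`; the config (and
the root seed) fully determines every emitted number, and the output
tables are written with fixed float formatting so reruns are byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bh
from . import inference as inf
from . import trace_qc as qc
from . import tuning as tn
from .session import read_session, write_session
from .simulate import SimConfig, make_cohort

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "make_report", "demo_config"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


@dataclass
class PipelineConfig:
    """All thresholds and bookkeeping for one pipeline run."""

    input_dir: str | None = None          # read sessions from here...
    sim: SimConfig | None = None          # ...or simulate a cohort
    out_dir: str = "axonav_out"
    seed: int = 0

    # behavior
    immobile_cm_s: float = 5.0
    stationary_cm_s: float = 0.2
    onset_still_s: float = 1.5
    onset_run_s: float = 3.0
    # qc
    merge_r_min: float = 0.7
    snr_sd_factor: float = 1.5
    dff_short_window: int = 300
    dff_long_window: int = 2000
    shift_min_run: int = 2000
    shift_end_run: int = 500
    # tuning
    position_bin_cm: float = 5.0
    velocity_bin_cm_s: float = 1.0
    velocity_range: tuple = (1.0, 30.0)
    onset_window_s: tuple = (-2.0, 3.0)
    premotion_window_s: float = 2.0
    aligned_bin_frames: int = 50
    switch_window_s: tuple = (-120.0, 180.0)
    # inference
    alpha: float = 0.05
    n_shuffles: int = 1000
    n_subsample_reps: int = 1000
    min_run_frames: int = 2
    min_run_bins: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("velocity_range", "onset_window_s", "switch_window_s"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def demo_config(out_dir: str = "axonav_demo_out", seed: int = 7) -> PipelineConfig:
    """Small packaged demo: 2 LC-like sessions, reduced shuffle reps."""
    from .simulate import EncodingPrior

    sim = SimConfig(
        n_sessions=2,
        axons_per_session=10,
        blebs_per_session=3,
        source="LC",
        track_length_cm=300.0,
        familiar_duration_s=180.0,
        novel_duration_s=120.0,
        encoding=EncodingPrior(
            ramp_gain=(0.0, 0.0),
            velocity_gain=(0.02, 0.06),
            premotion_gain=(0.3, 0.8),
            novelty_amp=(0.5, 1.5),
        ),
        unhealthy_fraction=0.1,
        seed=seed,
    )
    return PipelineConfig(
        sim=sim, out_dir=out_dir, seed=seed,
        n_shuffles=100, n_subsample_reps=100,
        switch_window_s=(-60.0, 90.0),
    )


@dataclass
class ResultsBundle:
    config: PipelineConfig
    qc_reports: dict = field(default_factory=dict)
    lap_summaries: dict = field(default_factory=dict)
    tuning_curves: dict = field(default_factory=dict)    # (env, covariate) -> per-ROI curves
    population_fits: dict = field(default_factory=dict)
    roi_fits: dict = field(default_factory=dict)
    classifications: dict = field(default_factory=dict)
    resample_cloud: inf.ResampleCloud | None = None
    novelty: dict = field(default_factory=dict)
    behavior_anova: dict = field(default_factory=dict)
    lapwise_ancova: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_sessions(cfg: PipelineConfig):
    if cfg.sim is not None:
        sessions, truth = make_cohort(cfg.sim)
        return sessions, truth
    if cfg.input_dir is None:
        raise ValueError("PipelineConfig needs input_dir or sim")
    sessions = []
    for name in sorted(os.listdir(cfg.input_dir)):
        path = os.path.join(cfg.input_dir, name)
        if os.path.isdir(path) and os.path.exists(os.path.join(path, "session.json")):
            sessions.append(read_session(path))
    if not sessions:
        raise ValueError(f"no session directories under {cfg.input_dir!r}")
    return sessions, None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage=%s event=start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage=%s event=done", name)
            return out
        return wrapper
    return deco


def _population_points(curves: dict) -> tuple:
    """Pool (bin value, across-lap ROI-bin mean) points across ROIs."""
    xs, ys = [], []
    for curve in curves.values():
        x = curve.bin_centers
        y = curve.mean
        ok = np.isfinite(y)
        xs.append(x[ok])
        ys.append(y[ok])
    return np.concatenate(xs), np.concatenate(ys)


def _roi_lap_points(curve: tn.TuningCurve) -> tuple:
    """Per-ROI regression sample: lap x bin matrix flattened."""
    laps, bins = curve.per_lap.shape
    x = np.tile(curve.bin_centers, laps)
    y = curve.per_lap.ravel()
    ok = np.isfinite(y)
    return x[ok], y[ok]


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Execute every stage and write the results bundle under cfg.out_dir."""
    bundle = ResultsBundle(config=cfg)
    rng_root = np.random.SeedSequence(cfg.seed)
    os.makedirs(cfg.out_dir, exist_ok=True)

    sessions, truth = _stage("load")(_load_sessions)(cfg)

    derived = {}
    for s in sessions:
        derived[s.session_id] = _stage("behavior")(bh.derive_behavior)(
            s, cfg.immobile_cm_s, cfg.stationary_cm_s
        )

    for s in sessions:
        bundle.qc_reports[s.session_id] = _stage("qc")(qc.run_qc)(
            s,
            short_window=cfg.dff_short_window,
            long_window=cfg.dff_long_window,
            r_min=cfg.merge_r_min,
            sd_factor=cfg.snr_sd_factor,
            min_run=cfg.shift_min_run,
            end_run=cfg.shift_end_run,
        )

    # ---- per-lap behavior metrics
    for s in sessions:
        d = derived[s.session_id]
        bundle.lap_summaries[s.session_id] = bh.lap_metrics(
            d.velocity_cm_s, d.laps, s.env_per_frame(), cfg.immobile_cm_s
        )

    # ---- tuning curves per included ROI, per environment
    envs_present = sorted({lab for s in sessions for lab, _ in s.env_schedule
                           if lab != "dark"})
    included = {
        s.session_id: set(bundle.qc_reports[s.session_id].included_ids())
        for s in sessions
    }

    def curves_for(env: str, covariate: str) -> dict:
        out = {}
        for s in sessions:
            d = derived[s.session_id]
            env_pf = s.env_per_frame()
            for r in s.rois:
                if r.roi_id not in included[s.session_id]:
                    continue
                key = f"{s.session_id}/{r.roi_id}"
                try:
                    if covariate == "position":
                        out[key] = tn.bin_by_position(
                            r.norm_q, s.behavior.position_cm, d.laps, env_pf, env,
                            s.track_length_cm, cfg.position_bin_cm)
                    elif covariate == "velocity":
                        out[key] = tn.bin_by_velocity(
                            r.norm_q, d.velocity_cm_s, d.laps, env_pf, env,
                            cfg.velocity_bin_cm_s, cfg.velocity_range)
                except ValueError as exc:
                    log.info("skip curve %s %s/%s: %s", covariate, env, key, exc)
        return out

    stage_tuning = _stage("tuning")(lambda: None)
    stage_tuning()
    for env in envs_present:
        for cov in ("position", "velocity"):
            curves = curves_for(env, cov)
            if curves:
                bundle.tuning_curves[(env, cov)] = curves

    # motion-onset aligned per ROI (familiar)
    onset_curves = {}
    for s in sessions:
        d = derived[s.session_id]
        events = bh.detect_motion_onsets(
            d.velocity_cm_s, s.frame_rate_hz, cfg.immobile_cm_s,
            cfg.onset_still_s, cfg.onset_run_s)
        env_pf = s.env_per_frame()
        fam_events = [e for e in events if env_pf[e.onset_frame] == "familiar"]
        for r in s.rois:
            if r.roi_id not in included[s.session_id]:
                continue
            try:
                mat = tn.align_to_motion_onset(
                    r.norm_q, fam_events, s.frame_rate_hz, cfg.onset_window_s)
                onset_curves[f"{s.session_id}/{r.roi_id}"] = mat
            except ValueError as exc:
                log.info("skip onset alignment for %s/%s: %s", s.session_id, r.roi_id, exc)
    bundle.tuning_curves[("familiar", "motion_onset")] = onset_curves

    # ---- regression analyses
    def fits_stage():
        for (env, cov), curves in bundle.tuning_curves.items():
            if cov == "motion_onset":
                pts_x, pts_y, roi_fits = [], [], {}
                for key, mat in curves.items():
                    t, vals = mat.segment(-cfg.premotion_window_s, 0.0)
                    mean_curve = vals.mean(axis=0)
                    pts_x.append(t)
                    pts_y.append(mean_curve)
                    try:
                        roi_fits[key] = inf.fit_linear(t, mean_curve)
                    except ValueError:
                        pass
                if pts_x:
                    bundle.population_fits[(env, cov)] = inf.fit_linear(
                        np.concatenate(pts_x), np.concatenate(pts_y))
                    bundle.roi_fits[(env, cov)] = roi_fits
                    bundle.classifications[(env, cov)] = inf.classify_roi_fits(
                        list(roi_fits.values()), cfg.alpha)
                continue
            x, y = _population_points(curves)
            if x.size >= 3:
                bundle.population_fits[(env, cov)] = inf.fit_linear(x, y)
            roi_fits = {}
            for key, curve in curves.items():
                try:
                    roi_fits[key] = inf.fit_linear(*_roi_lap_points(curve))
                except ValueError:
                    pass
            bundle.roi_fits[(env, cov)] = roi_fits
            bundle.classifications[(env, cov)] = inf.classify_roi_fits(
                list(roi_fits.values()), cfg.alpha)

    _stage("regression")(fits_stage)()

    # resample cloud: population versus a VTA-sized subset (n=9 reference)
    pos_curves = bundle.tuning_curves.get(("familiar", "position"), {})
    if len(pos_curves) > 10:
        keys = sorted(pos_curves)
        roi_points = [_roi_lap_points(pos_curves[k]) for k in keys]
        ref = bundle.population_fits.get(("familiar", "position"))
        if ref is not None:
            bundle.resample_cloud = _stage("resample")(inf.resample_comparison)(
                roi_points, subsample_n=9, reference_fit=ref,
                n_reps=cfg.n_subsample_reps,
                seed=int(rng_root.spawn(1)[0].generate_state(1)[0]),
            )

    # ---- novelty analysis (per session with a novel segment)
    def novelty_stage():
        out = {}
        for s in sessions:
            sched = dict(s.env_schedule)
            if "novel" not in sched:
                continue
            switch = sched["novel"]
            d = derived[s.session_id]
            rois = [r for r in s.rois if r.roi_id in included[s.session_id]]
            if len(rois) < 2:
                continue
            traces = np.vstack([r.norm_mean for r in rois])
            seed = int(rng_root.spawn(1)[0].generate_state(1)[0])
            res = {}
            for variant, mask in (("all", None),
                                  ("running", ~d.stationary_02)):
                try:
                    mat = tn.align_to_transition(
                        traces, switch, s.frame_rate_hz, cfg.switch_window_s,
                        frame_mask=mask,
                        row_ids=[r.roi_id for r in rois])
                except ValueError as exc:
                    log.info("novelty variant %s skipped for %s: %s",
                             variant, s.session_id, exc)
                    continue

                def transform(trace, mask=mask):
                    m = tn.align_to_transition(
                        trace[None, :], switch, s.frame_rate_hz,
                        cfg.switch_window_s, frame_mask=mask)
                    return np.where(m.valid[0], m.values[0], np.nan)

                base = inf.shuffle_baseline(
                    traces, subsample_n=len(rois),
                    frame_rate_hz=s.frame_rate_hz,
                    n_shuffles=cfg.n_shuffles,
                    n_subsample_reps=cfg.n_subsample_reps,
                    seed=seed, transform=transform)
                runs = inf.detect_significant_runs(
                    mat.population_mean, base, cfg.min_run_frames)

                binned = tn.bin_aligned(mat, "frames", cfg.aligned_bin_frames)
                lap_binned = tn.bin_aligned(mat, "lap", lap_index=d.laps.index)
                res[variant] = {
                    "aligned": mat, "baseline": base, "runs": runs,
                    "binned_frames": binned, "binned_lap": lap_binned,
                }
            if res:
                out[s.session_id] = res
        return out

    bundle.novelty = _stage("novelty")(novelty_stage)()

    # ---- behavior ANOVA: lap metric vs final familiar lap, across sessions
    def behavior_anova_stage():
        out = {}
        for metric in ("mean_moving_velocity_cm_s", "freezing_ratio"):
            groups: dict = {}
            for s in sessions:
                summaries = bundle.lap_summaries[s.session_id]
                fam = [ls for ls in summaries if ls.env == "familiar"]
                nov = [ls for ls in summaries if ls.env == "novel"]
                if not fam or not nov:
                    continue
                groups.setdefault("fam_last", []).append(getattr(fam[-1], metric))
                for i, ls in enumerate(nov[:10]):
                    groups.setdefault(f"nov_{i + 1}", []).append(getattr(ls, metric))
            if len(groups) >= 2:
                try:
                    out[metric] = inf.anova_tukey(groups, reference="fam_last")
                except ValueError as exc:
                    log.info("behavior anova for %s skipped: %s", metric, exc)
        return out

    bundle.behavior_anova = _stage("behavior_stats")(behavior_anova_stage)()

    # ---- lap-by-lap ANCOVA: familiar (last laps) vs first novel laps, position
    def lapwise_stage():
        out = {}
        curves_fam = bundle.tuning_curves.get(("familiar", "position"), {})
        curves_nov = bundle.tuning_curves.get(("novel", "position"), {})
        if not curves_fam or not curves_nov:
            return out
        shared = sorted(set(curves_fam) & set(curves_nov))
        if not shared:
            return out

        def pooled(curves, keys, lap_sel=None):
            xs, ys = [], []
            for k in keys:
                c = curves[k]
                per_lap = c.per_lap if lap_sel is None else c.per_lap[lap_sel(c), :]
                laps = per_lap.shape[0]
                x = np.tile(c.bin_centers, laps)
                y = per_lap.ravel()
                ok = np.isfinite(y)
                xs.append(x[ok])
                ys.append(y[ok])
            return np.concatenate(xs), np.concatenate(ys)

        groups = [("fam_last", *pooled(curves_fam, shared,
                                       lambda c: slice(max(0, c.per_lap.shape[0] - 4), None)))]
        max_novel = min(3, min(curves_nov[k].per_lap.shape[0] for k in shared))
        for lap in range(max_novel):
            groups.append((f"nov_{lap + 1}",
                           *pooled(curves_nov, shared, lambda c, lap=lap: slice(lap, lap + 1))))
        try:
            out["position"] = inf.ancova_slopes(groups)
        except ValueError as exc:
            log.info("lapwise ancova skipped: %s", exc)
        return out

    bundle.lapwise_ancova = _stage("lapwise_ancova")(lapwise_stage)()

    _stage("export")(_export_bundle)(bundle, sessions, truth)
    return bundle


def _analysis_config(cfg: PipelineConfig) -> dict:
    """Config dict without execution paths: what the numbers depend on."""
    d = cfg.to_dict()
    d.pop("out_dir", None)
    d.pop("input_dir", None)
    return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(_analysis_config(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _export_bundle(bundle: ResultsBundle, sessions, truth) -> None:
    cfg = bundle.config
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(os.path.join(out, name), index=False,
                  float_format=_FLOAT_FMT, lineterminator="\n")

    qc_rows = []
    for sid, rep in bundle.qc_reports.items():
        df = rep.to_frame()
        df.insert(0, "session_id", sid)
        df["snr_threshold"] = rep.snr_threshold
        qc_rows.append(df)
    if qc_rows:
        save(pd.concat(qc_rows, ignore_index=True), "qc_report.csv")

    lap_rows = []
    for sid, summaries in bundle.lap_summaries.items():
        for ls in summaries:
            lap_rows.append({"session_id": sid, **vars(ls)})
    if lap_rows:
        save(pd.DataFrame(lap_rows), "lap_summaries.csv")

    curve_rows = []
    for (env, cov), curves in bundle.tuning_curves.items():
        if cov == "motion_onset":
            for key, mat in curves.items():
                mean = mat.values.mean(axis=0)
                for t, v in zip(mat.time_axis_s, mean):
                    curve_rows.append({"env": env, "covariate": cov, "roi": key,
                                       "bin": t, "value": v})
            continue
        for key, curve in curves.items():
            for c, v in zip(curve.bin_centers, curve.mean):
                curve_rows.append({"env": env, "covariate": cov, "roi": key,
                                   "bin": c, "value": v})
    if curve_rows:
        save(pd.DataFrame(curve_rows), "tuning_curves.csv")

    fit_rows = []
    for (env, cov), fit in bundle.population_fits.items():
        fit_rows.append({"env": env, "covariate": cov, "level": "population",
                         "roi": "", **vars(fit)})
    for (env, cov), fits in bundle.roi_fits.items():
        for key, fit in fits.items():
            fit_rows.append({"env": env, "covariate": cov, "level": "roi",
                             "roi": key, **vars(fit)})
    if fit_rows:
        save(pd.DataFrame(fit_rows), "regression_fits.csv")

    class_rows = []
    for (env, cov), counts in bundle.classifications.items():
        class_rows.append({"env": env, "covariate": cov,
                           "positive": counts["positive"],
                           "negative": counts["negative"], "ns": counts["ns"]})
    if class_rows:
        save(pd.DataFrame(class_rows), "classifications.csv")

    if bundle.resample_cloud is not None:
        rc = bundle.resample_cloud
        save(pd.DataFrame({"slope": rc.slopes, "intercept": rc.intercepts}),
             "resample_cloud.csv")

    nov_rows = []
    for sid, variants in bundle.novelty.items():
        for variant, res in variants.items():
            base = res["baseline"]
            mat = res["aligned"]
            series = mat.population_mean
            for i, t in enumerate(mat.time_axis_s):
                nov_rows.append({"session_id": sid, "variant": variant, "time_s": t,
                                 "mean": series[i], "base_mean": base.mean[i],
                                 "ci_lo": base.ci_lo[i], "ci_hi": base.ci_hi[i]})
    if nov_rows:
        save(pd.DataFrame(nov_rows), "novelty_aligned.csv")

    run_rows = []
    for sid, variants in bundle.novelty.items():
        for variant, res in variants.items():
            for a, b in res["runs"].segments:
                run_rows.append({"session_id": sid, "variant": variant,
                                 "start": a, "end": b, "n_frames": b - a})
    save(pd.DataFrame(run_rows, columns=["session_id", "variant", "start", "end",
                                         "n_frames"]), "novelty_runs.csv")

    stat_rows = []
    for name, comp in {**{f"anova/{k}": v for k, v in bundle.behavior_anova.items()},
                       **{f"ancova/{k}": v for k, v in bundle.lapwise_ancova.items()}}.items():
        stat_rows.append({"analysis": name, "kind": comp.kind, "group_a": "",
                          "group_b": "", "estimate": comp.omnibus_F,
                          "p": comp.omnibus_p, "level": "omnibus"})
        for a, b, est, p in comp.pairwise:
            stat_rows.append({"analysis": name, "kind": comp.kind, "group_a": a,
                              "group_b": b, "estimate": est, "p": p,
                              "level": "pairwise"})
    if stat_rows:
        save(pd.DataFrame(stat_rows), "group_comparisons.csv")

    manifest = {
        "config": _analysis_config(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_sessions": len(sessions),
        "sessions": [s.session_id for s in sessions],
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    bundle.manifest = manifest
    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    if truth is not None:
        gt = [{k: v for k, v in vars(rec).items() if k != "latent_rate"}
              for rec in truth]
        with open(os.path.join(out, "ground_truth.json"), "w", encoding="utf-8") as fh:
            json.dump(gt, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def make_report(bundle: ResultsBundle, path: str | None = None) -> str:
    """Markdown summary (plus PNG figures when matplotlib is importable)."""
    cfg = bundle.config
    out = path or cfg.out_dir
    os.makedirs(out, exist_ok=True)
    lines = ["# axonav pipeline report", ""]
    lines.append(f"- config hash: `{bundle.manifest.get('config_hash', 'n/a')}`")
    lines.append(f"- seed: {cfg.seed}")
    lines.append("")

    lines.append("## QC")
    if bundle.qc_reports:
        for sid, rep in sorted(bundle.qc_reports.items()):
            n_axon = sum(1 for r in rep.rows if r.kind == "axon")
            n_pass = sum(1 for r in rep.rows if r.passed_snr)
            n_flag = sum(1 for r in rep.rows if r.shift_flag)
            n_inc = sum(1 for r in rep.rows if r.included_final)
            lines.append(
                f"- {sid}: {n_pass}/{n_axon} axons passed SNR "
                f"(threshold {rep.snr_threshold:.3g}), {n_flag} shift-flagged, "
                f"{n_inc} included")
    else:
        lines.append("- not run")
    lines.append("")

    lines.append("## Tuning and regression")
    if bundle.population_fits:
        for (env, cov), fit in sorted(bundle.population_fits.items()):
            cls = bundle.classifications.get((env, cov), {})
            lines.append(
                f"- {env}/{cov}: population slope {fit.slope:.4g} "
                f"(F={fit.F_stat:.3g}, p={fit.p_value:.3g}); per-ROI "
                f"+{cls.get('positive', 0)}/-{cls.get('negative', 0)}"
                f"/ns {cls.get('ns', 0)}")
    else:
        lines.append("- not run")
    lines.append("")

    lines.append("## Resampling comparison")
    if bundle.resample_cloud is not None:
        rc = bundle.resample_cloud
        lines.append(
            f"- n={rc.subsample_n} x {rc.n_reps} reps; reference slope "
            f"{rc.reference_slope:.4g} contained: {rc.contained}")
    else:
        lines.append("- not run")
    lines.append("")

    lines.append("## Novelty")
    if bundle.novelty:
        for sid, variants in sorted(bundle.novelty.items()):
            for variant, res in sorted(variants.items()):
                segs = res["runs"].segments
                lines.append(f"- {sid} [{variant}]: {len(segs)} significant epochs "
                             f"{segs[:3]}")
    else:
        lines.append("- not run")
    lines.append("")

    lines.append("## Group comparisons")
    all_comps = {**{f"anova {k}": v for k, v in bundle.behavior_anova.items()},
                 **{f"ancova {k}": v for k, v in bundle.lapwise_ancova.items()}}
    if all_comps:
        for name, comp in sorted(all_comps.items()):
            lines.append(f"- {name}: omnibus F={comp.omnibus_F:.3g}, "
                         f"p={comp.omnibus_p:.3g}")
    else:
        lines.append("- not run")
    lines.append("")

    _render_figures(bundle, out)

    text = "\n".join(lines)
    with open(os.path.join(out, "report.md"), "w", encoding="utf-8") as fh:
        fh.write(text)
    return text


def _render_figures(bundle: ResultsBundle, out: str) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - matplotlib always present in practice
        return

    curves = bundle.tuning_curves.get(("familiar", "position"), {})
    if curves:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for key, curve in sorted(curves.items()):
            ax.plot(curve.bin_centers, curve.mean, alpha=0.4, lw=0.8)
        fit = bundle.population_fits.get(("familiar", "position"))
        if fit is not None:
            xs = np.array([min(c.bin_edges[0] for c in curves.values()),
                           max(c.bin_edges[-1] for c in curves.values())])
            ax.plot(xs, fit.intercept + fit.slope * xs, "k--", lw=1.5)
        ax.set_xlabel("position (cm)")
        ax.set_ylabel("normalized dF/F")
        fig.tight_layout()
        fig.savefig(os.path.join(out, "fig_position_curves.png"), dpi=100)
        plt.close(fig)

    for sid, variants in sorted(bundle.novelty.items()):
        res = variants.get("all")
        if res is None:
            continue
        mat, base, runs = res["aligned"], res["baseline"], res["runs"]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        t = mat.time_axis_s
        ax.fill_between(t, base.ci_lo, base.ci_hi, color="0.8", label="null 95% CI")
        ax.plot(t, mat.population_mean, "b-", lw=0.8, label="population mean")
        for a, b in runs.segments:
            ax.plot(t[a:b], mat.population_mean[a:b], "r-", lw=1.5)
        ax.axvline(0, color="k", ls=":")
        ax.set_xlabel("time from switch (s)")
        ax.set_ylabel("mean-normalized F")
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        fig.savefig(os.path.join(out, f"fig_novelty_{sid}.png"), dpi=100)
        plt.close(fig)
        break  # one example figure keeps the report light
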