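"""Synthetic session generator with known ground truth.

Emulates the behavioral protocol — run/pause locomotion on a 2 m or 3 m
virtual linear track, reward at the track end followed by a 1.5 s pause and
a teleport to the start, an optional dark lead-in and a familiar->novel
environment switch with a transient velocity dip and persistently reduced
immobility — and renders latent axon rates through a GCaMP-like
double-exponential kernel with Gaussian noise.

Latent rate model per axon (everything optional via its gain):

* ramp-to-reward: ``g_r * position/track_length`` while reward expectation
  is active, decaying with ``tau_rw`` after each reward delivery;
* velocity coupling: ``g_v * velocity``;
* pre-motion ramp: linear rise to ``g_m`` over the 2 s before each
  generative pause->run transition;
* novelty transient: ``A * exp(-(t - t_switch)/tau_nov)`` after the novel
  switch, and (scaled) after a dark->VR onset.

Cohorts are a pure function of (config, seed).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, asdict

import numpy as np

from .session import BehaviorRaw, RoiTrace, Session

__all__ = [
    "RunPauseParams",
    "NoveltyBehaviorParams",
    "EncodingPrior",
    "KernelParams",
    "SimConfig",
    "GroundTruthRecord",
    "simulate_behavior",
    "simulate_axon_rates",
    "render_fluorescence",
    "make_cohort",
]


@dataclass
class RunPauseParams:
    mean_speed_cm_s: float = 15.0
    speed_sd_cm_s: float = 3.0
    pause_rate_per_s: float = 0.05
    pause_duration_mean_s: float = 3.0
    post_teleport_pause_prob: float = 0.6


@dataclass
class NoveltyBehaviorParams:
    velocity_dip_fraction: float = 0.5   # first-novel-lap speed multiplier
    dip_recovery_s: float = 30.0
    freezing_reduction: float = 0.5      # pause-rate multiplier is (1 - this)


@dataclass
class EncodingPrior:
    """Per-axon gain ranges; each axon draws uniformly from [lo, hi].

    ``event_rate_hz``/``event_amp`` parameterize a private train of
    calcium-event impulses added to the latent rate. These give each axon
    the transient, broadband activity real GCaMP traces show — which both
    decorrelates distinct axons (so only true duplicates merge) and puts
    kernel-shaped power into the SNR signal band.
    """

    ramp_gain: tuple = (0.5, 1.5)
    velocity_gain: tuple = (0.0, 0.05)
    premotion_gain: tuple = (0.0, 0.0)
    novelty_amp: tuple = (0.0, 0.0)
    novelty_tau_s: float = 30.0
    post_reward_tau_s: float = 2.0
    vr_onset_scale: float = 0.5
    base_rate: float = 0.2
    event_rate_hz: float = 0.4
    event_amp: tuple = (5.0, 15.0)


@dataclass
class KernelParams:
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.5


@dataclass
class SimConfig:
    n_sessions: int = 1
    axons_per_session: int = 10
    blebs_per_session: int = 3
    source: str = "LC"
    track_length_cm: float = 300.0
    frame_rate_hz: float = 30.0
    familiar_duration_s: float = 300.0
    novel_duration_s: float = 300.0
    dark_lead_s: float = 0.0
    reward_pause_s: float = 1.5
    run_pause: RunPauseParams = field(default_factory=RunPauseParams)
    novelty_behavior: NoveltyBehaviorParams = field(default_factory=NoveltyBehaviorParams)
    encoding: EncodingPrior = field(default_factory=EncodingPrior)
    kernel: KernelParams = field(default_factory=KernelParams)
    noise_sd: float = 0.05
    baseline_f0: float = 100.0
    bleach_per_frame: float = 0.0
    unhealthy_fraction: float = 0.0
    unhealthy_step_sd: float = 5.0       # step magnitude in units of noise_sd
    rewarded: bool = True                 # reward expectation active in VR envs
    seed: int = 0

    def validate(self) -> None:
        if min(self.familiar_duration_s, self.novel_duration_s) < 0:
            raise ValueError("durations must be non-negative")
        if self.dark_lead_s < 0:
            raise ValueError("dark_lead_s must be >= 0")
        for name in ("track_length_cm", "frame_rate_hz", "reward_pause_s",
                     "noise_sd", "baseline_f0"):
            if getattr(self, name) <= 0 and name not in ("noise_sd",):
                raise ValueError(f"{name} must be > 0")
        for frac in (self.unhealthy_fraction, self.novelty_behavior.velocity_dip_fraction,
                     self.novelty_behavior.freezing_reduction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.kernel.tau_rise_s <= 0 or self.kernel.tau_decay_s <= 0:
            raise ValueError("kernel taus must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, sub in (("run_pause", RunPauseParams),
                         ("novelty_behavior", NoveltyBehaviorParams),
                         ("encoding", EncodingPrior),
                         ("kernel", KernelParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d[key].items()})
        return cls(**d)


@dataclass
class GroundTruthRecord:
    roi_id: str
    session_id: str
    is_bleb: bool
    ramp_gain: float = 0.0
    velocity_gain: float = 0.0
    premotion_gain: float = 0.0
    novelty_amp: float = 0.0
    novelty_tau_s: float = 0.0
    post_reward_tau_s: float = 0.0
    event_rate_hz: float = 0.0
    event_amp_mean: float = 0.0
    private_seed: int | None = None
    unhealthy_step: tuple | None = None  # (frame, magnitude)
    latent_rate: np.ndarray | None = None


def simulate_behavior(cfg: SimConfig, seed: int) -> tuple:
    """Simulate one session's behavior.

    Returns ``(BehaviorRaw, env_schedule)``. Position advances only during
    run bouts of a two-state run/pause process; reaching the track end emits
    a reward frame, freezes position for the reward pause, then a teleport
    frame resets position to 0. After the familiar->novel switch the run
    speed is multiplied by the configured dip fraction for the first novel
    lap (recovering over ``dip_recovery_s`` afterwards) and the pause rate
    drops by the freezing reduction.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    fs = cfg.frame_rate_hz
    dt = 1.0 / fs
    n_dark = int(round(cfg.dark_lead_s * fs))
    n_fam = int(round(cfg.familiar_duration_s * fs))
    n_nov = int(round(cfg.novel_duration_s * fs))
    n = n_dark + n_fam + n_nov
    switch_frame = n_dark + n_fam

    rp = cfg.run_pause
    min_lap_s = cfg.track_length_cm / max(rp.mean_speed_cm_s, 1e-9) + cfg.reward_pause_s
    if cfg.familiar_duration_s < min_lap_s:
        raise ValueError(
            f"familiar duration {cfg.familiar_duration_s}s too short for one lap (~{min_lap_s:.1f}s)"
        )

    pos = np.zeros(n)
    reward_frames: list = []
    teleport_frames: list = []

    # state machine
    speed = max(0.0, rng.normal(rp.mean_speed_cm_s, rp.speed_sd_cm_s))
    pause_left = 0                 # frames left in a pause
    freeze_left = 0                # frames left in a reward freeze
    x = 0.0
    first_novel_lap_done = False
    recovery_start: int | None = None
    pause_frames_base = rp.pause_duration_mean_s * fs

    for t in range(n):
        in_novel = t >= switch_frame and n_nov > 0
        if t == switch_frame and n_nov > 0:
            # teleport into the novel environment at the track start
            teleport_frames.append(t)
            x = 0.0
            freeze_left = 0
            pause_left = 0
            first_novel_lap_done = False
            recovery_start = None

        if freeze_left > 0:
            freeze_left -= 1
            pos[t] = x
            if freeze_left == 0:
                # teleport back to start; next frame begins the new lap
                if t + 1 < n and not (t + 1 == switch_frame and n_nov > 0):
                    teleport_frames.append(t + 1)
                x = 0.0
                if in_novel and not first_novel_lap_done:
                    first_novel_lap_done = True
                    recovery_start = t + 1
                if rng.random() < rp.post_teleport_pause_prob:
                    pause_left = max(1, int(rng.exponential(pause_frames_base)))
            continue

        if pause_left > 0:
            pause_left -= 1
            pos[t] = x
            continue

        # running
        pause_rate = rp.pause_rate_per_s
        if in_novel:
            pause_rate *= 1.0 - cfg.novelty_behavior.freezing_reduction
        if rng.random() < pause_rate * dt:
            pause_left = max(1, int(rng.exponential(pause_frames_base)))
            pos[t] = x
            speed = max(0.0, rng.normal(rp.mean_speed_cm_s, rp.speed_sd_cm_s))
            continue

        # speed wanders within a run bout (OU around the bout mean, ~3 s
        # correlation) so velocity genuinely spans its tuning bins
        if rp.speed_sd_cm_s > 0:
            tau_frames = 3.0 * fs
            speed += (rp.mean_speed_cm_s - speed) / tau_frames \
                + rp.speed_sd_cm_s * math.sqrt(2.0 / tau_frames) * rng.standard_normal()
            speed = max(0.0, speed)
        v = speed
        if in_novel:
            nb = cfg.novelty_behavior
            if not first_novel_lap_done:
                v *= nb.velocity_dip_fraction
            elif recovery_start is not None:
                frac = min(1.0, (t - recovery_start) / max(nb.dip_recovery_s * fs, 1))
                v *= nb.velocity_dip_fraction + (1.0 - nb.velocity_dip_fraction) * frac

        x = x + v * dt
        if x >= cfg.track_length_cm:
            if t < n_dark:
                # wheel wrap in darkness: silent reset, no reward or pause
                x = 0.0
                pos[t] = x
                teleport_frames.append(t)
                continue
            x = cfg.track_length_cm
            pos[t] = x
            if cfg.rewarded:
                reward_frames.append(t)
            freeze_left = int(round(cfg.reward_pause_s * fs))
            speed = max(0.0, rng.normal(rp.mean_speed_cm_s, rp.speed_sd_cm_s))
            continue
        pos[t] = x

    env_schedule = []
    if n_dark > 0:
        env_schedule.append(("dark", 0))
    env_schedule.append(("familiar", n_dark))
    if n_nov > 0:
        env_schedule.append(("novel", switch_frame))

    behavior = BehaviorRaw(
        position_cm=pos,
        reward_frames=np.asarray(sorted(set(reward_frames)), dtype=np.int64),
        teleport_frames=np.asarray(sorted(set(f for f in teleport_frames if f < n)),
                                   dtype=np.int64),
        valid=np.ones(n, dtype=bool),
    )
    return behavior, env_schedule


def _sim_velocity(pos: np.ndarray, teleports: np.ndarray, fs: float) -> np.ndarray:
    """Generator-level velocity: backward difference with resets zeroed."""
    v = np.empty_like(pos)
    v[1:] = np.diff(pos) * fs
    v[0] = 0.0
    v[v < 0] = 0.0
    tel = teleports[(teleports > 0) & (teleports < pos.shape[0])]
    v[tel] = 0.0
    return v


def simulate_axon_rates(
    behavior: BehaviorRaw,
    env_schedule: list,
    params: GroundTruthRecord,
    cfg: SimConfig,
) -> np.ndarray:
    """Latent (non-negative) rate per frame for one axon."""
    fs = cfg.frame_rate_hz
    n = behavior.n_frames
    pos_norm = behavior.position_cm / cfg.track_length_cm
    velocity = _sim_velocity(behavior.position_cm, behavior.teleport_frames, fs)

    env = np.empty(n, dtype=object)
    sched = list(env_schedule) + [(None, n)]
    for (label, start), (_, end) in zip(sched[:-1], sched[1:]):
        env[start:end] = label
    in_vr = env != "dark"

    rate = np.full(n, cfg.encoding.base_rate, dtype=float)

    if params.ramp_gain != 0.0 and cfg.rewarded:
        ramp = params.ramp_gain * pos_norm * in_vr
        # after each reward the accumulated ramp decays with tau_rw
        t_idx = np.arange(n)
        decay = np.zeros(n)
        for r in behavior.reward_frames:
            seg = t_idx >= r
            decay_r = params.ramp_gain * np.exp(-(t_idx - r) / (params.post_reward_tau_s * fs))
            decay = np.where(seg, np.maximum(decay, decay_r * seg), decay)
        rate += np.maximum(ramp, decay)

    if params.velocity_gain != 0.0:
        rate += params.velocity_gain * velocity

    if params.premotion_gain != 0.0:
        n_ramp = int(round(2.0 * fs))
        running = velocity >= 5.0
        # generative motion onsets: first running frame after >=1.5 s still
        n_still = int(round(1.5 * fs))
        still = ~running
        cs = np.concatenate([[0], np.cumsum(still)])
        for t in range(n_still, n):
            if running[t] and cs[t] - cs[t - n_still] == n_still:
                a = max(0, t - n_ramp)
                rate[a:t] += params.premotion_gain * np.linspace(
                    1 - (t - a) / n_ramp, 1.0, t - a, endpoint=False
                )

    if params.novelty_amp != 0.0:
        t_idx = np.arange(n)
        tau = params.novelty_tau_s * fs
        for label, start in env_schedule:
            if label == "novel":
                seg = t_idx >= start
                rate += params.novelty_amp * np.exp(-(t_idx - start) / tau) * seg
            elif label == "familiar" and any(l == "dark" for l, _ in env_schedule):
                seg = t_idx >= start
                rate += (cfg.encoding.vr_onset_scale * params.novelty_amp
                         * np.exp(-(t_idx - start) / tau) * seg)

    if params.event_rate_hz > 0 and params.private_seed is not None:
        ev_rng = np.random.default_rng(params.private_seed)
        hits = ev_rng.random(n) < params.event_rate_hz / fs
        amps = ev_rng.exponential(params.event_amp_mean, size=n)
        rate += np.where(hits, amps, 0.0)

    return np.clip(rate, 0.0, None)


def gcamp_kernel(kernel: KernelParams, fs: float, length_s: float = 10.0) -> np.ndarray:
    """Unit-sum double-exponential kernel sampled at the frame rate."""
    if kernel.tau_rise_s <= 0 or kernel.tau_decay_s <= 0:
        raise ValueError("kernel taus must be > 0")
    t = np.arange(int(round(length_s * fs))) / fs
    k = np.exp(-t / kernel.tau_decay_s) - np.exp(-t / kernel.tau_rise_s)
    total = k.sum()
    if total <= 0:
        raise ValueError("degenerate kernel (tau_rise >= tau_decay?)")
    return k / total


def render_fluorescence(
    rate: np.ndarray,
    kernel: KernelParams,
    noise_sd: float,
    baseline_f0: float,
    bleach_per_frame: float,
    fs: float,
    seed: int,
    unhealthy_step: tuple | None = None,
) -> np.ndarray:
    """Raw fluorescence: bleached baseline + kernel-convolved rate + noise.

    ``raw_f = f0 * (1 - bleach)^t + (rate (*) kernel) + N(0, noise_sd) [+ step]``
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rate.shape[0]
    k = gcamp_kernel(kernel, fs)
    signal = np.convolve(rate, k)[:n]
    t = np.arange(n)
    raw = baseline_f0 * (1.0 - bleach_per_frame) ** t + signal
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=n)
    if unhealthy_step is not None:
        frame, magnitude = unhealthy_step
        raw[int(frame):] += magnitude
    return raw


def _draw(rng: np.random.Generator, lohi: tuple) -> float:
    lo, hi = lohi
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def make_cohort(cfg: SimConfig) -> tuple:
    """Generate ``cfg.n_sessions`` Sessions plus ground-truth records.

    Per-session seeds derive from ``cfg.seed`` via ``SeedSequence.spawn`` so
    the cohort is reproducible and sessions are independent.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    session_seeds = root.spawn(cfg.n_sessions)

    sessions, truths = [], []
    for i, ss in enumerate(session_seeds):
        child = ss.generate_state(4)
        behavior, env_schedule = simulate_behavior(cfg, seed=int(child[0]))
        rng = np.random.default_rng(int(child[1]))
        session_id = f"sim-{cfg.source}-{i:03d}"
        n = behavior.n_frames

        n_unhealthy = int(round(cfg.unhealthy_fraction * cfg.axons_per_session))
        unhealthy_ids = set(rng.choice(cfg.axons_per_session, size=n_unhealthy,
                                       replace=False).tolist()) if n_unhealthy else set()

        rois = []
        for a in range(cfg.axons_per_session):
            enc = cfg.encoding
            rec = GroundTruthRecord(
                roi_id=f"axon{a:03d}",
                session_id=session_id,
                is_bleb=False,
                ramp_gain=_draw(rng, enc.ramp_gain),
                velocity_gain=_draw(rng, enc.velocity_gain),
                premotion_gain=_draw(rng, enc.premotion_gain),
                novelty_amp=_draw(rng, enc.novelty_amp),
                novelty_tau_s=enc.novelty_tau_s,
                post_reward_tau_s=enc.post_reward_tau_s,
                event_rate_hz=enc.event_rate_hz,
                event_amp_mean=_draw(rng, enc.event_amp),
                private_seed=int(rng.integers(2**63)),
            )
            if a in unhealthy_ids:
                frame = int(rng.integers(n // 4, 3 * n // 4))
                rec.unhealthy_step = (frame, cfg.unhealthy_step_sd * cfg.noise_sd)
            rate = simulate_axon_rates(behavior, env_schedule, rec, cfg)
            rec.latent_rate = rate
            raw = render_fluorescence(
                rate, cfg.kernel, cfg.noise_sd, cfg.baseline_f0,
                cfg.bleach_per_frame, cfg.frame_rate_hz,
                seed=int(rng.integers(2**63)),
                unhealthy_step=rec.unhealthy_step,
            )
            rois.append(RoiTrace(roi_id=rec.roi_id, kind="axon", raw_f=raw))
            truths.append(rec)

        for b in range(cfg.blebs_per_session):
            rec = GroundTruthRecord(
                roi_id=f"bleb{b:03d}", session_id=session_id, is_bleb=True
            )
            raw = render_fluorescence(
                np.zeros(n), cfg.kernel, cfg.noise_sd, cfg.baseline_f0,
                cfg.bleach_per_frame, cfg.frame_rate_hz,
                seed=int(rng.integers(2**63)),
            )
            rois.append(RoiTrace(roi_id=rec.roi_id, kind="bleb", raw_f=raw))
            truths.append(rec)

        sessions.append(
            Session(
                session_id=session_id,
                source=cfg.source,
                frame_rate_hz=cfg.frame_rate_hz,
                track_length_cm=cfg.track_length_cm,
                env_schedule=env_schedule,
                behavior=behavior,
                rois=rois,
                meta={"simulated": True, "config_seed": cfg.seed},
            )
        )
    return sessions, truths
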