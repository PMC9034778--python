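"""Ground-truth-labeled synthetic cohorts: tracking plus photometry.

Trajectories alternate constant-ish-speed runs with pauses placed by a
spatial hazard (pauses per cm traversed, bimodal by default with peaks
near both track ends). Each pause resolves by a (choice, RT) draw from
the local zone's LBA race: approach resumes motion toward the goal,
avoid reverses toward the start, producing the bistable start-goal
oscillations the downstream stages assume. Photometry channels share a
multiplicative artifact; the Ca channel additionally carries either
event-locked transients at goal-zone pause onsets ("goal_locked") or a
spatial ramp toward the goal ("spatial_ramp").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .lba.core import LBAParams, sample_race
from .microstructure import TrackGeometry, TrackingTrace
from .photometry import PhotometryRecording

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_zone_params",
    "default_hazard",
    "simulate_trial_trajectory",
    "simulate_photometry",
    "simulate_cohort",
]


def default_zone_params() -> dict[str, LBAParams]:
    """Zone-wise race parameters embodying the qualitative regime structure:
    elevated caution and slower avoid decisions at the goal, fast
    approach-dominated decisions elsewhere."""
    return {
        "start": LBAParams(v=(2.2, 1.2), A=0.7, k=0.8, t0=0.15),
        "mid": LBAParams(v=(2.6, 1.0), A=0.5, k=0.5, t0=0.15),
        "goal": LBAParams(v=(2.0, 1.6), A=1.2, k=1.6, t0=0.20),
    }


def default_hazard(x) -> np.ndarray:
    """Pauses per cm traversed; bimodal with peaks near both track ends."""
    x = np.asarray(x, dtype=float)
    return (
        0.02
        + 0.10 * np.exp(-0.5 * ((x - 5.0) / 5.0) ** 2)
        + 0.40 * np.exp(-0.5 * ((x - 85.5) / 2.5) ** 2)
    )


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 8
    n_trials: int = 20
    frame_rate: float = 30.0
    geometry: TrackGeometry = field(default_factory=TrackGeometry)
    zone_params: dict[str, LBAParams] = field(default_factory=default_zone_params)
    pause_hazard_profile: object = None  # callable x -> pauses/cm; None = default
    run_speed_mean: float = 15.0
    run_speed_sd: float = 1.0
    photometry_mode: str = "goal_locked"  # or "spatial_ramp"
    transient_amplitude: float = 0.05
    noise_sd: float = 0.002
    artifact_gain: float = 0.1
    seed: int = 0
    timeout_s: float = 120.0
    goal_dwell_s: float = 1.0
    start_dwell_s: float = 1.0
    trial_gap_s: float = 2.0
    refractory_cm: float = 2.0
    tracking_jitter_sd: float = 0.0
    dropout_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.photometry_mode not in ("goal_locked", "spatial_ramp"):
            raise ValueError("unknown photometry_mode")
        names = set(self._zone_names())
        missing = names - set(self.zone_params)
        if missing:
            raise ValueError(f"zone(s) without LBA parameters: {sorted(missing)}")
        grid = np.linspace(0, self.geometry.track_len, 200)
        if np.any(self.hazard(grid) < 0):
            raise ValueError("pause_hazard_profile must be >= 0 everywhere")

    def _zone_names(self) -> list[str]:
        n = len(self.geometry.zone_boundaries) + 1
        return ["start", "mid", "goal"] if n == 3 else [f"zone{i}" for i in range(n)]

    def hazard(self, x):
        f = self.pause_hazard_profile or default_hazard
        return np.asarray(f(x), dtype=float)

    def zone_of(self, x: float) -> str:
        names = self._zone_names()
        return names[int(np.searchsorted(self.geometry.zone_boundaries, x, "right"))]


@dataclass
class GroundTruth:
    """Generative record: per-subject parameters, pause draws, photometry."""

    subject_params: dict[str, dict[str, LBAParams]] = field(default_factory=dict)
    pauses: pd.DataFrame = field(default_factory=pd.DataFrame)
    transient_times: dict[str, np.ndarray] = field(default_factory=dict)
    transient_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    artifacts: dict[str, np.ndarray] = field(default_factory=dict)
    signals: dict[str, np.ndarray] = field(default_factory=dict)


def simulate_trial_trajectory(
    subject_params: dict[str, LBAParams],
    config: CohortConfig,
    rng: np.random.Generator,
    t_offset: float = 0.0,
    subject_id: str = "s0",
    trial: int = 0,
) -> tuple[TrackingTrace, list[dict]]:
    """One trial: Start box -> oscillations -> goal entry + dwell (or timeout).

    Returns the trace (timestamps offset by ``t_offset``) and the list of
    generative pause records (onset frame/time, location, zone, choice, rt).
    """
    geo = config.geometry
    dt = 1.0 / config.frame_rate
    max_frames = int(round(config.timeout_s * config.frame_rate))
    goal_dwell = int(round(config.goal_dwell_s * config.frame_rate))
    start_dwell = int(round(config.start_dwell_s * config.frame_rate))

    x = -geo.start_box_len / 2.0
    direction = 1
    xs = [x]
    truth: list[dict] = []
    pause_left = 0
    pending_dir = 1
    dwell_left = 0
    dist_since_event = np.inf
    goal_reached = False
    frame = 0

    while frame < max_frames - 1:
        frame += 1
        if pause_left > 0:
            pause_left -= 1
            xs.append(x)
            if pause_left == 0:
                direction = pending_dir
                dist_since_event = 0.0
            continue
        if dwell_left > 0:
            dwell_left -= 1
            xs.append(x)
            if dwell_left == 0:
                if goal_reached:
                    break
                direction = 1
                dist_since_event = 0.0
            continue
        speed = max(rng.normal(config.run_speed_mean, config.run_speed_sd), 0.0)
        nx = x + direction * speed * dt
        step = abs(nx - x)
        x = nx
        xs.append(x)
        dist_since_event += step
        if direction > 0 and x >= geo.track_len + geo.goal_box_len / 2.0:
            goal_reached = True
            dwell_left = goal_dwell
            continue
        if direction < 0 and x <= -geo.start_box_len / 4.0:
            dwell_left = start_dwell
            continue
        on_track = 0.0 <= x <= geo.track_len
        if on_track and dist_since_event >= config.refractory_cm:
            if rng.uniform() < float(config.hazard(x)) * step:
                zone = config.zone_of(x)
                draw = sample_race(subject_params[zone], 1, rng)
                rt = float(draw.rts[0])
                choice = "approach" if draw.choices[0] == 0 else "avoid"
                # the arrival frame already sits at the pause location, so
                # hold for round(rt/dt) - 1 further frames
                pause_left = max(2, int(round(rt * config.frame_rate)) - 1)
                pending_dir = 1 if choice == "approach" else -1
                truth.append(
                    {
                        "subject": subject_id,
                        "trial": trial,
                        "onset_frame": frame,
                        "onset_time": t_offset + frame * dt,
                        "location": x,
                        "zone": zone,
                        "choice": choice,
                        "rt": rt,
                    }
                )

    xs = np.asarray(xs)
    n = xs.size
    if config.tracking_jitter_sd > 0:
        xs = xs + rng.normal(0.0, config.tracking_jitter_sd, size=n)
    y = 7.5 + rng.normal(0.0, 0.1, size=n)  # jitter around the track midline
    valid = np.ones(n, dtype=bool)
    if config.dropout_frac > 0:
        drop = rng.uniform(size=n) < config.dropout_frac
        drop[0] = drop[-1] = False
        valid = ~drop
    trace = TrackingTrace(
        subject_id=subject_id,
        session_id=f"trial{trial}",
        timestamps=t_offset + np.arange(n) * dt,
        x=xs,
        y=y,
        valid=valid,
    )
    return trace, truth


def _transient_kernel(tau: np.ndarray, rise: float = 0.1, decay: float = 0.6) -> np.ndarray:
    k = np.where(tau >= 0, np.exp(-tau / decay) - np.exp(-tau / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    return k / peak


def simulate_photometry(
    trace: TrackingTrace,
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator,
) -> PhotometryRecording:
    """Two channels sharing a multiplicative artifact; Ca carries the signal.

    iso = base * artifact + noise; ca = base * artifact * (1 + signal) + noise.
    The generative artifact and signal traces are stored in ``truth``.
    """
    t = trace.timestamps
    n = t.size
    dt = float(np.median(np.diff(t))) if n > 1 else 1.0 / config.frame_rate
    fs = 1.0 / dt

    slow = rng.normal(size=n)
    slow = gaussian_filter1d(slow, sigma=max(5.0 * fs, 1.0))
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    vel = np.abs(np.gradient(trace.x, t)) if n > 1 else np.zeros(n)
    vsd = vel.std()
    motion = (vel - vel.mean()) / vsd if vsd > 0 else np.zeros(n)
    artifact = np.exp(config.artifact_gain * (0.8 * slow + 0.2 * motion))

    signal = np.zeros(n)
    ev_times = np.array([])
    ev_amps = np.array([])
    if config.transient_amplitude != 0:
        if config.photometry_mode == "goal_locked":
            if len(truth.pauses):
                sub = truth.pauses
                sel = (sub["subject"] == trace.subject_id) & (sub["zone"] == "goal")
                ev_times = sub.loc[sel, "onset_time"].to_numpy()
            ev_amps = np.full(ev_times.size, config.transient_amplitude)
            for ev, amp in zip(ev_times, ev_amps):
                m = (t >= ev - 1.0) & (t <= ev + 6.0)
                signal[m] += amp * _transient_kernel(t[m] - ev)
        else:  # spatial_ramp
            signal = config.transient_amplitude * np.clip(
                trace.x / config.geometry.track_len, 0.0, 1.0
            )

    iso_base, ca_base = 200.0, 400.0
    iso = iso_base * artifact + rng.normal(0, config.noise_sd * iso_base, n)
    ca = ca_base * artifact * (1.0 + signal) + rng.normal(
        0, config.noise_sd * ca_base, n
    )

    truth.transient_times[trace.subject_id] = ev_times
    truth.transient_amplitudes[trace.subject_id] = ev_amps
    truth.artifacts[trace.subject_id] = artifact
    truth.signals[trace.subject_id] = signal

    return PhotometryRecording(
        timestamps=t,
        ca_signal=ca,
        iso_signal=iso,
        events={"pause_onset": truth.pauses.loc[
            truth.pauses["subject"] == trace.subject_id, "onset_time"
        ].to_numpy() if len(truth.pauses) else np.array([])},
        x=trace.x,
        subject_id=trace.subject_id,
    )


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[TrackingTrace], list[PhotometryRecording], GroundTruth]:
    """Full cohort: one concatenated session per subject, deterministic in seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * config.n_subjects)
    truth = GroundTruth()
    traces: list[TrackingTrace] = []
    all_pauses: list[dict] = []
    dt = 1.0 / config.frame_rate
    gap_frames = int(round(config.trial_gap_s * config.frame_rate))

    for s, child in enumerate(children[: config.n_subjects]):
        rng = np.random.default_rng(child)
        sid = f"s{s}"
        truth.subject_params[sid] = dict(config.zone_params)
        t_offset = 0.0
        xs_parts, y_parts, valid_parts = [], [], []
        for trial in range(config.n_trials):
            tr, tp = simulate_trial_trajectory(
                truth.subject_params[sid], config, rng, t_offset, sid, trial
            )
            xs_parts.append(tr.x)
            y_parts.append(tr.y)
            valid_parts.append(tr.valid)
            all_pauses.extend(tp)
            t_offset += len(tr) * dt
            if trial < config.n_trials - 1 and gap_frames:
                xs_parts.append(np.full(gap_frames, -config.geometry.start_box_len / 2))
                y_parts.append(np.full(gap_frames, 7.5))
                valid_parts.append(np.ones(gap_frames, dtype=bool))
                t_offset += gap_frames * dt
        x = np.concatenate(xs_parts)
        traces.append(
            TrackingTrace(
                subject_id=sid,
                session_id="session0",
                timestamps=np.arange(x.size) * dt,
                x=x,
                y=np.concatenate(y_parts),
                valid=np.concatenate(valid_parts),
            )
        )

    truth.pauses = pd.DataFrame(
        all_pauses,
        columns=[
            "subject", "trial", "onset_frame", "onset_time",
            "location", "zone", "choice", "rt",
        ],
    )
    if len(truth.pauses):
        # session-global frame index (trial records are trial-local)
        truth.pauses["onset_frame"] = np.rint(
            truth.pauses["onset_time"].to_numpy() * config.frame_rate
        ).astype(int)

    recordings = []
    for trace, child in zip(traces, children[config.n_subjects :]):
        rng = np.random.default_rng(child)
        recordings.append(simulate_photometry(trace, truth, config, rng))
    return traces, recordings, truth
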