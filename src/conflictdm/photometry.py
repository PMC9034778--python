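"""Fiber-photometry dF/F, peri-event kernels, and bootstrap significance.

dF/F is computed against a fitted isosbestic reference: the isosbestic
channel is the regressor in an ordinary least-squares fit of the
Ca-dependent channel, and dF/F = (ca - fitted) / fitted. Peri-event
kernels collate dF/F in a [-5, +5] s window around events, baselined to
[-5, -2.5] s, and significance of the across-subject mean waveform is
assessed with a subject-level percentile bootstrap whose interval
half-widths are expanded by sqrt(n / (n - 1)); a significant epoch must
exclude zero for at least 1/3 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PhotometryRecording",
    "DffTrace",
    "EventKernel",
    "SpatialDffMap",
    "compute_dff",
    "extract_kernels",
    "bootstrap_ci",
    "significant_epochs",
    "spatial_dff",
    "pause_dff",
]

KERNEL_WINDOW = (-5.0, 5.0)
KERNEL_BASELINE = (-5.0, -2.5)
KERNEL_FS = 20.0  # Hz; oversamples the 3 Hz hardware low-pass
MIN_EPOCH_S = 1.0 / 3.0


@dataclass
class PhotometryRecording:
    """Demodulated two-channel recording with synchronized events/position."""

    timestamps: np.ndarray
    ca_signal: np.ndarray
    iso_signal: np.ndarray
    events: dict[str, np.ndarray] = field(default_factory=dict)
    x: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ca_signal = np.asarray(self.ca_signal, dtype=float)
        self.iso_signal = np.asarray(self.iso_signal, dtype=float)
        n = self.timestamps.size
        if self.ca_signal.size != n or self.iso_signal.size != n:
            raise ValueError("channel lengths must match timestamps")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must strictly increase")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.size != n:
                raise ValueError("position sync length must match timestamps")

    def to_frame(self) -> pd.DataFrame:
        d = {
            "time_s": self.timestamps,
            "ca_465": self.ca_signal,
            "iso_405": self.iso_signal,
        }
        if self.x is not None:
            d["x_cm"] = self.x
        return pd.DataFrame(d)


@dataclass
class DffTrace:
    timestamps: np.ndarray
    dff: np.ndarray
    slope: float
    intercept: float

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class EventKernel:
    """Peri-event waveforms on a common time axis, baselined per event."""

    time: np.ndarray
    waveforms: np.ndarray  # (n_events, n_time)
    mean: np.ndarray
    n_dropped: int = 0
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    epochs: list[tuple[float, float, int]] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.waveforms.shape[0]


@dataclass
class SpatialDffMap:
    bin_edges: np.ndarray
    bin_means: np.ndarray  # NaN for empty bins
    bin_counts: np.ndarray
    zone_means: dict[str, float] = field(default_factory=dict)


def compute_dff(rec: PhotometryRecording) -> DffTrace:
    """(ca - fitted isosbestic) / fitted isosbestic, with OLS fitted = m*iso + c."""
    if rec.timestamps.size < 100:
        raise ValueError("need at least 100 samples")
    iso = rec.iso_signal
    if np.ptp(iso) == 0:
        raise ValueError("constant isosbestic channel: regression degenerate")
    slope, intercept = np.polyfit(iso, rec.ca_signal, 1)
    fitted = slope * iso + intercept
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (rec.ca_signal - fitted) / fitted
    return DffTrace(
        timestamps=rec.timestamps,
        dff=dff,
        slope=float(slope),
        intercept=float(intercept),
    )


def extract_kernels(
    dff: DffTrace,
    events: np.ndarray,
    window: tuple[float, float] = KERNEL_WINDOW,
    baseline: tuple[float, float] = KERNEL_BASELINE,
    fs: float = KERNEL_FS,
) -> EventKernel:
    """Collate baselined dF/F around each event on a uniform time axis.

    Events whose window is not fully covered by the recording are dropped
    and logged.
    """
    events = np.atleast_1d(np.asarray(events, dtype=float))
    axis = np.arange(window[0], window[1] + 0.5 / fs, 1.0 / fs)
    t0, t1 = dff.timestamps[0], dff.timestamps[-1]
    usable = (events + window[0] >= t0) & (events + window[1] <= t1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("dropped %d events with incomplete windows", n_dropped)
    waves = []
    bmask = (axis >= baseline[0]) & (axis <= baseline[1])
    for ev in events[usable]:
        w = np.interp(ev + axis, dff.timestamps, dff.dff)
        waves.append(w - w[bmask].mean())
    if not waves:
        log.warning("no usable events for kernel extraction")
        waves = np.empty((0, axis.size))
    else:
        waves = np.asarray(waves)
    mean = waves.mean(axis=0) if waves.shape[0] else np.full(axis.size, np.nan)
    return EventKernel(time=axis, waveforms=waves, mean=mean, n_dropped=n_dropped)


def significant_epochs(
    time: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    min_epoch_s: float = MIN_EPOCH_S,
) -> list[tuple[float, float, int]]:
    """Maximal runs where the CI excludes 0 for at least ``min_epoch_s``.

    Returns (start, end, sign) tuples; sign is +1 for positive epochs.
    """
    dt = float(np.median(np.diff(time)))
    min_samples = int(np.ceil(min_epoch_s / dt))
    sig = np.where(lower > 0, 1, np.where(upper < 0, -1, 0))
    epochs = []
    i = 0
    n = sig.size
    while i < n:
        if sig[i] == 0:
            i += 1
            continue
        j = i
        while j < n and sig[j] == sig[i]:
            j += 1
        if j - i >= min_samples:
            epochs.append((float(time[i]), float(time[j - 1]), int(sig[i])))
        i = j
    return epochs


def bootstrap_ci(
    waveforms: np.ndarray,
    time: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    min_epoch_s: float = MIN_EPOCH_S,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[float, float, int]]]:
    """Across-subject bootstrap CI of the mean waveform plus significant epochs.

    Subject mean waveforms (rows) are resampled with replacement; the
    pointwise percentile interval is expanded about the bootstrap mean by
    sqrt(n / (n - 1)).
    """
    waveforms = np.asarray(waveforms, dtype=float)
    n = waveforms.shape[0]
    if n < 2:
        raise ValueError("bootstrap requires >= 2 subjects")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = waveforms[idx].mean(axis=1)  # (n_boot, n_time)
    lo = np.percentile(boot_means, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot_means, 100 * (1 - alpha / 2), axis=0)
    center = boot_means.mean(axis=0)
    factor = np.sqrt(n / (n - 1.0))
    lower = center - factor * (center - lo)
    upper = center + factor * (hi - center)
    mean = waveforms.mean(axis=0)
    epochs = significant_epochs(time, lower, upper, min_epoch_s)
    return mean, lower, upper, epochs


def spatial_dff(
    dff: DffTrace,
    x: np.ndarray,
    geometry,
    partition=None,
) -> SpatialDffMap:
    """Mean dF/F per 5 cm track bin; empty bins are NaN, not zero.

    With a ZonePartition (or geometry zone boundaries), zone aggregates
    average samples on the track proper only.
    """
    x = np.asarray(x, dtype=float)
    if x.size != len(dff):
        raise ValueError("position sync length mismatch")
    edges = geometry.bin_edges()
    means = np.full(edges.size - 1, np.nan)
    counts = np.zeros(edges.size - 1, dtype=int)
    on = (x >= 0) & (x <= geometry.track_len)
    which = np.clip(np.searchsorted(edges, x[on], side="right") - 1, 0, edges.size - 2)
    vals = dff.dff[on]
    for b in range(edges.size - 1):
        m = which == b
        counts[b] = int(m.sum())
        if counts[b]:
            means[b] = float(vals[m].mean())
    zone_means: dict[str, float] = {}
    boundaries = None
    if partition is not None:
        boundaries = partition.boundaries
    elif geometry.zone_boundaries:
        boundaries = geometry.zone_boundaries
    if boundaries is not None:
        names = ["start", "mid", "goal"] if len(boundaries) == 2 else [
            f"zone{i}" for i in range(len(boundaries) + 1)
        ]
        zi = np.searchsorted(boundaries, x[on], side="right")
        for i, name in enumerate(names):
            m = zi == i
            if m.any():
                zone_means[name] = float(vals[m].mean())
    return SpatialDffMap(
        bin_edges=edges, bin_means=means, bin_counts=counts, zone_means=zone_means
    )


def pause_dff(dff: DffTrace, pauses) -> pd.DataFrame:
    """Mean dF/F over each pause's [onset, offset]; per-(subject, zone) means.

    Pauses outside the recording span are dropped and logged. Returns a
    tidy frame with one row per usable pause; aggregate with
    ``df.groupby(["subject", "zone"])["dff"].mean()``.
    """
    t0, t1 = dff.timestamps[0], dff.timestamps[-1]
    rows = []
    n_dropped = 0
    for p in pauses:
        if p.onset_time < t0 or p.offset_time > t1:
            n_dropped += 1
            continue
        m = (dff.timestamps >= p.onset_time) & (dff.timestamps <= p.offset_time)
        if not m.any():
            n_dropped += 1
            continue
        rows.append(
            {
                "subject": p.subject_id,
                "zone": p.zone,
                "onset_s": p.onset_time,
                "dff": float(dff.dff[m].mean()),
                "outcome": p.outcome,
            }
        )
    if n_dropped:
        log.info("dropped %d pauses outside the recording span", n_dropped)
    return pd.DataFrame(rows, columns=["subject", "zone", "onset_s", "dff", "outcome"])
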