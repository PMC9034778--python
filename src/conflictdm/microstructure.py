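"""Behavioral microstructure of linear-track tracking traces.

Raw center-point tracking is turned into motion segments (toward the
goal, toward the start, or paused), pause-resolved approach-avoid
decisions, data-driven spatial zones, and response-time summaries.

Coordinate convention: 1-D track-proper coordinate with 0 at the Start
box door, increasing toward the goal; the Start box maps to negative x
and the Goal box to x greater than the track length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

log = logging.getLogger(__name__)

__all__ = [
    "TrackGeometry",
    "TrackingTrace",
    "MotionSegment",
    "PauseEvent",
    "ZonePartition",
    "RTSummary",
    "UnusableTraceError",
    "interpolate_gaps",
    "classify_motion",
    "detect_pauses",
    "assign_zones",
    "cluster_zones",
    "summarize_rts",
    "summarize_session",
]

MIN_PAUSE_S = 0.090
MIN_MOVE_CM = 1.5
STILL_TOL_CM = 0.2


class UnusableTraceError(ValueError):
    pass


@dataclass(frozen=True)
class TrackGeometry:
    """Linear-track layout: Start box | track proper | Goal box."""

    start_box_len: float = 22.0
    track_len: float = 88.0
    goal_box_len: float = 10.0
    bin_width: float = 5.0
    zone_boundaries: tuple[float, ...] = (15.0, 83.0)

    def __post_init__(self) -> None:
        for name in ("start_box_len", "track_len", "goal_box_len", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        zb = tuple(float(b) for b in self.zone_boundaries)
        if any(not 0 < b < self.track_len for b in zb):
            raise ValueError("zone boundaries must lie within (0, track_len)")
        if any(b2 <= b1 for b1, b2 in zip(zb, zb[1:])):
            raise ValueError("zone boundaries must be strictly increasing")
        object.__setattr__(self, "zone_boundaries", zb)

    @property
    def total_len(self) -> float:
        return self.start_box_len + self.track_len + self.goal_box_len

    def bin_edges(self) -> np.ndarray:
        edges = np.arange(0.0, self.track_len, self.bin_width)
        return np.append(edges, self.track_len)

    def zone_of(self, x: float) -> str:
        """Zone label for an on-track position (start/mid/goal for 3 zones)."""
        names = _zone_names(len(self.zone_boundaries) + 1)
        i = int(np.searchsorted(self.zone_boundaries, x, side="right"))
        return names[i]


def _zone_names(n: int) -> list[str]:
    if n == 3:
        return ["start", "mid", "goal"]
    return [f"zone{i}" for i in range(n)]


@dataclass
class TrackingTrace:
    """Timestamped 1-D track positions of one subject in one session."""

    subject_id: str
    session_id: str
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.timestamps.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("all per-frame arrays must have equal length")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must strictly increase")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.timestamps)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.timestamps,
                "x_cm": self.x,
                "y_cm": self.y,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "", session_id: str = "") -> "TrackingTrace":
        df = pd.read_csv(path)
        return cls(
            subject_id=subject_id,
            session_id=session_id,
            timestamps=df["time_s"].to_numpy(),
            x=df["x_cm"].to_numpy(),
            y=df["y_cm"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
        )


@dataclass(frozen=True)
class MotionSegment:
    start: int  # first frame index (inclusive)
    end: int  # last frame index (inclusive)
    state: str  # toward_goal | toward_start | paused
    displacement: float


@dataclass
class PauseEvent:
    """One approach-avoid decision resolved from a pause."""

    subject_id: str
    onset_time: float
    offset_time: float
    location: float
    outcome: str  # approach | avoid
    zone: str | None = None
    session_id: str = ""
    onset_frame: int = -1

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time


@dataclass
class ZonePartition:
    k: int
    boundaries: tuple[float, ...]
    silhouette_values: np.ndarray | None
    mean_silhouette: float | None
    min_silhouette: float | None
    bin_centers: np.ndarray
    labels: np.ndarray
    contiguous: bool

    def zone_of(self, x: float) -> str:
        names = _zone_names(len(self.boundaries) + 1)
        return names[int(np.searchsorted(self.boundaries, x, side="right"))]


@dataclass
class RTSummary:
    n: int
    hist_counts: np.ndarray | None = None
    hist_edges: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None
    r2: float | None = None
    cv_slope: float | None = None
    cv_intercept: float | None = None
    cv_r2: float | None = None
    group_means: np.ndarray | None = None
    group_sds: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def interpolate_gaps(trace: TrackingTrace) -> TrackingTrace:
    """Fill invalid frames by linear interpolation between valid neighbors.

    Leading/trailing invalid frames take the nearest valid value.
    """
    valid = trace.valid
    if valid.sum() < 2:
        raise UnusableTraceError("fewer than 2 valid frames")
    if valid.all():
        return trace
    t = trace.timestamps
    x = np.interp(t, t[valid], trace.x[valid])
    y = np.interp(t, t[valid], trace.y[valid])
    return replace(trace, x=x, y=y, valid=np.ones_like(valid))


def classify_motion(
    trace: TrackingTrace,
    geometry: TrackGeometry | None = None,
    *,
    still_tol: float = STILL_TOL_CM,
    min_pause_s: float = MIN_PAUSE_S,
    min_move_cm: float = MIN_MOVE_CM,
) -> list[MotionSegment]:
    """Partition frames into paused / toward_goal / toward_start segments.

    A frame-to-frame step is "still" when |dx| < still_tol. A pause is a
    maximal still run spanning at least ``min_pause_s`` (counting frames
    at the nominal frame interval) that is followed by an uninterrupted
    movement run of cumulative displacement >= ``min_move_cm``. Movement
    runs below the displacement criterion and non-qualifying still runs
    are absorbed into the neighboring segment.
    """
    if not trace.valid.all():
        raise ValueError("classify_motion requires a gap-filled trace")
    n = len(trace)
    if n < 2:
        return []
    dt = trace.frame_interval
    dx = np.diff(trace.x)
    step = np.where(np.abs(dx) < still_tol, 0, np.sign(dx)).astype(int)

    # run-length encode the step sequence
    runs = []  # (first_step, last_step, kind)
    a = 0
    for i in range(1, step.size + 1):
        if i == step.size or step[i] != step[a]:
            runs.append((a, i - 1, step[a]))
            a = i

    state = np.array([""] * n, dtype=object)
    for ridx, (a, b, kind) in enumerate(runs):
        if kind == 0:
            # still run: frames a .. b+1 are (near) constant;
            # the frame-count duration is (#frames) * dt
            dur = (b - a + 2) * dt
            if dur + 1e-9 < min_pause_s:
                continue
            if ridx + 1 >= len(runs):
                continue  # session ends while still: handled downstream
            na, nb, nkind = runs[ridx + 1]
            move = trace.x[nb + 1] - trace.x[na]
            if abs(move) + 1e-9 >= min_move_cm:
                state[a : b + 2] = "paused"
        else:
            move = trace.x[b + 1] - trace.x[a]
            if abs(move) + 1e-9 >= min_move_cm:
                lab = "toward_goal" if kind > 0 else "toward_start"
                sl = state[a : b + 2]
                sl[sl == ""] = lab  # do not overwrite pause frames
                state[a : b + 2] = sl

    # absorb unassigned frames into the previous (else next) segment's state
    last = None
    for i in range(n):
        if state[i] == "":
            if last is not None:
                state[i] = last
        else:
            last = state[i]
    # degenerate fallback (nothing qualified): label by net displacement
    default = "toward_goal" if trace.x[-1] >= trace.x[0] else "toward_start"
    nxt = None
    for i in range(n - 1, -1, -1):
        if state[i] == "":
            state[i] = nxt if nxt is not None else default
        else:
            nxt = state[i]

    segments = []
    a = 0
    for i in range(1, n + 1):
        if i == n or state[i] != state[a]:
            segments.append(
                MotionSegment(
                    start=a,
                    end=i - 1,
                    state=str(state[a]),
                    displacement=float(trace.x[i - 1] - trace.x[a]),
                )
            )
            a = i
    return segments


def detect_pauses(
    segments: list[MotionSegment],
    trace: TrackingTrace,
    geometry: TrackGeometry,
) -> list[PauseEvent]:
    """One PauseEvent per paused segment located on the track proper.

    The outcome is the direction of the first qualifying post-pause
    movement; pauses at session end with no subsequent movement are
    dropped and logged. Pauses inside the Start or Goal box are excluded.
    """
    events: list[PauseEvent] = []
    for i, seg in enumerate(segments):
        if seg.state != "paused":
            continue
        loc = float(np.median(trace.x[seg.start : seg.end + 1]))
        if not 0.0 <= loc <= geometry.track_len:
            continue
        outcome = None
        for nseg in segments[i + 1 :]:
            if nseg.state in ("toward_goal", "toward_start"):
                outcome = "approach" if nseg.state == "toward_goal" else "avoid"
                break
        if outcome is None:
            log.info(
                "dropping pause at t=%.3f: no subsequent movement before session end",
                trace.timestamps[seg.start],
            )
            continue
        dt = trace.frame_interval
        onset = float(trace.timestamps[seg.start])
        # frame-count duration: a k-frame still span lasts k * dt
        offset = onset + (seg.end - seg.start + 1) * dt
        events.append(
            PauseEvent(
                subject_id=trace.subject_id,
                session_id=trace.session_id,
                onset_time=onset,
                offset_time=offset,
                location=loc,
                outcome=outcome,
                onset_frame=seg.start,
            )
        )
    return events


def assign_zones(pauses: list[PauseEvent], boundaries) -> list[PauseEvent]:
    """Label each pause with its zone given ordered boundary positions."""
    names = _zone_names(len(tuple(boundaries)) + 1)
    for p in pauses:
        p.zone = names[int(np.searchsorted(boundaries, p.location, side="right"))]
    return pauses


def _bin_features(pauses, geometry, conflict_only=False):
    edges = geometry.bin_edges()
    locs = np.array([p.location for p in pauses])
    durs = np.array([p.duration for p in pauses])
    appr = np.array([p.outcome == "approach" for p in pauses], dtype=float)
    which = np.clip(np.searchsorted(edges, locs, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = which == b
        if not m.any():
            continue
        rows.append(
            {
                "bin": b,
                "center": 0.5 * (edges[b] + edges[b + 1]),
                "median_loc": float(np.median(locs[m])),
                "count": int(m.sum()),
                "median_dur": float(np.median(durs[m])),
                "pct_approach": float(100.0 * appr[m].mean()),
            }
        )
    return pd.DataFrame(rows)


def cluster_zones(
    pauses: list[PauseEvent],
    geometry: TrackGeometry,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> ZonePartition:
    """k-means over per-5cm-bin pause features; silhouette-scored zones.

    Features per non-empty bin: median location, pause count, median
    pause duration, and % approach decisions, z-scored before
    clustering. Zone boundaries are midpoints between adjacent bins
    assigned to different clusters when the clusters are spatially
    contiguous; a non-contiguous solution is reported with a warning.
    """
    feats = _bin_features(pauses, geometry)
    if len(feats) < k:
        raise ValueError(f"k={k} exceeds the {len(feats)} non-empty 5 cm bins")
    order = np.argsort(feats["median_loc"].to_numpy())
    feats = feats.iloc[order].reset_index(drop=True)
    X = feats[["median_loc", "count", "median_dur", "pct_approach"]].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd

    if k == 1:
        return ZonePartition(
            k=1,
            boundaries=(),
            silhouette_values=None,
            mean_silhouette=None,
            min_silhouette=None,
            bin_centers=feats["center"].to_numpy(),
            labels=np.zeros(len(feats), dtype=int),
            contiguous=True,
        )

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Xz)
    sil = silhouette_samples(Xz, labels) if len(feats) > k else None

    # contiguity along the track: each cluster label occupies one block
    blocks = [labels[0]]
    for lab in labels[1:]:
        if lab != blocks[-1]:
            blocks.append(lab)
    contiguous = len(blocks) == k
    if not contiguous:
        log.warning("zone clusters are not spatially contiguous: %s", labels.tolist())

    centers = feats["median_loc"].to_numpy()
    bin_centers = feats["center"].to_numpy()
    bounds = tuple(
        float(0.5 * (centers[i] + centers[i + 1]))
        for i in range(len(labels) - 1)
        if labels[i] != labels[i + 1]
    )
    return ZonePartition(
        k=k,
        boundaries=bounds,
        silhouette_values=sil,
        mean_silhouette=None if sil is None else float(sil.mean()),
        min_silhouette=None if sil is None else float(sil.min()),
        bin_centers=bin_centers,
        labels=labels,
        contiguous=contiguous,
    )


def summarize_rts(
    pauses: list[PauseEvent],
    min_events: int = 20,
    bin_width: float = 5.0,
) -> RTSummary:
    """Log-normal MLE of pause durations plus the mean-SD (CV) linearity fit.

    The histogram R^2 compares the fitted log-normal density with a
    Freedman-Diaconis-binned empirical density. The CV fit regresses the
    SD of RT on the mean of RT across 5 cm location bins.
    """
    durs = np.array([p.duration for p in pauses], dtype=float)
    out = RTSummary(n=durs.size)
    if durs.size < min_events:
        out.flags.append("too_few_events")
        return out
    logd = np.log(durs)
    out.mu = float(logd.mean())
    out.sigma = float(logd.std())
    if out.sigma == 0:
        out.flags.append("degenerate_sigma")
        return out
    counts, edges = np.histogram(durs, bins="fd", density=True)
    out.hist_counts, out.hist_edges = counts, edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    fitted = stats.lognorm.pdf(centers, s=out.sigma, scale=np.exp(out.mu))
    ss_res = float(np.sum((counts - fitted) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    out.r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    if out.r2 is None:
        out.flags.append("histogram_r2_undefined")

    locs = np.array([p.location for p in pauses])
    bins = np.floor(locs / bin_width).astype(int)
    means, sds = [], []
    for b in np.unique(bins):
        m = bins == b
        if m.sum() >= 3:
            means.append(durs[m].mean())
            sds.append(durs[m].std(ddof=1))
    if len(means) >= 3:
        means = np.asarray(means)
        sds = np.asarray(sds)
        out.group_means, out.group_sds = means, sds
        res = stats.linregress(means, sds)
        out.cv_slope = float(res.slope)
        out.cv_intercept = float(res.intercept)
        out.cv_r2 = float(res.rvalue**2)
    else:
        out.flags.append("too_few_bins_for_cv_fit")
    return out


def summarize_session(trace: TrackingTrace, geometry: TrackGeometry) -> dict:
    """Region occupancy, distance-from-goal and velocity series, goal latency."""
    t = trace.timestamps
    x = trace.x
    dt = trace.frame_interval
    in_start = x < 0
    on_track = (x >= 0) & (x <= geometry.track_len)
    in_goal = x > geometry.track_len
    velocity = np.gradient(x, t)
    goal_frames = np.nonzero(x >= geometry.track_len)[0]
    latency = float(t[goal_frames[0]] - t[0]) if goal_frames.size else None
    return {
        "time_start_box_s": float(in_start.sum() * dt),
        "time_track_s": float(on_track.sum() * dt),
        "time_goal_box_s": float(in_goal.sum() * dt),
        "distance_from_goal_cm": geometry.track_len - x,
        "velocity_cm_s": velocity,
        "latency_to_goal_s": latency,
    }
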