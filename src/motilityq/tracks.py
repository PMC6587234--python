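"""Single-cell trajectory analytics.

Mirrors the manual-tracking → chemotaxis-tool workflow: parse a plain-text
track table (track number, slice, x, y), calibrate to μm and hours, compute
per-track motility statistics (accumulated and Euclidean distance, velocity,
directionality, forward migration index), filter by distance/velocity
restrictions, set tracks to a common origin, bin net-displacement directions
into a rose histogram, and aggregate a cohort mean ± SD.

Definitions
-----------
accumulated distance
    Sum of consecutive-point Euclidean step lengths (μm).
euclidean distance
    Straight-line displacement from first to last point (μm).
velocity
    Accumulated distance divided by elapsed time (μm/h); equals the mean of
    per-step velocities when the sampling interval is constant.
directionality
    euclidean / accumulated, in [0, 1]; 1 for perfectly straight movement.
FMI (forward migration index)
    Net displacement along a reference axis divided by the accumulated path
    length, per track, then averaged over the cohort (the ibidi convention);
    signed, in [−1, 1].

A stationary track (accumulated distance 0) takes directionality, FMI and
velocity 0 and is flagged rather than dropped. Missing slices contribute one
straight step spanning the actual elapsed frames; no interpolation.
"""

from __future__ import annotations

import io as _io
import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imcore import InvalidInputError, MotilityWarning

__all__ = [
    "Track",
    "TrackSet",
    "TrackStats",
    "RoseHistogram",
    "CohortSummary",
    "TrackParseError",
    "parse_manual_tracking",
    "calibrate",
    "track_stats",
    "apply_restrictions",
    "common_origin",
    "rose_histogram",
    "aggregate",
    "plot_trajectories",
    "plot_rose",
]


class TrackParseError(ValueError):
    """A track table could not be parsed."""


@dataclass(frozen=True)
class Track:
    """Ordered positions of one cell: (frame index, x, y) per point."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if not (f.shape == x.shape == y.shape) or f.ndim != 1:
            raise InvalidInputError("track arrays must be 1-D and equally long")
        if f.size and np.any(np.diff(f) <= 0):
            raise InvalidInputError("frame indices must be strictly increasing")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_points(self) -> int:
        return self.frames.size


@dataclass(frozen=True)
class TrackSet:
    """A cohort of tracks with (optional) calibration state.

    Uncalibrated sets hold pixel coordinates and no time interval; calibrated
    sets hold μm and hours. Calibrating twice is rejected, guarding against
    the classic double-scaling mistake.
    """

    tracks: tuple[Track, ...]
    time_interval: float | None = None
    px_size: float | None = None
    calibrated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "tracks", tuple(self.tracks))
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise InvalidInputError("track ids must be unique")
        if self.time_interval is not None and self.time_interval <= 0:
            raise InvalidInputError("time_interval must be > 0")

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class TrackStats:
    """Per-track motility statistics (see module docstring for definitions)."""

    track_id: int
    accumulated_distance: float
    euclidean_distance: float
    velocity: float
    directionality: float
    fmi_x: float
    fmi_y: float
    stationary: bool = False

    _FIELDS = (
        "accumulated_distance",
        "euclidean_distance",
        "velocity",
        "directionality",
        "fmi_x",
        "fmi_y",
    )


@dataclass(frozen=True)
class RoseHistogram:
    """Counts of net-displacement directions per angular sector.

    Bin k covers [k·2π/n, (k+1)·2π/n) from angle 0 (half-open, so a boundary
    angle falls in the higher bin). Angles use standard math orientation:
    the screen y-axis is flipped so "up" is +90°. Tracks with zero net
    displacement are excluded from the counts and tallied separately.
    """

    n_bins: int
    counts: np.ndarray
    n_stationary: int = 0


@dataclass(frozen=True)
class CohortSummary:
    """Mean and sample SD of each statistic across tracks (n reported)."""

    n: int
    mean: pd.Series
    sd: pd.Series
    single_track: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


# ---------------------------------------------------------------------------
# parsing and calibration
# ---------------------------------------------------------------------------

def _normalise(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def parse_manual_tracking(table) -> TrackSet:
    """Parse a manual-tracking export table into an uncalibrated TrackSet.

    Accepts a path, the table text itself, or a DataFrame. The table must be
    tab- or whitespace-separated with a header containing track-number,
    slice/frame, x and y columns (extra distance/velocity columns are
    ignored). Points are ordered by slice; non-consecutive slices are kept
    as-is. Duplicate (track, slice) rows are rejected.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        if isinstance(table, (str, os.PathLike)) and "\n" not in str(table) and os.path.exists(table):
            with open(table, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(table)
        if not text.strip():
            raise TrackParseError("empty track table")
        try:
            df = pd.read_csv(_io.StringIO(text), sep=None, engine="python")
        except Exception as exc:  # pragma: no cover - pandas error variety
            raise TrackParseError(f"could not parse track table: {exc}") from exc

    cols = {_normalise(c): c for c in df.columns}

    def locate(*keys: str, required: str) -> str:
        for norm, original in cols.items():
            if any(k == norm or norm.startswith(k) for k in keys):
                return original
        raise TrackParseError(f"missing required column: {required}")

    c_track = locate("track", "trackn", required="track number")
    c_slice = locate("slice", "slicen", "frame", required="slice/frame number")
    c_x = locate("x", required="x")
    c_y = locate("y", required="y")

    df = df[[c_track, c_slice, c_x, c_y]].dropna()
    if df.empty:
        warnings.warn("track table contains a header but no rows", MotilityWarning,
                      stacklevel=2)
        return TrackSet(tracks=())
    dup = df.duplicated(subset=[c_track, c_slice])
    if dup.any():
        bad = df.loc[dup, [c_track, c_slice]].iloc[0]
        raise TrackParseError(
            f"duplicate (track, slice) row: track {bad[c_track]}, slice {bad[c_slice]}"
        )
    tracks = []
    for tid, grp in df.groupby(c_track, sort=True):
        grp = grp.sort_values(c_slice)
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp[c_slice].to_numpy(dtype=np.int64),
                x=grp[c_x].to_numpy(dtype=np.float64),
                y=grp[c_y].to_numpy(dtype=np.float64),
            )
        )
    return TrackSet(tracks=tuple(tracks))


def calibrate(ts: TrackSet, px_size: float, time_interval: float) -> TrackSet:
    """Scale pixel coordinates to μm and attach the frame interval (h).

    Recalibrating an already calibrated set raises, since applying the scale
    twice silently corrupts every distance.
    """
    if px_size <= 0 or time_interval <= 0:
        raise InvalidInputError("px_size and time_interval must be > 0")
    if ts.calibrated:
        raise InvalidInputError("track set is already calibrated")
    tracks = tuple(
        Track(t.track_id, t.frames, t.x * px_size, t.y * px_size) for t in ts.tracks
    )
    return TrackSet(tracks=tracks, time_interval=time_interval, px_size=px_size,
                    calibrated=True)


# ---------------------------------------------------------------------------
# per-track statistics
# ---------------------------------------------------------------------------

def track_stats(t: Track, time_interval: float) -> TrackStats:
    """Compute the motility statistics of one track (needs >= 2 points)."""
    if t.n_points < 2:
        raise InvalidInputError("track statistics require at least two points")
    if time_interval <= 0:
        raise InvalidInputError("time_interval must be > 0")
    dx = np.diff(t.x)
    dy = np.diff(t.y)
    steps = np.hypot(dx, dy)
    accumulated = float(steps.sum())
    euclidean = float(np.hypot(t.x[-1] - t.x[0], t.y[-1] - t.y[0]))
    elapsed = float(t.frames[-1] - t.frames[0]) * time_interval
    velocity = accumulated / elapsed
    if accumulated > 0:
        directionality = euclidean / accumulated
        fmi_x = float(t.x[-1] - t.x[0]) / accumulated
        fmi_y = float(t.y[-1] - t.y[0]) / accumulated
        stationary = False
    else:
        directionality = fmi_x = fmi_y = 0.0
        stationary = True
    return TrackStats(
        track_id=t.track_id,
        accumulated_distance=accumulated,
        euclidean_distance=euclidean,
        velocity=velocity,
        directionality=directionality,
        fmi_x=fmi_x,
        fmi_y=fmi_y,
        stationary=stationary,
    )


def _all_stats(ts: TrackSet) -> list[TrackStats]:
    if not ts.calibrated or ts.time_interval is None:
        raise InvalidInputError("calibrate the track set first")
    return [track_stats(t, ts.time_interval) for t in ts.tracks]


def apply_restrictions(
    ts: TrackSet, min_accumulated: float = 0.0, min_velocity: float = 0.0
) -> TrackSet:
    """Keep tracks with accumulated distance AND velocity above thresholds.

    Zero thresholds are the identity; impossible thresholds yield an empty
    set, not an error.
    """
    if min_accumulated < 0 or min_velocity < 0:
        raise InvalidInputError("restriction thresholds must be >= 0")
    if min_accumulated == 0 and min_velocity == 0:
        return ts
    stats = _all_stats(ts)
    kept = tuple(
        t
        for t, s in zip(ts.tracks, stats)
        if s.accumulated_distance >= min_accumulated and s.velocity >= min_velocity
    )
    return replace(ts, tracks=kept)


def common_origin(ts: TrackSet) -> TrackSet:
    """Translate every track so its first point is (0, 0); steps unchanged."""
    tracks = tuple(
        Track(t.track_id, t.frames, t.x - t.x[0], t.y - t.y[0]) for t in ts.tracks
    )
    return replace(ts, tracks=tracks)


def rose_histogram(ts: TrackSet, n_bins: int = 16) -> RoseHistogram:
    """Bin net-displacement directions into ``n_bins`` angular sectors."""
    if n_bins < 2:
        raise InvalidInputError("n_bins must be >= 2")
    counts = np.zeros(n_bins, dtype=np.int64)
    stationary = 0
    width = 2.0 * np.pi / n_bins
    for t in ts.tracks:
        dx = t.x[-1] - t.x[0]
        dy = t.y[-1] - t.y[0]
        if dx == 0 and dy == 0:
            stationary += 1
            continue
        angle = np.arctan2(-dy, dx) % (2.0 * np.pi)  # screen y flipped
        k = int(angle // width)
        counts[min(k, n_bins - 1)] += 1
    return RoseHistogram(n_bins=n_bins, counts=counts, n_stationary=stationary)


def aggregate(ts: TrackSet) -> CohortSummary:
    """Cohort mean and sample (n−1) SD of every per-track statistic.

    A single-track cohort reports SD 0 with the ``single_track`` flag set.
    """
    stats = _all_stats(ts)
    if not stats:
        raise InvalidInputError("cannot aggregate an empty track set")
    df = pd.DataFrame(
        {f: [getattr(s, f) for s in stats] for f in TrackStats._FIELDS}
    )
    single = len(stats) == 1
    sd = df.std(ddof=1) if not single else pd.Series(0.0, index=df.columns)
    return CohortSummary(n=len(stats), mean=df.mean(), sd=sd, single_track=single)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_trajectories(ts: TrackSet, ax=None):
    """Common-origin trajectory plot (μm); returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    co = common_origin(ts)
    for t in co.tracks:
        ax.plot(t.x, -t.y, lw=0.8)
    ax.axhline(0, color="0.6", lw=0.5)
    ax.axvline(0, color="0.6", lw=0.5)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_aspect("equal")
    return ax


def plot_rose(hist: RoseHistogram, ax=None):
    """Polar rose diagram of migration directions; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    width = 2.0 * np.pi / hist.n_bins
    theta = np.arange(hist.n_bins) * width + width / 2.0
    ax.bar(theta, hist.counts, width=width, edgecolor="k", linewidth=0.5)
    return ax
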