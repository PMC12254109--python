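"""Cell tracks: I/O, step kinematics, binning, and descriptive chemotaxis metrics.

A track is an ordered sequence of (t, x, y) positions for one cell, in
minutes and micrometres. Step kinematics are computed relative to a wound:
the heading gamma_t of each step is its absolute direction of motion (the
angle of the displacement vector), and the bias angle beta is the direction
from the step's start position toward the wound centre. Headings are
absolute directions, not increments: the persistent component of the walk
model centres the next heading on the previous heading, which is only
coherent for absolute angles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLAIN_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]
TRACKMATE_COLUMNS = ["TRACK_ID", "POSITION_X", "POSITION_Y", "POSITION_T", "FRAME"]


class TrackFormatError(ValueError):
    """Raised when a track file does not match the expected dialect."""


class TrackValidationError(ValueError):
    """Raised when track contents violate invariants (e.g. duplicate times)."""


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class Track:
    """Ordered (t, x, y) positions of one cell; t in minutes, x/y in um."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise TrackValidationError(f"track {self.track_id}: t, x, y must be 1-D and equal length")
        if t.size == 0:
            raise TrackValidationError(f"track {self.track_id}: empty track")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise TrackValidationError(f"track {self.track_id}: non-finite coordinates")
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(f"track {self.track_id}: times not strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.t.size

    @property
    def n_steps(self) -> int:
        return max(self.t.size - 1, 0)


@dataclass(frozen=True)
class StepRecord:
    """Kinematics of one step of one cell, referenced to a wound."""

    track_id: str
    t: float  # minutes, at step start
    x: float  # um, step start
    y: float
    heading: float  # gamma_t, radians in (-pi, pi]
    previous_heading: float | None  # gamma_{t-1}, None for a track's first step
    bearing: float  # beta: direction from (x, y) to the wound reference point
    distance: float  # r: um from wound centre
    azimuth: float  # phi of (x, y) about the wound centre


@dataclass(frozen=True)
class WoundGeometry:
    """A circular wound with attractant sources along part of its edge.

    ``source_arc`` lists azimuth intervals (radians, within (-pi, pi]) over
    which point sources are placed; the default is the full circle. An
    inactive wound keeps its geometry (for binning and bearings) but
    contributes no attractant sources.
    """

    center: tuple[float, float]
    radius: float
    source_arc: tuple[tuple[float, float], ...] = ((-math.pi, math.pi),)
    n_sources: int = 36
    active: bool = True

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("wound radius must be positive")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        arcs = tuple((float(lo), float(hi)) for lo, hi in self.source_arc)
        for lo, hi in arcs:
            if not (-math.pi - 1e-12 <= lo < hi <= math.pi + 1e-12):
                raise ValueError(f"source arc ({lo}, {hi}) not an increasing interval within (-pi, pi]")
        object.__setattr__(self, "source_arc", arcs)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    def source_positions(self) -> np.ndarray:
        """(n, 2) array of point-source positions spread over the source arcs.

        Sources are allotted to arcs proportionally to arc length and placed
        at arc midpoints of equal subdivisions, so a full circle gives
        equally spaced sources with no duplicate at the branch cut.
        """
        lengths = np.array([hi - lo for lo, hi in self.source_arc])
        counts = np.maximum(1, np.round(self.n_sources * lengths / lengths.sum()).astype(int))
        # adjust rounding drift so the total equals n_sources
        while counts.sum() > self.n_sources:
            counts[np.argmax(counts)] -= 1
        while counts.sum() < self.n_sources:
            counts[np.argmin(counts)] += 1
        pts = []
        for (lo, hi), c in zip(self.source_arc, counts):
            phis = lo + (hi - lo) * (np.arange(c) + 0.5) / c
            pts.append(np.column_stack([
                self.center[0] + self.radius * np.cos(phis),
                self.center[1] + self.radius * np.sin(phis),
            ]))
        return np.concatenate(pts, axis=0)


@dataclass(frozen=True)
class BinGrid:
    """Spatiotemporal (and optional azimuthal) bins for pooling steps.

    Bins are half-open [lo, hi) in wound distance r (um) and time t (min).
    The default spatial grid starts at 70 um because steps inside 70 um
    (wound radius ~40 um plus a cell radius ~15-30 um) are excluded from
    attractant inference; the 0-70 um bin is still present so stage 1 can
    report it.
    """

    spatial_edges: tuple[float, ...] = (0.0, 70.0, 110.0, 150.0, 190.0, 230.0)
    temporal_edges: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)
    azimuth_ranges: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        se = tuple(float(v) for v in self.spatial_edges)
        te = tuple(float(v) for v in self.temporal_edges)
        if len(se) < 2 or np.any(np.diff(se) <= 0):
            raise ValueError("spatial_edges must be >= 2 strictly increasing values")
        if len(te) < 2 or np.any(np.diff(te) <= 0):
            raise ValueError("temporal_edges must be >= 2 strictly increasing values")
        object.__setattr__(self, "spatial_edges", se)
        object.__setattr__(self, "temporal_edges", te)
        if self.azimuth_ranges is not None:
            object.__setattr__(
                self, "azimuth_ranges", tuple((float(lo), float(hi)) for lo, hi in self.azimuth_ranges)
            )

    @property
    def n_spatial(self) -> int:
        return len(self.spatial_edges) - 1

    @property
    def n_temporal(self) -> int:
        return len(self.temporal_edges) - 1

    def spatial_centers(self) -> np.ndarray:
        e = np.asarray(self.spatial_edges)
        return 0.5 * (e[:-1] + e[1:])

    def temporal_centers(self) -> np.ndarray:
        e = np.asarray(self.temporal_edges)
        return 0.5 * (e[:-1] + e[1:])


# ---------------------------------------------------------------------------
# I/O


def _tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_min")
        tracks.append(
            Track(
                track_id=str(tid),
                t=sub["t_min"].to_numpy(float),
                x=sub["x_um"].to_numpy(float),
                y=sub["y_um"].to_numpy(float),
            )
        )
    return tracks


def load_tracks(
    path: str | Path,
    dialect: str = "plain",
    *,
    um_per_pixel: float = 1.0,
    min_per_time_unit: float = 1.0,
) -> list[Track]:
    """Read tracks from a CSV file.

    dialect "plain" expects columns track_id,frame,t_min,x_um,y_um.
    dialect "trackmate" expects TRACK_ID,POSITION_X,POSITION_Y,POSITION_T,FRAME
    (the TrackMate spot-export layout); when POSITION_* are uncalibrated,
    supply ``um_per_pixel`` and ``min_per_time_unit``.
    """
    path = Path(path)
    if dialect == "trackmate":
        # TrackMate CSV exports carry up to three non-data header rows; keep
        # only rows whose FRAME parses as a number.
        df = pd.read_csv(path, low_memory=False)
        missing = [c for c in TRACKMATE_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"{path}: missing TrackMate column(s) {missing}")
        df = df[pd.to_numeric(df["FRAME"], errors="coerce").notna()].copy()
        out = pd.DataFrame(
            {
                "track_id": df["TRACK_ID"].astype(str),
                "frame": pd.to_numeric(df["FRAME"]).astype(int),
                "t_min": pd.to_numeric(df["POSITION_T"]).astype(float) * min_per_time_unit,
                "x_um": pd.to_numeric(df["POSITION_X"]).astype(float) * um_per_pixel,
                "y_um": pd.to_numeric(df["POSITION_Y"]).astype(float) * um_per_pixel,
            }
        )
    elif dialect == "plain":
        df = pd.read_csv(path)
        missing = [c for c in PLAIN_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"{path}: missing column(s) {missing}")
        out = df[PLAIN_COLUMNS].copy()
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _tracks_from_frame(out)


def save_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks as plain-dialect CSV (track_id,frame,t_min,x_um,y_um)."""
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append((tr.track_id, k, tr.t[k], tr.x[k], tr.y[k]))
    pd.DataFrame(rows, columns=PLAIN_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Step kinematics


def compute_steps(track: Track, wound: WoundGeometry) -> list[StepRecord]:
    """Per-step headings, wound bearings, distances and azimuths.

    Stationary steps (zero displacement: heading undefined) and steps
    starting exactly at the wound centre (bearing undefined) are excluded;
    the count of exclusions is logged. The step following an excluded step
    keeps its true previous heading where one exists.
    """
    if len(track) < 2:
        raise TrackValidationError(f"track {track.track_id}: need >= 2 points for steps")
    cx, cy = wound.center
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    headings = np.arctan2(dy, dx)
    moving = (dx != 0.0) | (dy != 0.0)

    records: list[StepRecord] = []
    n_dropped = 0
    prev_heading: float | None = None
    for k in range(dx.size):
        x0, y0, t0 = track.x[k], track.y[k], track.t[k]
        r = math.hypot(x0 - cx, y0 - cy)
        if not moving[k] or r == 0.0:
            n_dropped += 1
            if moving[k]:
                prev_heading = float(headings[k])
            continue
        records.append(
            StepRecord(
                track_id=track.track_id,
                t=float(t0),
                x=float(x0),
                y=float(y0),
                heading=float(wrap_angle(headings[k])),
                previous_heading=prev_heading,
                bearing=float(math.atan2(cy - y0, cx - x0)),
                distance=r,
                azimuth=float(math.atan2(y0 - cy, x0 - cx)),
            )
        )
        prev_heading = float(headings[k])
    if n_dropped:
        logger.info("track %s: excluded %d degenerate step(s)", track.track_id, n_dropped)
    return records


def assign_bins(
    steps: Sequence[StepRecord], grid: BinGrid
) -> dict[tuple[int, ...], list[StepRecord]]:
    """Partition steps into (time, space[, azimuth]) bins.

    Keys are (i_time, j_space) or (i_time, j_space, k_azimuth); bins are
    half-open [lo, hi). Steps outside the grid (or outside all azimuth
    ranges, when given) are dropped; the dropped count is logged.
    """
    se = np.asarray(grid.spatial_edges)
    te = np.asarray(grid.temporal_edges)
    out: dict[tuple[int, ...], list[StepRecord]] = {}
    n_dropped = 0
    for s in steps:
        j = int(np.searchsorted(se, s.distance, side="right")) - 1
        i = int(np.searchsorted(te, s.t, side="right")) - 1
        if not (0 <= j < grid.n_spatial and 0 <= i < grid.n_temporal):
            n_dropped += 1
            continue
        if grid.azimuth_ranges is not None:
            k = next(
                (ki for ki, (lo, hi) in enumerate(grid.azimuth_ranges) if lo <= s.azimuth < hi),
                None,
            )
            if k is None:
                n_dropped += 1
                continue
            key: tuple[int, ...] = (i, j, k)
        else:
            key = (i, j)
        out.setdefault(key, []).append(s)
    if n_dropped:
        logger.info("assign_bins: dropped %d step(s) outside the grid", n_dropped)
    return out


# ---------------------------------------------------------------------------
# Descriptive metrics


def chemotaxis_metrics(track: Track, wound: WoundGeometry) -> dict[str, float]:
    """Standard per-track chemotaxis summary statistics.

    Returns accumulated path distance (um), mean velocity (um/min),
    start-to-end Euclidean distance (um), directionality (Euclidean /
    accumulated, in [0, 1]), terminal displacement (final distance to the
    wound centre, um) and delta displacement (initial minus final distance
    to the wound centre, um; positive means net approach).
    """
    if len(track) < 2:
        raise TrackValidationError(f"track {track.track_id}: need >= 2 points for metrics")
    cx, cy = wound.center
    seg = np.hypot(np.diff(track.x), np.diff(track.y))
    accumulated = float(seg.sum())
    euclid = float(math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    duration = float(track.t[-1] - track.t[0])
    r0 = math.hypot(track.x[0] - cx, track.y[0] - cy)
    r1 = math.hypot(track.x[-1] - cx, track.y[-1] - cy)
    return {
        "track_id": track.track_id,
        "accumulated_distance_um": accumulated,
        "mean_velocity_um_per_min": accumulated / duration,
        "euclidean_distance_um": euclid,
        "directionality": euclid / accumulated if accumulated > 0 else 0.0,
        "terminal_displacement_um": r1,
        "delta_displacement_um": r0 - r1,
    }


def metrics_table(tracks: Iterable[Track], wound: WoundGeometry) -> pd.DataFrame:
    """Chemotaxis metrics for many tracks, one row per track."""
    return pd.DataFrame([chemotaxis_metrics(tr, wound) for tr in tracks])
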