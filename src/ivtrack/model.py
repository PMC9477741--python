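"""Core domain types for intravital cell-track analysis.

All positions are in micrometres and all times in minutes; every speed in
this package is therefore in µm/min, the unit in which intravital imaging
studies report lymphocyte motility. Arrest coefficients are stored as
percentages (0–100).

A :class:`Track` is one cell's ordered positions; a :class:`TrackSet` is a
cohort of tracks acquired under the same imaging parameters and condition
label. Tracks store their coordinates as numpy arrays for efficiency and
expose a ``points`` view of :class:`TrackPoint` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TrackError",
    "TrackPoint",
    "Track",
    "TrackSet",
    "AcquisitionParams",
    "MotilityMetrics",
    "MSDCurve",
    "validate_track",
]

#: tolerance (minutes) when checking that time steps sit on the frame grid
TIME_TOL = 1e-6


class TrackError(ValueError):
    """Validation failure for a track or track set.

    ``code`` is a stable machine-readable identity (``"too_short"``,
    ``"non_monotone_time"``, ``"non_finite"``, ``"off_grid_time"``,
    ``"duplicate_track_id"``, ``"mixed_frame_interval"``, ``"empty"``).
    """

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class TrackPoint:
    """A single tracked position: time (min) and coordinates (µm)."""

    t: float
    x: float
    y: float
    z: float | None = None


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging acquisition geometry and noise.

    Defaults follow typical intravital two-photon time-lapse settings for
    the small intestine: a 40–60 µm tissue volume scanned at 7 µm z-steps
    every 60 s, with sub-micron spot-localization error.
    """

    frame_interval: float = 1.0  # minutes
    volume_depth: float = 50.0  # µm
    z_step: float = 7.0  # µm
    localization_sigma: float = 0.3  # µm

    def __post_init__(self):
        for name in ("frame_interval", "volume_depth", "z_step", "localization_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise TrackError("invalid_acquisition", f"{name} must be positive, got {v!r}")


@dataclass
class Track:
    """One cell's ordered positions.

    Coordinates are stored as 1-D float arrays (``z`` is ``None`` after 2-D
    projection). ``frame_interval`` is the nominal sampling interval in
    minutes; after gap-splitting every time step is an integer multiple of
    it (a multiple > 1 marks a tolerated gap).
    """

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None
    cell_class: str = ""
    condition: str = ""
    frame_interval: float = 1.0
    #: id of the original track if this one is a segment split out of it
    source_id: str | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)

    # -- convenience ------------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Track duration in minutes."""
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    @property
    def ndim(self) -> int:
        return 2 if self.z is None else 3

    @property
    def positions(self) -> np.ndarray:
        """(n_points, ndim) coordinate array."""
        cols = [self.x, self.y] if self.z is None else [self.x, self.y, self.z]
        return np.column_stack(cols)

    @property
    def points(self) -> list[TrackPoint]:
        if self.z is None:
            return [TrackPoint(t, x, y) for t, x, y in zip(self.t, self.x, self.y)]
        return [TrackPoint(t, x, y, z) for t, x, y, z in zip(self.t, self.x, self.y, self.z)]

    @classmethod
    def from_points(
        cls,
        track_id: str,
        points: Sequence[TrackPoint],
        *,
        cell_class: str = "",
        condition: str = "",
        frame_interval: float = 1.0,
    ) -> "Track":
        has_z = any(p.z is not None for p in points)
        return cls(
            track_id=track_id,
            t=np.array([p.t for p in points], dtype=float),
            x=np.array([p.x for p in points], dtype=float),
            y=np.array([p.y for p in points], dtype=float),
            z=np.array([p.z for p in points], dtype=float) if has_z else None,
            cell_class=cell_class,
            condition=condition,
            frame_interval=frame_interval,
        )

    def with_positions(self, pos: np.ndarray) -> "Track":
        """Copy of this track with coordinates replaced by ``pos``."""
        pos = np.asarray(pos, dtype=float)
        z = pos[:, 2].copy() if pos.shape[1] == 3 else None
        return replace(self, x=pos[:, 0].copy(), y=pos[:, 1].copy(), z=z)


def validate_track(track: Track) -> Track:
    """Check track invariants and return the track unchanged.

    Raises :class:`TrackError` with a distinct ``code`` for each failure
    mode: fewer than two points (``too_short``), non-increasing time
    (``non_monotone_time``), non-finite values (``non_finite``), or time
    steps that are not positive integer multiples of the frame interval
    (``off_grid_time``).
    """
    if track.n_points < 2:
        raise TrackError("too_short", f"track {track.track_id!r} has {track.n_points} point(s); need >= 2")
    coords = track.positions
    if not np.all(np.isfinite(track.t)) or not np.all(np.isfinite(coords)):
        raise TrackError("non_finite", f"track {track.track_id!r} contains non-finite time or coordinates")
    if np.any(track.t < 0):
        raise TrackError("non_finite", f"track {track.track_id!r} has negative time")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise TrackError("non_monotone_time", f"track {track.track_id!r} time is not strictly increasing")
    mult = dt / track.frame_interval
    if np.any(np.abs(mult - np.round(mult)) > TIME_TOL) or np.any(np.round(mult) < 1):
        raise TrackError(
            "off_grid_time",
            f"track {track.track_id!r} has time steps that are not multiples of "
            f"frame_interval={track.frame_interval}",
        )
    return track


@dataclass
class TrackSet:
    """A cohort of tracks sharing acquisition parameters and a condition label."""

    tracks: list[Track] = field(default_factory=list)
    condition: str = ""
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    #: set by :func:`ivtrack.preprocess.project_2d`
    projected: bool = False

    def __post_init__(self):
        ids = [tr.track_id for tr in self.tracks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackError("duplicate_track_id", f"duplicate track_id(s): {dup}")
        fi = {tr.frame_interval for tr in self.tracks}
        if len(fi) > 1:
            raise TrackError("mixed_frame_interval", f"tracks mix frame intervals: {sorted(fi)}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterable[Track]:
        return iter(self.tracks)

    @property
    def frame_interval(self) -> float:
        return self.tracks[0].frame_interval if self.tracks else self.acquisition.frame_interval

    def replace_tracks(self, tracks: list[Track], **kw) -> "TrackSet":
        ts = TrackSet(
            tracks=tracks,
            condition=kw.get("condition", self.condition),
            acquisition=self.acquisition,
            projected=kw.get("projected", self.projected),
        )
        return ts


@dataclass
class MotilityMetrics:
    """Per-track motility record.

    ``straightness`` is NaN when the path length is zero (a perfectly
    stationary track has no defined directionality). ``error`` is a reason
    string for tracks on which metrics could not be computed; such records
    carry NaN metrics but are never silently dropped.
    """

    track_id: str
    mean_speed: float = np.nan  # µm/min
    arrest_coefficient: float = np.nan  # percent, 0–100
    straightness: float = np.nan  # unitless, [0, 1]
    net_displacement: float = np.nan  # µm
    path_length: float = np.nan  # µm
    n_steps: int = 0
    cell_class: str = ""
    condition: str = ""
    error: str | None = None


@dataclass
class MSDCurve:
    """Mean squared displacement vs. lag time.

    ``lags`` are positive multiples of the frame interval (minutes),
    ``values`` are µm², and ``n_intervals`` counts the overlapping
    displacement intervals that contributed at each lag (summed over
    tracks for a cohort curve). ``n_tracks`` is per-lag for cohort curves
    and 1 for single-track curves.
    """

    lags: np.ndarray
    values: np.ndarray
    n_intervals: np.ndarray
    n_tracks: np.ndarray | None = None

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_intervals = np.asarray(self.n_intervals, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise TrackError("bad_msd_lags", "MSD lags must be strictly increasing")
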