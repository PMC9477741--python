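"""Preprocessing of raw track tables before metric computation.

Mirrors the standard intravital-imaging workflow: 3-D positions are
analysed as 2-D projections (tracking in a thin, moving tissue volume makes
the axial coordinate unreliable), bulk XY tissue drift from peristalsis and
breathing is estimated and subtracted, and tracks with untracked holes are
split or filtered.

The drift estimator is registration-free: for each frame transition it
takes the componentwise **median** of the frame-to-frame displacement over
all cells present at both frames. With most cells immotile — the typical
villus situation — the median is the tissue motion itself, and it is robust
to a minority of genuinely motile cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .model import TIME_TOL, Track, TrackError, TrackSet

__all__ = [
    "DriftSeries",
    "SplitReport",
    "project_2d",
    "estimate_drift",
    "correct_drift",
    "apply_drift",
    "split_and_filter",
]


@dataclass
class DriftSeries:
    """Per-frame XY tissue displacement in µm.

    ``per_step[k]`` is the estimated displacement from frame ``k`` to
    ``k+1``; ``cumulative[k]`` is the total displacement of frame ``k``
    relative to frame 0 (so ``cumulative[0] == (0, 0)``).
    """

    frame_interval: float
    per_step: np.ndarray  # (n_frames - 1, 2)
    cumulative: np.ndarray  # (n_frames, 2)

    @property
    def n_frames(self) -> int:
        return len(self.cumulative)

    @classmethod
    def from_per_step(cls, per_step: np.ndarray, frame_interval: float) -> "DriftSeries":
        per_step = np.asarray(per_step, dtype=float).reshape(-1, 2)
        cumulative = np.vstack([np.zeros(2), np.cumsum(per_step, axis=0)])
        return cls(frame_interval=frame_interval, per_step=per_step, cumulative=cumulative)

    def write_csv(self, path: str | Path) -> Path:
        """Audit output: frame, per-step and cumulative drift components."""
        path = Path(path)
        rows = ["frame,dx_um,dy_um,cum_dx_um,cum_dy_um"]
        for k in range(self.n_frames):
            dx, dy = (self.per_step[k] if k < len(self.per_step) else (0.0, 0.0))
            rows.append(f"{k},{dx!r},{dy!r},{self.cumulative[k, 0]!r},{self.cumulative[k, 1]!r}")
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        return path


def project_2d(ts: TrackSet) -> TrackSet:
    """Drop the axial coordinate; x and y are unchanged.

    All downstream metrics then operate on in-plane positions only, which
    shortens displacements relative to the full 3-D path (measured speeds
    of motile cells are slightly underestimated, a conservative bias).
    """
    tracks = [replace(tr, z=None) for tr in ts.tracks]
    return ts.replace_tracks(tracks, projected=True)


def _frames(tr: Track) -> np.ndarray:
    return np.round(tr.t / tr.frame_interval).astype(int)


def estimate_drift(ts: TrackSet) -> DriftSeries:
    """Estimate per-step XY tissue drift on the cohort's frame grid.

    Frame transitions spanned by no track get zero drift.
    """
    if not ts.tracks:
        raise TrackError("empty", "cannot estimate drift from an empty track set")
    fi = ts.frame_interval
    n_frames = max(int(_frames(tr)[-1]) for tr in ts.tracks) + 1
    steps: list[list[np.ndarray]] = [[] for _ in range(n_frames - 1)]
    for tr in ts.tracks:
        frames = _frames(tr)
        pos = np.column_stack([tr.x, tr.y])
        contig = np.diff(frames) == 1  # only true consecutive-frame displacements
        for i in np.nonzero(contig)[0]:
            steps[frames[i]].append(pos[i + 1] - pos[i])
    per_step = np.zeros((n_frames - 1, 2))
    for k, disp in enumerate(steps):
        if disp:
            per_step[k] = np.median(np.asarray(disp), axis=0)
    return DriftSeries.from_per_step(per_step, fi)


def correct_drift(ts: TrackSet, drift: DriftSeries) -> TrackSet:
    """Subtract cumulative drift from every position.

    The drift series must cover the cohort's frame grid (same frame
    interval, at least as many frames); otherwise a
    ``frame_grid_mismatch`` error is raised.
    """
    return apply_drift(ts, drift, sign=-1.0)


def apply_drift(ts: TrackSet, drift: DriftSeries, sign: float = 1.0) -> TrackSet:
    """Add (``sign=+1``) or subtract (``sign=-1``) a drift series."""
    if abs(drift.frame_interval - ts.frame_interval) > TIME_TOL:
        raise TrackError("frame_grid_mismatch", "drift series frame interval differs from track set")
    tracks = []
    for tr in ts.tracks:
        frames = _frames(tr)
        if frames[-1] >= drift.n_frames:
            raise TrackError(
                "frame_grid_mismatch",
                f"track {tr.track_id!r} reaches frame {frames[-1]} but drift covers {drift.n_frames}",
            )
        offset = sign * drift.cumulative[frames]
        tracks.append(replace(tr, x=tr.x + offset[:, 0], y=tr.y + offset[:, 1]))
    return ts.replace_tracks(tracks)


@dataclass
class SplitReport:
    n_input: int = 0
    n_kept: int = 0  # tracks passed through intact
    n_split: int = 0  # tracks split at a gap (counted once per input track)
    n_segments: int = 0  # segments produced by splitting that survived filtering
    n_discarded: int = 0  # tracks or segments dropped for short duration


def split_and_filter(ts: TrackSet, min_duration: float = 10.0, max_gap: int = 1) -> tuple[TrackSet, SplitReport]:
    """Split tracks at untracked holes and drop short segments.

    A hole of at most ``max_gap`` missing frames is tolerated: the track
    stays whole and the gap-spanning step is simply excluded from speed
    statistics downstream (no interpolation — interpolated points would
    fabricate slow steps and inflate arrest coefficients). Longer holes
    split the track into independent segments (``source_id`` records the
    original id). Tracks or segments shorter than ``min_duration`` minutes
    are discarded.
    """
    report = SplitReport(n_input=len(ts.tracks))
    out: list[Track] = []
    for tr in ts.tracks:
        frames = _frames(tr)
        gaps = np.diff(frames) - 1  # missing frames between consecutive points
        cut = np.nonzero(gaps > max_gap)[0]
        if len(cut) == 0:
            if tr.duration >= min_duration:
                report.n_kept += 1
                out.append(tr)
            else:
                report.n_discarded += 1
            continue
        report.n_split += 1
        bounds = [0, *list(cut + 1), tr.n_points]
        for seg_i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            if b - a < 2 or tr.t[b - 1] - tr.t[a] < min_duration:
                report.n_discarded += 1
                continue
            seg = replace(
                tr,
                track_id=f"{tr.track_id}#{seg_i}",
                t=tr.t[a:b].copy(),
                x=tr.x[a:b].copy(),
                y=tr.y[a:b].copy(),
                z=tr.z[a:b].copy() if tr.z is not None else None,
                source_id=tr.track_id,
            )
            report.n_segments += 1
            out.append(seg)
    return ts.replace_tracks(out), report
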