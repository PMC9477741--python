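"""Per-track and cohort motility statistics.

The metrics are the standard descriptors of lymphocyte motility in
intravital imaging:

* **instantaneous speed** — Euclidean displacement between consecutive
  frames divided by the elapsed time (µm/min);
* **mean speed** — arithmetic mean of a track's instantaneous speeds;
* **arrest coefficient** — the percentage of a track's steps with
  instantaneous speed strictly below a threshold (default 3 µm/min);
  values near 100% mean the cell is parked;
* **straightness ratio** — net displacement divided by total path length,
  1 for a perfectly directional track and near 0 for a confined one;
* **MSD** — mean squared displacement as a function of time lag, computed
  with the overlapping-interval estimator: MSD(nΔt) averages
  |r(i+n) − r(i)|² over *all* start indices i, which is the DiPer
  convention for single-track MSD.

Steps that span a tolerated tracking gap are excluded from the speed-based
statistics (their displacement is not an instantaneous step) but remain in
the path length, where the straight-line distance across the gap is a
lower bound on the distance travelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .model import TIME_TOL, MotilityMetrics, MSDCurve, Track, TrackError, TrackSet

__all__ = [
    "SpeedSeries",
    "SpeedOverTime",
    "instantaneous_speeds",
    "arrest_coefficient",
    "straightness_ratio",
    "mean_speed",
    "msd",
    "cohort_msd",
    "speed_over_time",
    "track_metrics",
    "metrics_table",
    "cohort_summary",
]


@dataclass
class SpeedSeries:
    """Instantaneous speeds (µm/min) with mid-interval timestamps (min).

    Gap-spanning steps are already excluded; ``n_total_steps`` counts all
    consecutive-point steps including excluded ones.
    """

    times: np.ndarray
    speeds: np.ndarray
    n_total_steps: int


def _require_points(track: Track, n: int) -> None:
    if track.n_points < n:
        raise TrackError("too_short", f"track {track.track_id!r} has {track.n_points} points; need >= {n}")


def instantaneous_speeds(track: Track) -> SpeedSeries:
    """Per-step speeds, excluding steps that span a tolerated gap."""
    _require_points(track, 2)
    dt = np.diff(track.t)
    disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    ok = dt <= track.frame_interval * (1 + TIME_TOL)
    mid = (track.t[:-1] + track.t[1:]) / 2.0
    return SpeedSeries(times=mid[ok], speeds=disp[ok] / dt[ok], n_total_steps=len(dt))


def arrest_coefficient(track: Track, threshold: float = 3.0) -> float:
    """Percentage of steps with instantaneous speed strictly below ``threshold``.

    The inequality is strict: a step at exactly the threshold counts as
    motile. With uniform frame sampling the step fraction equals the time
    fraction, so this is the fraction of time the cell spends arrested.
    """
    ss = instantaneous_speeds(track)
    if len(ss.speeds) == 0:
        raise TrackError("too_short", f"track {track.track_id!r} has no usable steps")
    return 100.0 * float(np.count_nonzero(ss.speeds < threshold)) / len(ss.speeds)


def straightness_ratio(track: Track) -> float:
    """Net displacement over path length, in [0, 1]; NaN for a zero-length path."""
    _require_points(track, 2)
    pos = track.positions
    path = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    if path == 0.0:
        return float("nan")
    return float(np.linalg.norm(pos[-1] - pos[0])) / path


def mean_speed(track: Track) -> float:
    """Arithmetic mean of instantaneous speeds (µm/min)."""
    ss = instantaneous_speeds(track)
    if len(ss.speeds) == 0:
        raise TrackError("too_short", f"track {track.track_id!r} has no usable steps")
    return float(np.mean(ss.speeds))


def _contiguous_blocks(track: Track) -> list[np.ndarray]:
    """Positions split into runs of consecutive frames (gap steps removed)."""
    mult = np.round(np.diff(track.t) / track.frame_interval).astype(int)
    cuts = np.nonzero(mult > 1)[0]
    bounds = [0, *list(cuts + 1), track.n_points]
    pos = track.positions
    return [pos[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 2]


def msd(track: Track, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Overlapping-interval mean squared displacement of one track.

    MSD(nΔt) = mean over all i of |r(i+n) − r(i)|², for
    n = 1 … floor(``max_lag_fraction`` × (N − 1)). Long lags are estimated
    from few intervals and are noisy; ``n_intervals`` is recorded per lag
    so users can truncate further. Tracks with tolerated gaps contribute
    intervals from each contiguous block.
    """
    _require_points(track, 3)
    blocks = _contiguous_blocks(track)
    if not blocks:
        raise TrackError("too_short", f"track {track.track_id!r} has no contiguous block of >= 2 points")
    max_lag = int(np.floor(max_lag_fraction * (track.n_points - 1)))
    lags, values, counts = [], [], []
    for n in range(1, max_lag + 1):
        sq: list[np.ndarray] = []
        for pos in blocks:
            if len(pos) > n:
                diff = pos[n:] - pos[:-n]
                sq.append(np.sum(diff * diff, axis=1))
        if not sq:
            break
        allsq = np.concatenate(sq)
        lags.append(n * track.frame_interval)
        values.append(float(np.mean(allsq)))
        counts.append(len(allsq))
    if not lags:
        raise TrackError("too_short", f"track {track.track_id!r} too short for MSD at max_lag_fraction={max_lag_fraction}")
    return MSDCurve(lags=np.array(lags), values=np.array(values), n_intervals=np.array(counts), n_tracks=np.ones(len(lags), dtype=int))


def cohort_msd(ts: TrackSet, max_lag_fraction: float = 0.5, min_tracks: int = 1) -> MSDCurve:
    """Unweighted track-average MSD for a cohort.

    Each track contributes its own MSD curve with equal weight (matching
    per-cell averaging and avoiding long-track dominance); lags where fewer
    than ``min_tracks`` tracks contribute are truncated.
    """
    curves = []
    for tr in ts.tracks:
        try:
            curves.append(msd(tr, max_lag_fraction))
        except TrackError:
            continue
    if not curves:
        raise TrackError("empty", "no track in the cohort is eligible for MSD")
    fi = ts.frame_interval
    max_n = max(int(round(c.lags[-1] / fi)) for c in curves)
    values, counts, ntr, lags = [], [], [], []
    for n in range(1, max_n + 1):
        vals = [c.values[n - 1] for c in curves if len(c.lags) >= n]
        ints = [int(c.n_intervals[n - 1]) for c in curves if len(c.lags) >= n]
        if len(vals) < min_tracks:
            break
        lags.append(n * fi)
        values.append(float(np.mean(vals)))
        counts.append(int(np.sum(ints)))
        ntr.append(len(vals))
    if not lags:
        raise TrackError("empty", f"no MSD lag reaches min_tracks={min_tracks}")
    return MSDCurve(lags=np.array(lags), values=np.array(values), n_intervals=np.array(counts), n_tracks=np.array(ntr))


@dataclass
class SpeedOverTime:
    """Binned cohort speed relative to a treatment event.

    ``times`` are bin centres in minutes relative to the event; empty bins
    are omitted rather than zero-filled.
    """

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    bin_width: float


def speed_over_time(ts: TrackSet, event_time: float = 0.0, bin_width: float = 5.0) -> SpeedOverTime:
    """Pool all instantaneous speeds into time bins relative to ``event_time``."""
    times, speeds = [], []
    for tr in ts.tracks:
        try:
            ss = instantaneous_speeds(tr)
        except TrackError:
            continue
        times.append(ss.times - event_time)
        speeds.append(ss.speeds)
    if not times:
        raise TrackError("empty", "no speeds available in the requested window")
    t = np.concatenate(times)
    v = np.concatenate(speeds)
    idx = np.floor(t / bin_width).astype(int)
    centres, means, sems, ns = [], [], [], []
    for k in np.unique(idx):
        vals = v[idx == k]
        centres.append((k + 0.5) * bin_width)
        means.append(float(np.mean(vals)))
        sems.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"))
        ns.append(len(vals))
    return SpeedOverTime(np.array(centres), np.array(means), np.array(sems), np.array(ns, dtype=int), bin_width)


def track_metrics(track: Track, arrest_threshold: float = 3.0) -> MotilityMetrics:
    """All per-track metrics in one record."""
    pos = track.positions
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path = float(np.sum(steps))
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    ss = instantaneous_speeds(track)
    if len(ss.speeds) == 0:
        raise TrackError("too_short", f"track {track.track_id!r} has no usable steps")
    return MotilityMetrics(
        track_id=track.track_id,
        mean_speed=float(np.mean(ss.speeds)),
        arrest_coefficient=100.0 * float(np.count_nonzero(ss.speeds < arrest_threshold)) / len(ss.speeds),
        straightness=(net / path) if path > 0 else float("nan"),
        net_displacement=net,
        path_length=path,
        n_steps=len(ss.speeds),
        cell_class=track.cell_class,
        condition=track.condition,
    )


def metrics_table(ts: TrackSet, config: RunConfig | None = None) -> list[MotilityMetrics]:
    """One :class:`MotilityMetrics` record per track, in track-id order.

    Tracks on which metrics cannot be computed (too short, zero usable
    steps) yield a record with NaN metrics and the failure reason in
    ``error`` — they are flagged, never silently dropped.
    """
    config = config or RunConfig()
    records = []
    for tr in sorted(ts.tracks, key=lambda tr: tr.track_id):
        try:
            records.append(track_metrics(tr, config.metrics.arrest_threshold))
        except TrackError as exc:
            records.append(MotilityMetrics(track_id=tr.track_id, cell_class=tr.cell_class,
                                           condition=tr.condition, error=exc.code))
    return records


def _mean_sem(vals: np.ndarray) -> tuple[float, float]:
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan"), float("nan")
    sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return float(np.mean(vals)), sem


def cohort_summary(records: list[MotilityMetrics]) -> dict:
    """Per-condition mean ± s.e.m. of each metric, with n."""
    out: dict[str, dict] = {}
    conditions = sorted({r.condition for r in records})
    for cond in conditions:
        sub = [r for r in records if r.condition == cond and r.error is None]
        entry: dict = {"n_tracks": len(sub), "n_failed": len([r for r in records if r.condition == cond and r.error])}
        for name in ("mean_speed", "arrest_coefficient", "straightness", "net_displacement", "path_length"):
            vals = np.array([getattr(r, name) for r in sub], dtype=float)
            m, s = _mean_sem(vals)
            entry[name] = {"mean": m, "sem": s}
        out[cond] = entry
    return out
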