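"""The standard analysis pipeline: raw tracks in, motility report out.

Stage order mirrors the imaging workflow: 2-D projection → optional XY
drift correction → gap splitting and minimum-duration filtering → per-track
metrics → spot/wavy classification → cohort MSD. :func:`analyze` is the
single entry point used by the command-line interface, the test suite and
the acceptance script, so every consumer sees identical numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, metrics as mx, preprocess as pp
from .config import RunConfig
from .model import MotilityMetrics, MSDCurve, TrackError, TrackSet
from .preprocess import DriftSeries, SplitReport

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    tracks: TrackSet
    records: list[MotilityMetrics]
    summary: dict
    patterns: dict
    msd_by_condition: dict[str, MSDCurve]
    drift: DriftSeries | None
    filter_report: SplitReport
    config: RunConfig = field(default_factory=RunConfig)

    def metrics_rows(self) -> list[dict]:
        """Per-track metric rows (with pattern label) for CSV export."""
        rows = []
        for r in self.records:
            row = {
                "track_id": r.track_id, "condition": r.condition, "cell_class": r.cell_class,
                "mean_speed_um_min": r.mean_speed, "arrest_coefficient_pct": r.arrest_coefficient,
                "straightness": r.straightness, "net_displacement_um": r.net_displacement,
                "path_length_um": r.path_length, "n_steps": r.n_steps, "error": r.error or "",
            }
            if r.error is None and np.isfinite(r.net_displacement):
                row["pattern"] = classify.classify_pattern(r, self.config.classification).label
                row["arrested_cell"] = classify.is_arrested_cell(r, self.config.classification.cell_arrest_cutoff)
            else:
                row["pattern"] = ""
                row["arrested_cell"] = ""
            rows.append(row)
        return rows


def analyze(ts: TrackSet, config: RunConfig | None = None, drift_correction: bool | None = None) -> AnalysisResult:
    """Run the full motility pipeline on a track set."""
    config = config or RunConfig()
    if drift_correction is None:
        drift_correction = config.pipeline.drift_correction
    ts = pp.project_2d(ts)
    drift = None
    if drift_correction and ts.tracks:
        drift = pp.estimate_drift(ts)
        ts = pp.correct_drift(ts, drift)
    ts, report = pp.split_and_filter(ts, config.metrics.min_track_duration, config.pipeline.max_gap)
    records = mx.metrics_table(ts, config)
    summary = mx.cohort_summary(records)
    usable = [r for r in records if r.error is None and np.isfinite(r.net_displacement)]
    patterns = classify.pattern_distribution(usable, config.classification) if usable else {}
    msd_by_condition: dict[str, MSDCurve] = {}
    for cond in sorted({tr.condition for tr in ts.tracks}):
        sub = ts.replace_tracks([tr for tr in ts.tracks if tr.condition == cond], condition=cond)
        try:
            msd_by_condition[cond] = mx.cohort_msd(
                sub, config.metrics.msd_max_lag_fraction, config.metrics.msd_min_tracks)
        except TrackError:
            continue
    return AnalysisResult(tracks=ts, records=records, summary=summary, patterns=patterns,
                          msd_by_condition=msd_by_condition, drift=drift,
                          filter_report=report, config=config)
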