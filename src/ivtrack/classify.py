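"""Per-cell behavioural classification.

Two complementary readouts of stop-and-go lymphocyte behaviour:

* an *arrested cell* is one whose arrest coefficient over the whole track
  meets a cutoff (default 80%): the cell was parked for essentially the
  entire observation;
* the *spot / wavy* dichotomy separates restricted, in-place tracks
  ("spot": the cell jitters around one position) from extended meandering
  patrolling tracks ("wavy"). The quantitative surrogate used here calls a
  track a spot when its net displacement stays below ``d_min`` (default
  10 µm, about one cell diameter — jitter, not translocation) or when the
  cell is arrested by the cutoff above; everything else is wavy. Both
  thresholds are configuration-exposed and reported with every output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ClassificationConfig
from .model import MotilityMetrics, TrackError

__all__ = ["PatternLabel", "is_arrested_cell", "classify_pattern", "pattern_distribution"]

PATTERNS = ("spot", "wavy")


@dataclass(frozen=True)
class PatternLabel:
    label: str  # "spot" or "wavy"
    net_displacement: float
    straightness: float
    arrest_coefficient: float


def is_arrested_cell(m: MotilityMetrics, cell_arrest_cutoff: float = 80.0) -> bool:
    """True iff the track's arrest coefficient meets the per-cell cutoff (percent)."""
    return bool(m.arrest_coefficient >= cell_arrest_cutoff)


def classify_pattern(m: MotilityMetrics, thresholds: ClassificationConfig | None = None) -> PatternLabel:
    """Deterministic spot/wavy label from per-track metrics."""
    th = thresholds or ClassificationConfig()
    spot = (m.net_displacement < th.d_min) or is_arrested_cell(m, th.cell_arrest_cutoff)
    return PatternLabel(
        label="spot" if spot else "wavy",
        net_displacement=m.net_displacement,
        straightness=m.straightness,
        arrest_coefficient=m.arrest_coefficient,
    )


def pattern_distribution(records: list[MotilityMetrics], thresholds: ClassificationConfig | None = None) -> dict:
    """Per-condition spot/wavy fractions (summing to 1) with integer counts."""
    th = thresholds or ClassificationConfig()
    usable = [r for r in records if r.error is None and np.isfinite(r.net_displacement)]
    if not usable:
        raise TrackError("empty", "no classifiable tracks")
    out: dict[str, dict] = {}
    for cond in sorted({r.condition for r in usable}):
        sub = [r for r in usable if r.condition == cond]
        counts = {p: 0 for p in PATTERNS}
        for r in sub:
            counts[classify_pattern(r, th).label] += 1
        total = sum(counts.values())
        out[cond] = {
            "counts": counts,
            "fractions": {p: counts[p] / total for p in PATTERNS},
            "n": total,
            "thresholds": {"d_min": th.d_min, "cell_arrest_cutoff": th.cell_arrest_cutoff},
        }
    return out
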