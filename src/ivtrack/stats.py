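"""Cohort-level group comparisons on per-track metrics.

The statistical unit is the track/cell, matching how intravital imaging
cohorts are reported (each point in a figure is one cell). Two tests are
exposed: the two-tailed Mann–Whitney U test for pairwise comparisons and
one-way ANOVA for multi-group designs. P values are unadjusted by default
(pairwise tests are reported per panel); Holm correction is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .model import MotilityMetrics, TrackError

__all__ = ["MWResult", "AnovaResult", "mann_whitney_u", "one_way_anova", "compare_conditions"]

_METRIC_NAMES = ("mean_speed", "arrest_coefficient", "straightness", "net_displacement", "path_length")


@dataclass(frozen=True)
class MWResult:
    u: float
    p: float
    method: str  # "exact" or "asymptotic"
    n_a: int
    n_b: int


@dataclass(frozen=True)
class AnovaResult:
    f: float  # NaN when undefined (zero within-group variance, equal means)
    p: float
    df_between: int
    df_within: int


def mann_whitney_u(sample_a, sample_b) -> MWResult:
    """Two-tailed Mann–Whitney U test.

    Uses the exact null distribution (full enumeration) when the smaller
    sample has at most 8 observations and there are no ties across the
    pooled data; otherwise the normal approximation with tie and
    continuity corrections. The method actually used is reported.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise TrackError("empty", "both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return MWResult(u=float(res.statistic), p=float(res.pvalue), method=method, n_a=len(a), n_b=len(b))


def one_way_anova(*groups) -> AnovaResult:
    """One-way ANOVA across ``groups`` (each with n >= 2).

    When every group is constant with equal means the F statistic is
    undefined (0/0); this is reported as NaN F with p = NaN rather than
    raising.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise TrackError("too_few_groups", "ANOVA needs at least two groups")
    for g in arrs:
        if len(g) < 2:
            raise TrackError("too_small_group", "every ANOVA group needs n >= 2")
    n_total = sum(len(g) for g in arrs)
    df_between = len(arrs) - 1
    df_within = n_total - len(arrs)
    within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrs)
    grand = float(np.concatenate(arrs).mean())
    between = sum(len(g) * (float(g.mean()) - grand) ** 2 for g in arrs)
    if within == 0.0:
        if between == 0.0:
            return AnovaResult(f=float("nan"), p=float("nan"), df_between=df_between, df_within=df_within)
        return AnovaResult(f=float("inf"), p=0.0, df_between=df_between, df_within=df_within)
    res = sps.f_oneway(*arrs)
    return AnovaResult(f=float(res.statistic), p=float(res.pvalue), df_between=df_between, df_within=df_within)


def _holm(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[k] = running
    return adj


def compare_conditions(
    metrics_by_condition: dict[str, list[MotilityMetrics]],
    metric: str = "mean_speed",
    test: str = "mw",
    holm: bool = False,
) -> dict:
    """Compare one metric across conditions.

    Returns per-condition n / mean / s.e.m. (tracks with a missing metric
    are excluded, with the exclusion count reported), plus pairwise
    Mann–Whitney tests (``test="mw"``) or an omnibus one-way ANOVA
    (``test="anova"``). With a single condition only the summary is
    produced, with a warning in the report.
    """
    if metric not in _METRIC_NAMES:
        raise TrackError("unknown_metric", f"unknown metric {metric!r}; choose from {_METRIC_NAMES}")
    samples: dict[str, np.ndarray] = {}
    report: dict = {"metric": metric, "test": test, "conditions": {}, "warnings": []}
    for cond, records in metrics_by_condition.items():
        vals = np.array([getattr(r, metric) for r in records if r.error is None], dtype=float)
        finite = vals[np.isfinite(vals)]
        n_excluded = len(records) - len(finite)
        samples[cond] = finite
        sem = float(np.std(finite, ddof=1) / np.sqrt(len(finite))) if len(finite) > 1 else float("nan")
        report["conditions"][cond] = {
            "n": len(finite),
            "n_excluded": n_excluded,
            "mean": float(np.mean(finite)) if len(finite) else float("nan"),
            "sem": sem,
        }
    conds = sorted(samples)
    if len(conds) < 2:
        report["warnings"].append("single condition: summary only, no test performed")
        return report
    if test == "mw":
        pairwise = {}
        for a, b in combinations(conds, 2):
            r = mann_whitney_u(samples[a], samples[b])
            pairwise[f"{a} vs {b}"] = {"U": r.u, "p": r.p, "method": r.method}
        if holm:
            adj = _holm({k: v["p"] for k, v in pairwise.items()})
            for k in pairwise:
                pairwise[k]["p_holm"] = adj[k]
        report["pairwise"] = pairwise
    elif test == "anova":
        r = one_way_anova(*(samples[c] for c in conds))
        report["anova"] = {"F": r.f, "p": r.p, "df_between": r.df_between, "df_within": r.df_within}
    else:
        raise TrackError("unknown_test", f"unknown test {test!r}; choose 'mw' or 'anova'")
    return report
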