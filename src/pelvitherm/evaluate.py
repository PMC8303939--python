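"""Benchmarking MR thermometry against intraluminal probe traces.

Per session and probe location: accuracy (mean absolute MR-probe
difference), temporal precision (sample standard deviation of the ROI mean
across scan times) and bias (signed mean difference).  Sessions are labeled
acceptable when their location-averaged accuracy is at most 1 deg C.
Cohort-level aggregation produces per-location mean +/- sd for the full and
the selected dataset, threshold deviations, and improvement percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import PROBE_LOCATIONS, SCAN_DURATION_S, ProbeTrace
from .thermometry import RoiTemperatureSeries

__all__ = [
    "LocationMetrics",
    "SessionMetrics",
    "CohortSummary",
    "accuracy",
    "precision",
    "bias",
    "session_acceptability",
    "compare_locations",
    "evaluate_session",
    "summarize_cohort",
    "ACCURACY_THRESHOLD_C",
    "PRECISION_THRESHOLD_C",
    "BIAS_THRESHOLD_C",
]

ACCURACY_THRESHOLD_C = 1.0
PRECISION_THRESHOLD_C = 1.0
BIAS_THRESHOLD_C = 0.5  # acceptable |bias|


def _paired(mr, probe) -> tuple[np.ndarray, np.ndarray]:
    mr = np.asarray(mr, dtype=float)
    probe = np.asarray(probe, dtype=float)
    if mr.shape != probe.shape:
        raise ValueError("MR and probe series must have equal length")
    ok = ~(np.isnan(mr) | np.isnan(probe))  # missing pairs dropped pairwise
    return mr[ok], probe[ok]


def accuracy(mr, probe) -> float:
    """Mean absolute MR-probe difference; NaN when no pairs remain."""
    m, p = _paired(mr, probe)
    if len(m) == 0:
        return float("nan")
    return float(np.mean(np.abs(m - p)))


def precision(mr) -> float:
    """Sample (n-1) standard deviation of the ROI mean across time points."""
    m = np.asarray(mr, dtype=float)
    m = m[~np.isnan(m)]
    if len(m) < 2:
        return float("nan")
    return float(np.std(m, ddof=1))


def bias(mr, probe) -> float:
    """Signed mean MR-probe difference; negative means MR underestimates."""
    m, p = _paired(mr, probe)
    if len(m) == 0:
        return float("nan")
    return float(np.mean(m - p))


@dataclass
class LocationMetrics:
    accuracy_c: float
    precision_c: float
    bias_c: float
    n_timepoints: int
    surviving_voxel_fraction: float


@dataclass
class SessionMetrics:
    session_id: str
    per_location: dict[str, LocationMetrics]
    cutoff_c: float = ACCURACY_THRESHOLD_C

    @property
    def session_accuracy_c(self) -> float:
        vals = [m.accuracy_c for m in self.per_location.values()
                if not np.isnan(m.accuracy_c)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def acceptable(self) -> bool:
        return session_acceptability(self, self.cutoff_c)


def session_acceptability(metrics: SessionMetrics, cutoff_c: float = ACCURACY_THRESHOLD_C) -> bool:
    """True iff the location-averaged accuracy is at most the cutoff (inclusive)."""
    acc = metrics.session_accuracy_c
    if np.isnan(acc):
        raise ValueError("session accuracy undefined: all locations missing")
    return bool(acc <= cutoff_c)


def compare_locations(groups: dict[str, np.ndarray] | list[np.ndarray]):
    """Classical one-way ANOVA across locations: returns (F, p).

    Raises on degenerate input (fewer than two groups with two values, or
    zero within-group variance making F unbounded).
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs at least two groups with two values each")
    if all(np.allclose(a, a[0]) for a in arrays):
        means = [a.mean() for a in arrays]
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        raise ValueError("zero within-group variance: F statistic unbounded")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def evaluate_session(
    session_id: str,
    roi_series: RoiTemperatureSeries,
    probes: dict[str, ProbeTrace],
    scan_duration_s: float = SCAN_DURATION_S,
    cutoff_c: float = ACCURACY_THRESHOLD_C,
    max_offset_s: float = 150.0,
) -> SessionMetrics:
    """Accuracy/precision/bias for one session, per probe location."""
    per_location: dict[str, LocationMetrics] = {}
    for loc, trace in probes.items():
        mr = roi_series.mean_c[loc]
        probe = np.array([
            v if (v := trace.aligned_mean(float(t), scan_duration_s, max_offset_s))
            is not None else np.nan
            for t in roi_series.scan_times_s
        ])
        m, p = _paired(mr, probe)
        per_location[loc] = LocationMetrics(
            accuracy_c=accuracy(mr, probe),
            precision_c=precision(mr),
            bias_c=bias(mr, probe),
            n_timepoints=len(m),
            surviving_voxel_fraction=float(np.mean(roi_series.surviving_fraction(loc))),
        )
    return SessionMetrics(session_id=session_id, per_location=per_location, cutoff_c=cutoff_c)


@dataclass
class CohortSummary:
    """Per-location mean +/- sd of each metric for the full and selected sets."""

    per_location: dict  # dataset -> metric -> location -> (mean, sd)
    overall: dict  # dataset -> metric -> mean of the three location means
    deviations_c: dict  # dataset -> metric -> deviation from its threshold
    improvement_pct: dict  # metric -> percent improvement all -> selected
    n_sessions: dict
    session_pct: dict

    def as_dict(self) -> dict:
        return {
            "per_location": self.per_location,
            "overall": self.overall,
            "deviations_c": self.deviations_c,
            "improvement_pct": self.improvement_pct,
            "n_sessions": self.n_sessions,
            "session_pct": self.session_pct,
        }


_METRICS = ("accuracy", "precision", "bias")


def _metric_value(m: LocationMetrics, name: str) -> float:
    return {"accuracy": m.accuracy_c, "precision": m.precision_c, "bias": m.bias_c}[name]


def summarize_cohort(
    all_metrics: list[SessionMetrics], selected_ids: set[str] | list[str]
) -> CohortSummary:
    """Aggregate session metrics for the full cohort and a selected subset.

    Overall values are the means of the three per-location means; threshold
    deviations are overall accuracy - 1, overall precision - 1 and
    |overall bias| - 0.5; improvements are relative reductions of the
    overall values (absolute value for bias).
    """
    selected_ids = set(selected_ids)
    unknown = selected_ids - {m.session_id for m in all_metrics}
    if unknown:
        raise ValueError(f"selected ids not in cohort: {sorted(unknown)}")
    datasets = {
        "all": all_metrics,
        "selected": [m for m in all_metrics if m.session_id in selected_ids],
    }
    per_location: dict = {}
    overall: dict = {}
    deviations: dict = {}
    for name, sessions in datasets.items():
        per_location[name] = {}
        overall[name] = {}
        deviations[name] = {}
        for metric in _METRICS:
            per_location[name][metric] = {}
            loc_means = []
            for loc in PROBE_LOCATIONS:
                vals = np.array([
                    _metric_value(s.per_location[loc], metric)
                    for s in sessions if loc in s.per_location
                ])
                vals = vals[~np.isnan(vals)]
                mean = float(np.mean(vals)) if len(vals) else float("nan")
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
                per_location[name][metric][loc] = (mean, sd)
                loc_means.append(mean)
            ov = float(np.mean(loc_means))
            overall[name][metric] = ov
            if metric == "bias":
                deviations[name][metric] = abs(ov) - BIAS_THRESHOLD_C
            else:
                thr = ACCURACY_THRESHOLD_C if metric == "accuracy" else PRECISION_THRESHOLD_C
                deviations[name][metric] = ov - thr

    improvement: dict = {}
    for metric in _METRICS:
        a, s = overall["all"][metric], overall["selected"][metric]
        if metric == "bias":
            a, s = abs(a), abs(s)
        improvement[metric] = float("nan") if (not datasets["selected"] or a == 0) \
            else 100.0 * (a - s) / a

    n_all, n_sel = len(all_metrics), len(datasets["selected"])
    return CohortSummary(
        per_location=per_location,
        overall=overall,
        deviations_c=deviations,
        improvement_pct=improvement,
        n_sessions={"all": n_all, "selected": n_sel},
        session_pct={"all": 100.0, "selected": 100.0 * n_sel / n_all if n_all else float("nan")},
    )
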