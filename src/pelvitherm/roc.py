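"""ROC analysis of imaging features as predictors of acceptable thermometry.

The curve is built from thresholds at the midpoints between sorted distinct
scores plus +/-infinity, with an inclusive comparison on the positive side.
AUC is the trapezoidal area, which equals the Mann-Whitney concordance
probability with ties counted one half.  The operating cut-off is the
threshold whose (FPR, TPR) point lies nearest the top-left corner (0, 1).
Confidence intervals use a stratified bootstrap; the p-value against the
no-discrimination null (AUC = 0.5) uses a label permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "roc_curve",
    "auc",
    "optimal_cutoff",
    "auc_inference",
    "select_sessions",
    "FEATURE_ORIENTATIONS",
]

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"

#: Declared orientation of each session feature: the direction physical
#: reasoning predicts for *acceptable* thermometry (little air motion, small
#: air volume close-packed anatomy).
FEATURE_ORIENTATIONS = {
    "jaccard": HIGHER_IS_POSITIVE,
    "min_distance_cm": HIGHER_IS_POSITIVE,
    "air_volume_ml": LOWER_IS_POSITIVE,
    "fat_volume_ml": LOWER_IS_POSITIVE,
}


@dataclass
class RocResult:
    feature_name: str
    thresholds: np.ndarray  # feature units, aligned with (fpr, tpr)
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: str
    auc: float = float("nan")
    cutoff_opt: float = float("nan")
    ci95: tuple[float, float] | None = None
    p_value: float | None = None


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and congruent")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for ROC analysis")
    return s, y


def roc_curve(
    scores, labels, orientation: str = HIGHER_IS_POSITIVE, feature_name: str = ""
) -> RocResult:
    """ROC points over midpoint thresholds (plus +/-inf), AUC and cut-off."""
    s, y = _validate(scores, labels)
    sign = 1.0 if orientation == HIGHER_IS_POSITIVE else -1.0
    z = sign * s  # predict positive iff z >= internal threshold

    distinct = np.unique(z)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    internal = np.concatenate([[np.inf], mids[::-1], [-np.inf]])

    pos, neg = z[y], z[~y]
    tpr = np.array([(pos >= t).mean() for t in internal])
    fpr = np.array([(neg >= t).mean() for t in internal])

    result = RocResult(
        feature_name=feature_name,
        thresholds=sign * internal,
        fpr=fpr,
        tpr=tpr,
        orientation=orientation,
    )
    result.auc = auc(result)
    result.cutoff_opt = optimal_cutoff(result)
    return result


def auc(result: RocResult) -> float:
    """Trapezoidal area under the curve (points are FPR-sorted by build)."""
    order = np.argsort(result.fpr, kind="stable")
    return float(np.trapezoid(result.tpr[order], result.fpr[order]))


def optimal_cutoff(result: RocResult) -> float:
    """Threshold minimizing the distance to the top-left corner (0, 1).

    Only data thresholds (score midpoints) are eligible, never the +/-inf
    endpoints; ties prefer lower FPR (higher specificity), then higher TPR.
    NaN when every score is identical (no midpoint thresholds exist).
    """
    finite = np.isfinite(result.thresholds)
    if not finite.any():
        return float("nan")
    d2 = result.fpr[finite] ** 2 + (1.0 - result.tpr[finite]) ** 2
    order = np.lexsort(
        (-result.tpr[finite], result.fpr[finite], np.round(d2, 12))
    )
    return float(result.thresholds[finite][order[0]])


def _auc_fast(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney with average ranks = ties counted 1/2)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_inference(
    scores,
    labels,
    orientation: str = HIGHER_IS_POSITIVE,
    n_boot: int = 2000,
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[tuple[float, float], float]:
    """95% CI (stratified bootstrap percentiles) and permutation p-value.

    The p-value tests AUC = 0.5 two-sidedly via the permutation null of
    |AUC - 0.5| at least as large as observed.
    """
    s, y = _validate(scores, labels)
    if orientation == LOWER_IS_POSITIVE:
        s = -s
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x40C]))
    observed = _auc_fast(s, y)

    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ineg = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([ip, ineg])
        boot[b] = _auc_fast(s[idx], y[idx])
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    stat = abs(observed - 0.5)
    exceed = 0
    yp = y.copy()
    for _ in range(n_perm):
        rng.shuffle(yp)
        if abs(_auc_fast(s, yp) - 0.5) >= stat - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return ci, float(p)


def analyze_feature(
    scores, labels, orientation: str, feature_name: str = "",
    n_boot: int = 2000, n_perm: int = 2000, seed: int = 0,
) -> RocResult:
    """Full per-feature analysis: curve, AUC, cut-off, CI and p-value."""
    result = roc_curve(scores, labels, orientation, feature_name)
    result.ci95, result.p_value = auc_inference(
        scores, labels, orientation, n_boot=n_boot, n_perm=n_perm, seed=seed
    )
    return result


def select_sessions(
    features: dict[str, dict[str, float]] | list,
    cutoff: float = 0.91,
    feature: str = "jaccard",
    orientation: str | None = None,
) -> list[str]:
    """Session ids passing the feature cut-off (inclusive, orientation-aware).

    ``features`` maps session id -> feature dict, or is a list of objects
    with ``session_id`` and ``as_dict()``.
    """
    if orientation is None:
        orientation = FEATURE_ORIENTATIONS.get(feature, HIGHER_IS_POSITIVE)
    if not isinstance(features, dict):
        features = {f.session_id: f.as_dict() for f in features}
    out = []
    for sid, fd in features.items():
        if feature not in fd:
            raise KeyError(f"feature {feature!r} missing for session {sid!r}")
        v = float(fd[feature])
        keep = v >= cutoff if orientation == HIGHER_IS_POSITIVE else v <= cutoff
        if keep:
            out.append(sid)
    return out
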