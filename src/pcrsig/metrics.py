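"""Classifier and survival evaluation.

The two headline classification measures are the ROC AUC and the *sensitivity
at zero false-positive rate*: the largest fraction of true positives captured
by any score threshold that admits no negatives. The latter is the deployment
metric for a pathological-complete-response caller that must never label an
incomplete responder as a complete responder — a positive tied with the best
negative therefore does NOT count (strict-inequality threshold semantics).

Survival comparison (Kaplan-Meier product-limit curves, two-group log-rank
test from the hypergeometric O-E / variance formula) is implemented directly
because it is part of this package's evaluation contract; results agree with
standard survival libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "SurvivalComparison",
    "sensitivity_at_zero_fpr",
    "auc",
    "roc_curve",
    "precision_recall_curve",
    "evaluate_scores",
    "spearman_rho",
    "km_estimate",
    "logrank_test",
    "median_split",
]


def _as_binary(labels) -> np.ndarray:
    """Coerce labels to a boolean positive-mask; both classes must appear."""
    arr = np.asarray(labels)
    if arr.dtype == object or arr.dtype.kind in "US":
        mask = arr == "positive"
        valid = np.isin(arr, ("positive", "negative"))
        if not np.all(valid):
            raise ValueError(f"unexpected labels: {set(arr[~valid])}")
    else:
        mask = arr.astype(bool)
    if mask.all() or (~mask).all():
        raise ValueError("both classes must be present for evaluation")
    return mask


def sensitivity_at_zero_fpr(scores, labels) -> float:
    """Fraction of positives scoring strictly above every negative."""
    s = np.asarray(scores, dtype=float)
    pos = _as_binary(labels)
    max_neg = s[~pos].max()
    return float(np.count_nonzero(s[pos] > max_neg)) / int(pos.sum())


def auc(scores, labels) -> float:
    """ROC AUC via the Mann-Whitney pair count; ties count one half."""
    s = np.asarray(scores, dtype=float)
    pos = _as_binary(labels)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    ranks = stats.rankdata(s, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> list[tuple[float, float]]:
    """ROC points (fpr, tpr), one per distinct threshold, from (0,0) to (1,1)."""
    s = np.asarray(scores, dtype=float)
    pos = _as_binary(labels)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    pos_sorted = pos[order]
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(~pos_sorted)
    # keep only the last index of each run of equal scores (distinct thresholds)
    distinct = np.append(s_sorted[1:] != s_sorted[:-1], True)
    pts = [(0.0, 0.0)]
    for i in np.flatnonzero(distinct):
        pts.append((fp[i] / n_neg, tp[i] / n_pos))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def precision_recall_curve(scores, labels) -> list[tuple[float, float]]:
    """Precision-recall points (recall, precision), one per distinct threshold."""
    s = np.asarray(scores, dtype=float)
    pos = _as_binary(labels)
    n_pos = int(pos.sum())
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    pos_sorted = pos[order]
    tp = np.cumsum(pos_sorted)
    pred_pos = np.arange(1, len(s) + 1)
    distinct = np.append(s_sorted[1:] != s_sorted[:-1], True)
    pts = []
    for i in np.flatnonzero(distinct):
        pts.append((tp[i] / n_pos, tp[i] / pred_pos[i]))
    return pts


@dataclass
class EvalReport:
    """Bundle of the evaluation quantities for one score vector."""

    auc: float
    sens_at_zero_fpr: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sens_at_zero_fpr": self.sens_at_zero_fpr,
            "roc_points": [list(p) for p in self.roc_points],
            "pr_points": [list(p) for p in self.pr_points],
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def evaluate_scores(scores, labels) -> EvalReport:
    pos = _as_binary(labels)
    return EvalReport(
        auc=auc(scores, labels),
        sens_at_zero_fpr=sensitivity_at_zero_fpr(scores, labels),
        roc_points=roc_curve(scores, labels),
        pr_points=precision_recall_curve(scores, labels),
        n_positive=int(pos.sum()),
        n_negative=int((~pos).sum()),
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation and its t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalComparison:
    chi_square: float
    p_value: float
    km_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "km_curves": {
                g: {"time": t.tolist(), "survival": s.tolist()}
                for g, (t, s) in self.km_curves.items()
            },
        }


def km_estimate(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate.

    Returns (event_times, survival) where ``survival[i]`` is S(t) just after
    ``event_times[i]``; S starts at 1 before the first event.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    event_times = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for et in event_times:
        at_risk = np.count_nonzero(t >= et)
        d = np.count_nonzero((t == et) & (e == 1))
        s *= 1.0 - d / at_risk
        surv.append(s)
    return event_times, np.asarray(surv)


def logrank_test(groups, times, events) -> SurvivalComparison:
    """Two-group log-rank test.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; the statistic is
    ``(sum(O-E))^2 / sum(V)`` with one degree of freedom.
    """
    g = np.asarray(groups)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {list(levels)}")
    if e.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    in1 = g == levels[1]
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = np.count_nonzero(at_risk)
        n1 = np.count_nonzero(at_risk & in1)
        d = np.count_nonzero((t == et) & (e == 1))
        d1 = np.count_nonzero((t == et) & (e == 1) & in1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    curves = {
        str(lev): km_estimate(t[g == lev], e[g == lev]) for lev in levels
    }
    return SurvivalComparison(chi_square=float(chi2), p_value=p, km_curves=curves)


def median_split(scores) -> np.ndarray:
    """Split scores into 'high' (strictly above the median) and 'low' groups."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least two scores to split")
    med = np.median(s)
    groups = np.where(s > med, "high", "low")
    if (groups == "low").all():
        warnings.warn(
            "all scores at or below the median; the 'high' group is empty",
            UserWarning,
            stacklevel=2,
        )
    return groups
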