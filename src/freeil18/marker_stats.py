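"""ROC construction, Youden cutoff selection, and two-group baseline tests.

The study dichotomizes subjects by a biomarker cutoff chosen to maximize the
Youden index J = sensitivity + specificity - 1 on the ROC curve, then compares
groups with the chi-square test (categorical) and the Mann-Whitney U test
(quantitative).  Because the exposure here is *low* free IL-18, the ROC is
built with ``low_predicts_event`` orientation: a subject is test-positive iff
marker < threshold, strictly, matching the "<6.0 pmol/l" low-group definition.

These primitives are implemented from first principles with the exact
conventions stated in their docstrings (strict inequality, midrank ties,
tie-corrected normal approximation); scipy/scikit-learn equivalents serve as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ROCCurve",
    "CutoffResult",
    "Contingency2x2",
    "ConfusionResult",
    "roc_curve",
    "youden_cutoff",
    "confusion_at_cutoff",
    "chi_square_2x2",
    "mann_whitney_u",
    "YoudenCutoff",
]

_ORIENTATIONS = ("low_predicts_event", "high_predicts_event")


class DegenerateOutcomeError(ValueError):
    """Outcome vector has no events or no non-events."""


def _check_marker_outcome(marker, outcome):
    m = np.asarray(marker, dtype=float).ravel()
    y = np.asarray(outcome).ravel().astype(int)
    if m.shape != y.shape:
        raise ValueError("marker and outcome must have the same length")
    if not np.all(np.isfinite(m)):
        raise ValueError("marker values must be finite")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary {0, 1}")
    return m, y


@dataclass(frozen=True)
class ROCCurve:
    """Thresholds with their sensitivity/specificity, plus trapezoidal AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: str
    auc: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class Contingency2x2:
    """Events/non-events cross test-positive/negative; all cells >= 0."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.tp + self.fn + self.fp + self.tn == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ConfusionResult:
    table: Contingency2x2
    sensitivity: float | None  # None when there are no events
    specificity: float | None  # None when there are no non-events


def roc_curve(marker, outcome, orientation: str = "low_predicts_event") -> ROCCurve:
    """ROC over all distinct marker values plus a saturating sentinel.

    With ``low_predicts_event`` a subject is positive iff marker < threshold
    (strict); thresholds are the distinct observed values in ascending order
    plus +inf, so the curve runs from (sens, spec) = (0, 1) to (1, 0).  With
    ``high_predicts_event`` positivity is marker > threshold and the sentinel
    is -inf.  AUC is the trapezoid rule over (1 - specificity, sensitivity).
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    m, y = _check_marker_outcome(marker, outcome)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateOutcomeError(
            "ROC needs at least one event and one non-event"
        )

    order = np.argsort(m, kind="mergesort")
    ms, ys = m[order], y[order]
    uniq, idx = np.unique(ms, return_index=True)
    # events/non-events strictly below each distinct value
    cum_ev = np.concatenate([[0], np.cumsum(ys)])
    ev_below = cum_ev[idx]
    tot_below = idx
    if orientation == "low_predicts_event":
        thresholds = np.concatenate([uniq, [np.inf]])
        tp = np.concatenate([ev_below, [n1]]).astype(float)
        pos = np.concatenate([tot_below, [y.size]]).astype(float)
    else:
        # positive iff marker > threshold; descending thresholds
        thresholds = np.concatenate([uniq[::-1], [-np.inf]])
        ev_le = cum_ev[np.concatenate([idx[1:], [y.size]])]  # events <= value
        tot_le = np.concatenate([idx[1:], [y.size]]).astype(float)
        tp = np.concatenate([n1 - ev_le[::-1], [n1]]).astype(float)
        pos = np.concatenate([y.size - tot_le[::-1], [y.size]])
    fp = pos - tp
    sens = tp / n1
    spec = 1.0 - fp / n0
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return ROCCurve(thresholds, sens, spec, orientation, auc)


def youden_cutoff(curve: ROCCurve) -> CutoffResult:
    """Threshold maximizing J = sens + spec - 1.

    Ties on J are broken toward the highest sensitivity, then the smallest
    threshold (the published analyses report a single cutoff without a rule;
    this one is deterministic and favors not missing events).
    """
    if curve.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-15)
    best = best[curve.sensitivity[best] >= curve.sensitivity[best].max() - 1e-15]
    i = best[np.argmin(curve.thresholds[best])]
    return CutoffResult(
        cutoff=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(curve.specificity[i]),
        youden_j=float(j[i]),
    )


def confusion_at_cutoff(
    marker, outcome, cutoff: float, orientation: str = "low_predicts_event"
) -> ConfusionResult:
    """2x2 table and sensitivity/specificity at a fixed cutoff.

    Positivity is strict: marker < cutoff (``low_predicts_event``) or
    marker > cutoff.  Metrics are ``None`` (never silently 0) when their
    denominator is empty.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    m, y = _check_marker_outcome(marker, outcome)
    positive = m < cutoff if orientation == "low_predicts_event" else m > cutoff
    tp = int(np.sum(positive & (y == 1)))
    fn = int(np.sum(~positive & (y == 1)))
    fp = int(np.sum(positive & (y == 0)))
    tn = int(np.sum(~positive & (y == 0)))
    table = Contingency2x2(tp, fn, fp, tn)
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    return ConfusionResult(table, sens, spec)


def chi_square_2x2(table: Contingency2x2, yates: bool = False):
    """Pearson chi-square for a 2x2 table, df = 1.

    Statistic n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with the optional Yates
    continuity correction |ad - bc| -> max(0, |ad - bc| - n/2).  A zero margin
    leaves the statistic undefined and raises.
    """
    a, b, c, d = table.tp, table.fn, table.fp, table.tn
    n = table.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise ValueError("chi-square undefined: a margin of the table is zero")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(0.0, delta - n / 2.0)
    statistic = n * delta**2 / math.prod(margins)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def mann_whitney_u(x, y):
    """Two-sided Mann-Whitney U with midrank ties and continuity correction.

    U counts pairs with x_i > y_j (ties contribute 1/2), so x entirely below
    y gives U = 0.  The p-value uses the normal approximation with the
    tie-corrected variance; identical constant samples return p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * float(stats.norm.sf(z))
    return float(u), min(p, 1.0)


class YoudenCutoff(BaseEstimator, ClassifierMixin):
    """Single-marker threshold classifier fit by the Youden index.

    ``fit(X, y)`` builds the ROC of the single marker column in ``X`` against
    the binary outcome ``y`` and stores the Youden-optimal threshold;
    ``predict`` labels subjects test-positive (1) by the strict inequality of
    the chosen orientation.  A user-supplied ``fixed_cutoff`` skips selection
    (the published 6.0 pmol/l cutoff can be applied directly).

    Attributes (after fit): ``cutoff_``, ``sensitivity_``, ``specificity_``,
    ``youden_j_``, ``auc_``, ``roc_``.
    """

    def __init__(
        self,
        orientation: str = "low_predicts_event",
        fixed_cutoff: float | None = None,
    ):
        self.orientation = orientation
        self.fixed_cutoff = fixed_cutoff

    def fit(self, X, y):
        m = np.asarray(X, dtype=float)
        if m.ndim == 2:
            if m.shape[1] != 1:
                raise ValueError("YoudenCutoff expects a single marker column")
            m = m[:, 0]
        self.roc_ = roc_curve(m, y, self.orientation)
        self.auc_ = self.roc_.auc
        if self.fixed_cutoff is None:
            res = youden_cutoff(self.roc_)
        else:
            conf = confusion_at_cutoff(m, y, self.fixed_cutoff, self.orientation)
            res = CutoffResult(
                float(self.fixed_cutoff),
                conf.sensitivity,
                conf.specificity,
                conf.sensitivity + conf.specificity - 1.0,
            )
        self.cutoff_ = res.cutoff
        self.sensitivity_ = res.sensitivity
        self.specificity_ = res.specificity
        self.youden_j_ = res.youden_j
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "cutoff_")
        m = np.asarray(X, dtype=float)
        if m.ndim == 2:
            m = m[:, 0]
        if self.orientation == "low_predicts_event":
            return (m < self.cutoff_).astype(int)
        return (m > self.cutoff_).astype(int)
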