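"""ROC discrimination for ordinal risk scores.

Builds the ROC curve over the observed score values, computes the trapezoid
AUC with a DeLong 95% confidence interval, and picks the Youden-optimal
cutoff.  The positive class is the *adverse* outcome (residual stone,
complication, high blood loss) so a useful score has AUC >= 0.5.

Integer scores produce heavy ties; the trapezoid AUC over tie-grouped
thresholds is therefore cross-checked against the tie-corrected pairwise
concordance (Mann-Whitney) statistic, which must agree to 1e-12
(:func:`auc_equivalence_check`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as skm

__all__ = [
    "ROCResult",
    "roc_curve",
    "auc_ci",
    "youden_cutoff",
    "auc_equivalence_check",
    "concordance_auc",
]


@dataclass
class ROCResult:
    """ROC sweep plus summary statistics for one score/outcome pair.

    ``thresholds`` descend from an ``+inf`` sentinel through the observed
    score values; a case is called positive when ``score >= threshold``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    optimal_cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    positive_label: object
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    def coordinates(self):
        """(threshold, sensitivity, specificity) triples as a structured array."""
        return np.rec.fromarrays(
            [self.thresholds, self.sensitivity, self.specificity],
            names=["threshold", "sensitivity", "specificity"],
        )


def _validate(scores, labels, positive_label) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_label
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if y.all() or not y.any():
        raise ValueError("labels must contain at least one positive and one negative case")
    return scores, y


def concordance_auc(scores, labels, positive_label=True) -> float:
    """AUC via tie-corrected pairwise concordance: P(pos > neg) + P(tie)/2.

    Computed from the Mann-Whitney U statistic, the independent counterpart
    of the trapezoid-rule AUC.
    """
    scores, y = _validate(scores, labels, positive_label)
    pos, neg = scores[y], scores[~y]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (len(pos) * len(neg))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance from midrank placement values."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    tx = stats.rankdata(pos)  # midranks within positives
    ty = stats.rankdata(neg)
    tz = stats.rankdata(combined)  # midranks in the pooled sample
    v10 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_curve(scores, labels, positive_label=True) -> ROCResult:
    """Full ROC analysis of a score against a binary adverse outcome.

    Threshold sweep over the unique observed score values (descending, with
    a ``+inf`` sentinel), trapezoid AUC, DeLong 95% CI and the Youden-optimal
    cutoff (ties broken toward higher specificity).
    """
    scores, y = _validate(scores, labels, positive_label)
    fpr, tpr, thr = skm.roc_curve(y.astype(int), scores, drop_intermediate=False)
    auc = float(skm.auc(fpr, tpr))
    lo, hi = _delong_ci(scores, y, auc)
    sens, spec = tpr, 1.0 - fpr
    j = sens + spec - 1.0
    best = _youden_index(j, spec)
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        optimal_cutoff=float(thr[best]),
        cutoff_sensitivity=float(sens[best]),
        cutoff_specificity=float(spec[best]),
        positive_label=positive_label,
        scores=scores,
        labels=y,
    )


def _youden_index(j: np.ndarray, spec: np.ndarray) -> int:
    jmax = j.max()
    candidates = np.flatnonzero(np.isclose(j, jmax))
    return int(candidates[np.argmax(spec[candidates])])


def _delong_ci(scores: np.ndarray, y: np.ndarray, auc: float,
               alpha: float = 0.05) -> tuple[float, float]:
    _, var = _delong_variance(scores[y], scores[~y])
    if var <= 0:
        warnings.warn("degenerate DeLong variance (perfect separation); CI collapses to the AUC",
                      RuntimeWarning, stacklevel=2)
        return auc, auc
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def auc_ci(result: ROCResult, method: str = "delong", alpha: float = 0.05) -> tuple[float, float]:
    """95% (or 1-alpha) confidence interval for the AUC, clipped to [0, 1]."""
    if method != "delong":
        raise ValueError(f"unsupported CI method {method!r}")
    return _delong_ci(result.scores, result.labels, result.auc, alpha)


def youden_cutoff(result: ROCResult) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximising Youden's J = sens + spec - 1.

    Ties in J are broken toward the higher-specificity (more conservative)
    threshold.  The returned threshold is an observed score value or the
    ``+inf`` sentinel.
    """
    j = result.sensitivity + result.specificity - 1.0
    best = _youden_index(j, result.specificity)
    return (
        float(result.thresholds[best]),
        float(result.sensitivity[best]),
        float(result.specificity[best]),
    )


def auc_equivalence_check(scores, labels, positive_label=True, tol: float = 1e-12) -> bool:
    """Dual-route AUC check: trapezoid rule vs pairwise-concordance statistic.

    The two formulas are algebraically identical under midrank tie handling;
    a discrepancy beyond ``tol`` indicates an implementation defect.
    """
    scores, y = _validate(scores, labels, positive_label)
    fpr, tpr, _ = skm.roc_curve(y.astype(int), scores, drop_intermediate=False)
    trapezoid = float(skm.auc(fpr, tpr))
    return abs(trapezoid - concordance_auc(scores, y, True)) <= tol
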