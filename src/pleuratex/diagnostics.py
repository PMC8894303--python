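"""Diagnostic-accuracy statistics for single texture features.

The empirical ROC curve is built over all distinct score thresholds and
integrated with the trapezoidal rule (ties contribute half, making the AUC
identical to the normalized Mann–Whitney U statistic).  The operating
cut-off maximizes Youden's J = sensitivity + specificity − 1; ties on J are
broken in favour of higher sensitivity, then the lower cut-off, and the
cut-off is reported as the midpoint between adjacent distinct scores so the
rule is deterministic.  The score direction is chosen so that AUC ≥ 0.5
("higher-positive" when larger scores indicate the positive class).

AUCs of two features measured on the same subjects are compared with a
stratified bootstrap (2000 replicates of raw-data resampling by default):
subjects are resampled with replacement within each class, ΔAUC is
recomputed per replicate, and a two-sided p-value is taken from the normal
approximation of the bootstrap ΔAUC distribution.

Classification error is estimated by stratified fourfold cross-validation
of the single-feature Youden rule: the cut-off and direction are fit on the
training folds and applied to the held-out subjects, and errors are pooled.

Inter-observer agreement uses the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1) from the
standard ANOVA mean-squares decomposition, with the F-based confidence
interval, plus Cronbach's alpha as an internal-consistency measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .errors import ValidationError

__all__ = [
    "RocResult",
    "AgreementResult",
    "YoudenCutoffClassifier",
    "roc_curve",
    "compare_auc_bootstrap",
    "cv_error",
    "icc_agreement",
]


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary for one feature."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # "higher-positive" | "lower-positive"

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "direction": self.direction,
        }


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    ci_low: float
    ci_high: float
    cronbach_alpha: float


def _validate_binary(scores, labels, positive):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    if np.any(np.isnan(scores)):
        raise ValidationError("missing scores are not allowed")
    y = labels == positive
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    return scores, y


def _empirical_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal AUC of the empirical ROC, higher scores = positive."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    pos = y[order].astype(float)
    neg = 1.0 - pos
    # collapse tied scores into single ROC vertices
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tpr = np.r_[0.0, np.cumsum(pos)[distinct] / pos.sum()]
    fpr = np.r_[0.0, np.cumsum(neg)[distinct] / neg.sum()]
    return float(np.trapezoid(tpr, fpr))


def _youden_cutoff(scores, y, higher_positive: bool):
    """Best midpoint cut-off by Youden's J (ties: higher sensitivity, lower cut)."""
    u = np.unique(scores)
    if u.size < 2:
        raise ValidationError("all scores identical; no cut-off exists")
    mid = (u[:-1] + u[1:]) / 2.0
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    # counts of scores <= each midpoint, per class
    pos_sorted = np.sort(scores[y])
    neg_sorted = np.sort(scores[~y])
    pos_le = np.searchsorted(pos_sorted, mid, side="right")
    neg_le = np.searchsorted(neg_sorted, mid, side="right")
    if higher_positive:
        sens = (n_pos - pos_le) / n_pos  # score > cutoff -> positive
        spec = neg_le / n_neg
    else:
        sens = pos_le / n_pos  # score < cutoff -> positive
        spec = (n_neg - neg_le) / n_neg
    j = sens + spec - 1.0
    # lexicographic argmax: J desc, sensitivity desc, cutoff asc
    best = max(range(mid.size), key=lambda k: (j[k], sens[k], -mid[k]))
    return float(mid[best]), float(sens[best]), float(spec[best])


def roc_curve(
    scores: Sequence[float],
    labels: Sequence,
    positive,
    ci: str = "bootstrap",
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> RocResult:
    """Empirical ROC with Youden cut-off for one feature.

    Parameters
    ----------
    scores, labels
        Paired feature values and class labels.
    positive
        The label value treated as the positive (diseased) class.
    ci
        ``"bootstrap"`` (percentile, stratified, default), ``"delong"``
        (asymptotic normal from the DeLong variance), or ``"none"``.
    """
    scores, y = _validate_binary(scores, labels, positive)
    auc_high = _empirical_auc(scores, y)
    if auc_high >= 0.5:
        direction, auc = "higher-positive", auc_high
    else:
        direction, auc = "lower-positive", _empirical_auc(-scores, y)
    cutoff, sens, spec = _youden_cutoff(scores, y, direction == "higher-positive")

    if ci == "none":
        lo = hi = auc
    elif ci == "delong":
        lo, hi = _delong_ci(scores if direction == "higher-positive" else -scores,
                            y, auc, alpha)
    elif ci == "bootstrap":
        lo, hi = _bootstrap_ci(scores, y, direction, n_boot, seed, alpha)
    else:
        raise ValidationError(f"unknown ci method {ci!r}")
    lo, hi = min(lo, auc), max(hi, auc)
    return RocResult(
        auc=auc,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        direction=direction,
    )


def _stratified_resample(rng, idx_pos, idx_neg):
    return np.r_[
        rng.choice(idx_pos, size=idx_pos.size, replace=True),
        rng.choice(idx_neg, size=idx_neg.size, replace=True),
    ]


def _bootstrap_ci(scores, y, direction, n_boot, seed, alpha):
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y)
    idx_neg = np.flatnonzero(~y)
    eff = scores if direction == "higher-positive" else -scores
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = _stratified_resample(rng, idx_pos, idx_neg)
        aucs[b] = _empirical_auc(eff[idx], y[idx])
    return (
        float(np.quantile(aucs, alpha / 2)),
        float(np.quantile(aucs, 1 - alpha / 2)),
    )


def _delong_ci(scores, y, auc, alpha):
    """Normal CI from the DeLong placement-value variance."""
    pos = np.sort(scores[y])
    neg = np.sort(scores[~y])
    m, n = pos.size, neg.size
    # placement of each positive among negatives: P(neg < s) + 0.5 P(neg = s)
    v10 = (np.searchsorted(neg, pos, side="left")
           + 0.5 * (np.searchsorted(neg, pos, side="right")
                    - np.searchsorted(neg, pos, side="left"))) / n
    v01 = (m - np.searchsorted(pos, neg, side="right")
           + 0.5 * (np.searchsorted(pos, neg, side="right")
                    - np.searchsorted(pos, neg, side="left"))) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc - half), float(auc + half)


def compare_auc_bootstrap(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    positive,
    n_boot: int = 2000,
    seed: int | None = None,
) -> float:
    """Two-sided bootstrap p-value for ΔAUC of two paired features.

    Subjects are resampled with replacement within each class; the AUC of
    each feature (in its full-sample direction) is recomputed per
    replicate; the p-value comes from the normal approximation of the
    bootstrap ΔAUC distribution.  Identical score vectors give p = 1.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable bootstrap p-value")
    a, y = _validate_binary(scores_a, labels, positive)
    b, _ = _validate_binary(scores_b, labels, positive)
    sign_a = 1.0 if _empirical_auc(a, y) >= 0.5 else -1.0
    sign_b = 1.0 if _empirical_auc(b, y) >= 0.5 else -1.0
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y)
    idx_neg = np.flatnonzero(~y)
    deltas = np.empty(n_boot)
    for k in range(n_boot):
        idx = _stratified_resample(rng, idx_pos, idx_neg)
        deltas[k] = _empirical_auc(sign_a * a[idx], y[idx]) - _empirical_auc(
            sign_b * b[idx], y[idx]
        )
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        return 1.0
    z = float(np.mean(deltas)) / sd
    return float(2.0 * stats.norm.sf(abs(z)))


class YoudenCutoffClassifier(BaseEstimator, ClassifierMixin):
    """Single-feature threshold classifier fit by Youden's J.

    ``fit`` chooses the score direction (so that training AUC ≥ 0.5) and
    the midpoint cut-off maximizing J on the training data; ``predict``
    applies the resulting rule.  This is the classifier whose fourfold
    cross-validated error rate accompanies each per-feature AUC.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``pos_label`` defaults to ``classes_[1]``.
    cutoff_ : float
        Fitted midpoint threshold, in score units.
    direction_ : str
        ``"higher-positive"`` or ``"lower-positive"``.
    auc_ : float
        Training AUC of the fitted direction.
    """

    def __init__(self, pos_label=None):
        self.pos_label = pos_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValidationError("expects a single score column")
            X = X[:, 0]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValidationError("requires exactly two classes")
        pos = self.pos_label if self.pos_label is not None else self.classes_[1]
        res = roc_curve(X, y, positive=pos, ci="none")
        self.positive_ = pos
        self.negative_ = self.classes_[self.classes_ != pos][0]
        self.cutoff_ = res.cutoff
        self.direction_ = res.direction
        self.auc_ = res.auc
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        if self.direction_ == "higher-positive":
            is_pos = X > self.cutoff_
        else:
            is_pos = X < self.cutoff_
        return np.where(is_pos, self.positive_, self.negative_)


def cv_error(
    scores: Sequence[float],
    labels: Sequence,
    positive=None,
    k: int = 4,
    seed: int | None = None,
) -> float:
    """Cross-validated misclassification rate of the Youden rule.

    Stratified k-fold (default fourfold): per fold the cut-off and
    direction are fit on the training subjects and applied to the held-out
    subjects; errors are pooled over folds.  If the minority class has
    fewer members than ``k``, the split degrades to leave-one-out with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValidationError("requires exactly two classes")
    if counts.min() < k:
        warnings.warn(
            f"minority class has {counts.min()} < k={k} members; "
            "falling back to leave-one-out"
        )
        splitter = LeaveOneOut()
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    clf = YoudenCutoffClassifier(pos_label=positive)
    errors = 0
    for train, test in splitter.split(scores.reshape(-1, 1), labels):
        clf.fit(scores[train], labels[train])
        errors += int(np.sum(clf.predict(scores[test]) != labels[test]))
    return errors / scores.size


def icc_agreement(ratings, alpha: float = 0.05) -> AgreementResult:
    """Two-way absolute-agreement single-measure ICC(2,1) and Cronbach's α.

    Parameters
    ----------
    ratings : array-like of shape (n_subjects, n_raters)
        Complete matrix, every rater scoring every subject.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("ratings must be (>=2 subjects) x (>=2 raters)")
    if np.any(np.isnan(x)):
        raise ValidationError("ratings matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_subjects = k * float(((row_means - grand) ** 2).sum())
    ss_raters = n * float(((col_means - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_raters
    msr = ss_subjects / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-300 or denom <= 0:
        warnings.warn("zero between-subject variance; ICC set to 0")
        icc = 0.0
    else:
        icc = min(1.0, (msr - mse) / denom)

    # Cronbach's alpha from rater variances vs variance of subject sums
    var_raters = x.var(axis=0, ddof=1).sum()
    var_sums = x.sum(axis=1).var(ddof=1)
    if var_sums <= 0:
        cronbach = float("nan")
    else:
        cronbach = min(1.0, k / (k - 1) * (1.0 - var_raters / var_sums))

    lo, hi = _icc_ci(icc, msr, msc, mse, n, k, alpha)
    return AgreementResult(
        icc=float(icc), ci_low=lo, ci_high=hi, cronbach_alpha=float(cronbach)
    )


def _icc_ci(icc, msr, msc, mse, n, k, alpha):
    """F-distribution CI for ICC(2,1) (two-way random, absolute agreement)."""
    if mse <= 0 or icc >= 1.0 - 1e-12:
        return float(icc), float(icc)
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(min(lower, icc)), float(max(upper, icc))
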