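"""Segmentation scoring, uncertainty-based error/QC prediction, statistics.

Three evaluation layers:

* overlap — per-class Dice ``2TP / (2TP + FN + FP)`` and its unweighted mean
  across all classes (background included);
* voxel level — ROC/AUC of per-voxel entropy as a predictor of
  misclassification (errors are the positive class);
* volume level — ROC/AUC of mean non-background entropy as a predictor of
  bad manual quality-control ratings, with a paired bootstrap harness for
  comparing score sets and a paired t-test for per-volume metrics.

Degenerate cases (a single class present, zero-variance differences) raise
explicit signals rather than returning silently meaningless numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .volumes import ValidationError

__all__ = [
    "EvalReport",
    "QCRecord",
    "UndefinedAUCError",
    "DegenerateTestError",
    "dice",
    "mean_dice",
    "per_class_dice",
    "error_mask",
    "error_roc",
    "average_roc",
    "qc_binarize",
    "qc_roc",
    "bootstrap_auc_compare",
    "paired_ttest",
    "evaluate_volume",
]


class UndefinedAUCError(ValidationError):
    """ROC analysis is undefined: only one class present."""


class DegenerateTestError(ValidationError):
    """The test statistic is undefined (e.g. zero-variance differences)."""


# ---------------------------------------------------------------------------
# Dice

def dice(prediction, target, class_id: int) -> float:
    """Dice overlap of one class's binary masks.

    Defined-empty convention: a class absent from both volumes scores 1
    (perfect agreement on absence); absent from exactly one scores 0.
    """
    pred = np.asarray(prediction)
    targ = np.asarray(target)
    if pred.shape != targ.shape:
        raise ValidationError(
            f"shape mismatch: prediction {pred.shape} vs target {targ.shape}"
        )
    p = pred == class_id
    t = targ == class_id
    p_sum = int(p.sum())
    t_sum = int(t.sum())
    if p_sum == 0 and t_sum == 0:
        return 1.0
    if p_sum == 0 or t_sum == 0:
        return 0.0
    tp = int(np.logical_and(p, t).sum())
    return 2.0 * tp / (p_sum + t_sum)


def per_class_dice(prediction, target, n_classes: int) -> np.ndarray:
    return np.array([dice(prediction, target, c) for c in range(n_classes)])


def mean_dice(prediction, target, n_classes: int) -> float:
    """Unweighted mean of per-class Dice over all ``n_classes`` classes
    (background class 0 included)."""
    return float(per_class_dice(prediction, target, n_classes).mean())


# ---------------------------------------------------------------------------
# voxelwise error prediction

def error_mask(predicted_labels, target_labels) -> np.ndarray:
    """Voxels evaluated in the error-ROC: any voxel where prediction or
    target is non-background (the mutual-background sea is excluded)."""
    pred = np.asarray(predicted_labels)
    targ = np.asarray(target_labels)
    return (pred != 0) | (targ != 0)


def error_roc(entropy, correct, mask=None):
    """ROC of per-voxel entropy as a misclassification predictor.

    Misclassified voxels are the positive class and entropy the ranking
    score; ties are handled by midranks (the standard rank-statistic AUC).
    Returns ``(fpr, tpr, auc)``.
    """
    scores = np.asarray(entropy, dtype=float).ravel()
    correct = np.asarray(correct, dtype=bool).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        scores, correct = scores[m], correct[m]
    positives = ~correct
    if positives.all() or (~positives).all():
        raise UndefinedAUCError(
            "error ROC undefined: need at least one correct and one "
            "misclassified voxel in the evaluation mask"
        )
    fpr, tpr, _ = roc_curve(positives, scores)
    auc = float(roc_auc_score(positives, scores))
    return fpr, tpr, auc


def average_roc(curves, grid_size: int = 101):
    """Average per-volume ROC curves on a common false-positive-rate grid.

    ``curves`` is a sequence of ``(fpr, tpr)`` pairs.  Each curve is
    linearly interpolated onto the grid and averaged; per-volume AUCs
    (trapezoid on the original curves) are kept for paired tests.  Returns
    ``(fpr_grid, mean_tpr, per_volume_aucs)``.
    """
    curves = list(curves)
    if not curves:
        raise ValidationError("average_roc needs at least one curve")
    fpr_grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    aucs = []
    for fpr, tpr in curves:
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1 or fpr.size < 2:
            raise ValidationError("each curve must be matched 1D fpr/tpr arrays")
        tprs.append(np.interp(fpr_grid, fpr, tpr))
        aucs.append(float(np.trapezoid(tpr, fpr)))
    return fpr_grid, np.mean(tprs, axis=0), np.asarray(aucs)


# ---------------------------------------------------------------------------
# scan-quality prediction

@dataclass(frozen=True)
class QCRecord:
    """Manual quality-control ratings for one volume.

    Scores run 1 (best) to 4 (worst), from two raters, with a third rater
    consulted when the first two differ by more than 1.  The consolidated
    score is the mean of available ratings; a volume is labelled bad quality
    iff that score is strictly greater than 2.
    """

    volume_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.scores) < 2:
            raise ValidationError("QCRecord needs at least two rater scores")
        for s in self.scores:
            if not (1.0 <= s <= 4.0):
                raise ValidationError(f"rater score {s} outside [1, 4]")

    @property
    def consolidated(self) -> float:
        return float(np.mean(self.scores))


def qc_binarize(record: QCRecord) -> bool:
    """True (bad quality) iff the consolidated score exceeds 2 (strict)."""
    return record.consolidated > 2.0


def qc_roc(volume_uncertainties, labels):
    """ROC of per-volume uncertainty as a bad-quality-scan predictor.

    ``labels`` are booleans (True = bad quality, the positive class).
    Returns ``(fpr, tpr, auc)``.
    """
    scores = np.asarray(volume_uncertainties, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be matched 1D arrays")
    if y.all() or (~y).all():
        raise UndefinedAUCError("QC ROC undefined: both classes required")
    fpr, tpr, _ = roc_curve(y, scores)
    return fpr, tpr, float(roc_auc_score(y, scores))


@dataclass
class BootstrapComparison:
    auc_a: float
    auc_b: float
    boot_auc_a: np.ndarray
    boot_auc_b: np.ndarray
    p_value: float
    n_boot: int
    direction: str


def bootstrap_auc_compare(scores_a, scores_b, labels, n_boot: int = 10000,
                          sample_size: int | None = None, seed: int = 0,
                          max_redraw_factor: int = 100) -> BootstrapComparison:
    """Paired bootstrap comparison of two scoring methods' QC AUCs.

    Volumes are resampled with replacement (the same index draw applied to
    both score vectors); each replicate yields an AUC pair.  The p-value is
    one-sided in the direction asserted by the point estimate (the method
    with the higher full-sample AUC): the fraction of replicates in which it
    fails to beat the other, with ties counted as 1/2 — so identical score
    vectors give p = 0.5 exactly.  Degenerate replicates (one class only)
    are redrawn, with a hard cap of ``max_redraw_factor * n_boot`` redraws.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape) or a.ndim != 1:
        raise ValidationError("score vectors and labels must be aligned 1D arrays")
    if y.all() or (~y).all():
        raise UndefinedAUCError("both classes required for AUC comparison")
    n = a.size
    sample_size = sample_size or n
    auc_a = float(roc_auc_score(y, a))
    auc_b = float(roc_auc_score(y, b))
    rng = np.random.default_rng(seed)
    boot_a = np.empty(n_boot)
    boot_b = np.empty(n_boot)
    redraws = 0
    cap = max_redraw_factor * n_boot
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=sample_size)
        yi = y[idx]
        if yi.all() or (~yi).all():
            redraws += 1
            if redraws > cap:
                raise DegenerateTestError(
                    "bootstrap redraw cap exceeded: labels too imbalanced"
                )
            continue
        boot_a[i] = roc_auc_score(yi, a[idx])
        boot_b[i] = roc_auc_score(yi, b[idx])
        i += 1
    if auc_a >= auc_b:
        hi, lo, direction = boot_a, boot_b, "a>=b"
    else:
        hi, lo, direction = boot_b, boot_a, "b>a"
    p = float(np.mean(hi < lo) + 0.5 * np.mean(hi == lo))
    return BootstrapComparison(auc_a, auc_b, boot_a, boot_b, p, n_boot, direction)


def paired_ttest(metric_a, metric_b):
    """Classical two-sided paired t-test on per-volume metric differences.

    Returns ``(t_statistic, p_value)``; zero-variance differences (e.g.
    identical inputs) raise :class:`DegenerateTestError`.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two aligned 1D arrays of length >= 2")
    if np.var(a - b) == 0:
        raise DegenerateTestError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# per-volume report

@dataclass
class EvalReport:
    """Per-volume evaluation summary."""

    per_class_dice: np.ndarray
    mean_dice: float
    error_auc: float | None = None
    volume_uncertainty: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = dict(self.metadata)
        row["mean_dice"] = self.mean_dice
        if self.error_auc is not None:
            row["error_auc"] = self.error_auc
        if self.volume_uncertainty is not None:
            row["volume_uncertainty"] = self.volume_uncertainty
        for c, d in enumerate(self.per_class_dice):
            row[f"dice_class_{c}"] = float(d)
        return row

    @staticmethod
    def to_frame(reports) -> pd.DataFrame:
        return pd.DataFrame.from_records([r.to_row() for r in reports])


def evaluate_volume(output, target, metadata=None) -> EvalReport:
    """Full per-volume report from a predictive output and reference labels.

    Computes per-class/mean Dice, the entropy->error AUC over the
    non-mutual-background mask (None when degenerate), and the volume-level
    uncertainty (None when the prediction is all background).
    """
    from .inference import AllBackgroundError, volume_uncertainty

    targ = np.asarray(target.data if hasattr(target, "data") else target)
    n_classes = output.n_classes
    pcd = per_class_dice(output.predicted_labels, targ, n_classes)
    report = EvalReport(pcd, float(pcd.mean()), metadata=dict(metadata or {}))
    correct = output.predicted_labels == targ
    mask = error_mask(output.predicted_labels, targ)
    try:
        _, _, auc = error_roc(output.entropy, correct, mask)
        report.error_auc = auc
    except UndefinedAUCError:
        report.error_auc = None
    try:
        report.volume_uncertainty = volume_uncertainty(output)
    except AllBackgroundError:
        report.volume_uncertainty = None
    return report
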