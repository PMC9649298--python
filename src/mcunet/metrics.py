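"""FOV-masked pixel-classification metrics for vessel segmentation.

Every pixel inside the field-of-view mask is classified vessel
(positive) or background (negative); from the confusion counts

    ACC = (TP + TN) / (TN + FP + TP + FN)
    SE  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    F1  = 2 TP / (2 TP + FP + FN)

and the ROC/AUC comes from a threshold sweep over the probability map,
restricted to FOV pixels.  Degenerate denominators (e.g. an image with
no vessel pixels) yield 0.0 with a warning rather than an exception.

Aggregation across images is pooled by default: confusion counts are
summed over all FOV pixels of all images before the ratios are taken.
Per-image averaging is available via ``aggregate(..., mode="per_image")``.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "confusion_counts",
    "accuracy",
    "sensitivity",
    "specificity",
    "f1_score",
    "roc_auc",
    "aggregate",
    "report_csv",
    "report_text",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self):
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ROCCurve:
    """Operating points (FPR, TPR), from (0, 0) to (1, 1), both
    coordinates non-decreasing along the threshold sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _as_binary(arr, name):
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")
    return a.astype(bool)


def confusion_counts(pred, truth, fov=None) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over FOV pixels; vessel = positive.

    ``fov=None`` evaluates every pixel.
    """
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if fov is None:
        fov = np.ones_like(truth, dtype=bool)
    else:
        fov = _as_binary(fov, "fov")
        if fov.shape != truth.shape:
            raise ValueError(f"shape mismatch: fov {fov.shape} vs truth {truth.shape}")
    p, t = pred[fov], truth[fov]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num, den, what):
    if den == 0:
        warnings.warn(f"degenerate image: zero denominator in {what}; returning 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def f1_score(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1_score")


def roc_auc(scores, truth, fov=None):
    """ROC curve and AUC over FOV pixels by threshold sweep.

    The trapezoid AUC equals the pairwise ranking probability
    P(score_pos > score_neg) + 0.5 P(tie); the test suite checks this
    identity against exhaustive pair counting.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = _as_binary(truth, "truth")
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must share a shape")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if fov is None:
        fov = np.ones_like(truth, dtype=bool)
    else:
        fov = _as_binary(fov, "fov")
    s, t = scores[fov].ravel(), truth[fov].ravel()
    if t.all() or not t.any():
        raise ValueError("AUC undefined: ground truth has a single class in FOV")
    fpr, tpr, thr = _sk_roc_curve(t.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr), auc


# ---------------------------------------------------------------------------
# aggregation and reporting
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ("ACC", "SEN", "SP", "AUC", "F1")


def aggregate(items, *, mode: str = "pooled", threshold: float = 0.5,
              use_fov: bool = True) -> dict:
    """Aggregate metrics over (scores, truth, fov) triples.

    ``mode='pooled'`` sums confusion counts over all FOV pixels of all
    images (one global ratio); ``'per_image'`` averages per-image
    metrics.  ``scores`` are probabilities; binarised at ``threshold``
    for ACC/SEN/SP/F1, used raw for AUC.
    """
    if mode not in ("pooled", "per_image"):
        raise ValueError("mode must be 'pooled' or 'per_image'")
    rows = []
    pooled = ConfusionCounts()
    all_scores, all_truth = [], []
    for scores, truth, fov in items:
        if not use_fov:
            fov = None
        c = confusion_counts(np.asarray(scores) >= threshold, truth, fov)
        pooled = pooled + c
        m = fov if fov is not None else np.ones_like(np.asarray(truth), bool)
        m = np.asarray(m, dtype=bool)
        all_scores.append(np.asarray(scores)[m].ravel())
        all_truth.append(np.asarray(truth)[m].ravel())
        rows.append((c, scores, truth, fov))
    if mode == "pooled":
        _, auc = roc_auc(np.concatenate(all_scores), np.concatenate(all_truth))
        c = pooled
        return {"ACC": accuracy(c), "SEN": sensitivity(c),
                "SP": specificity(c), "AUC": auc, "F1": f1_score(c),
                "n_pixels": c.total}
    per = []
    for c, scores, truth, fov in rows:
        _, auc = roc_auc(scores, truth, fov)
        per.append([accuracy(c), sensitivity(c), specificity(c), auc,
                    f1_score(c)])
    mean = np.mean(per, axis=0)
    out = dict(zip(METRIC_COLUMNS, (float(v) for v in mean)))
    out["n_pixels"] = pooled.total
    return out


def report_csv(results: dict, path=None) -> str:
    """Write a per-dataset metric table (columns ACC, SEN, SP, AUC, F1)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(("dataset",) + METRIC_COLUMNS)
    for name, row in results.items():
        writer.writerow([name] + [f"{row[c]:.4f}" for c in METRIC_COLUMNS])
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def report_text(results: dict) -> str:
    header = f"{'dataset':<12}" + "".join(f"{c:>9}" for c in METRIC_COLUMNS)
    lines = [header, "-" * len(header)]
    for name, row in results.items():
        lines.append(f"{name:<12}"
                     + "".join(f"{row[c]:>9.4f}" for c in METRIC_COLUMNS))
    return "\n".join(lines)
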