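"""Segmentation/classification metrics, cross-fold aggregation and the
significance tests used to compare models.

Conventions
-----------
- Masks are binary {0,1}; both-empty Dice/IoU is 1.0 by convention.
- An empty prediction against a nonempty reference gets Dice/IoU 0 and an
  average Hausdorff distance equal to the image-diagonal length (a finite,
  monotone penalty), with a warning.
- For classification, "malignant" is the positive class.
- Distances are in pixel units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

__all__ = [
    "BinaryMaskPair",
    "FoldResults",
    "AggregateReport",
    "dice_coefficient",
    "iou",
    "average_hausdorff",
    "accuracy",
    "sensitivity_specificity",
    "auc",
    "paired_t_test",
    "welch_t_test",
    "fold_aggregate",
    "load_published_folds",
    "binarize_probabilities",
]

POSITIVE_LABEL = "malignant"


@dataclass
class BinaryMaskPair:
    predicted: np.ndarray
    reference: np.ndarray
    pixel_spacing: tuple = (1.0, 1.0)

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted)
        self.reference = np.asarray(self.reference)
        if self.predicted.shape != self.reference.shape:
            raise ValueError(
                f"mask shape mismatch: {self.predicted.shape} vs {self.reference.shape}"
            )
        for name, m in (("predicted", self.predicted), ("reference", self.reference)):
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{name} mask is not binary (values {vals[:5]})")


def _counts(pair: BinaryMaskPair):
    p = pair.predicted.astype(bool)
    r = pair.reference.astype(bool)
    return p, r, np.logical_and(p, r).sum(), p.sum(), r.sum()


def dice_coefficient(pair: BinaryMaskPair) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    _, _, inter, np_, nr = _counts(pair)
    if np_ + nr == 0:
        return 1.0
    return 2.0 * inter / (np_ + nr)


def iou(pair: BinaryMaskPair) -> float:
    """|A∩B| / |A∪B|; 1.0 when both masks are empty."""
    _, _, inter, np_, nr = _counts(pair)
    union = np_ + nr - inter
    if union == 0:
        return 1.0
    return inter / union


def average_hausdorff(pair: BinaryMaskPair, boundary_only: bool = False) -> float:
    """Symmetric average of mean directed nearest-neighbour distances (px).

    With ``boundary_only`` the point sets are reduced to 4-connected boundary
    pixels before matching; the default uses every foreground pixel.
    """
    pred = pair.predicted.astype(bool)
    ref = pair.reference.astype(bool)
    if not ref.any():
        raise ValueError("average_hausdorff requires a nonempty reference mask")
    if boundary_only:
        pred, ref = _boundary(pred), _boundary(ref)
    if not pred.any():
        diag = float(np.hypot(*[d - 1 for d in pair.reference.shape]))
        warnings.warn(
            "empty predicted mask: reporting image-diagonal AHD penalty",
            stacklevel=2,
        )
        return diag
    a = np.argwhere(pred).astype(float)
    b = np.argwhere(ref).astype(float)
    d_ab = cKDTree(b).query(a)[0].mean()
    d_ba = cKDTree(a).query(b)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def _boundary(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    return mask & ~binary_erosion(mask, border_value=0)


def binarize_probabilities(prob_foreground: np.ndarray, threshold: float = 0.5):
    """Threshold a foreground-probability map into a {0,1} mask."""
    return (np.asarray(prob_foreground) >= threshold).astype(np.uint8)


# --- classification -----------------------------------------------------------


def _confusion(pred, true):
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("label arrays must be nonempty and equal-length")
    pos = POSITIVE_LABEL
    tp = np.sum((pred == pos) & (true == pos))
    tn = np.sum((pred != pos) & (true != pos))
    fp = np.sum((pred == pos) & (true != pos))
    fn = np.sum((pred != pos) & (true == pos))
    return tp, tn, fp, fn


def accuracy(pred_labels, true_labels) -> float:
    tp, tn, fp, fn = _confusion(pred_labels, true_labels)
    return (tp + tn) / (tp + tn + fp + fn)


def sensitivity_specificity(pred_labels, true_labels) -> tuple:
    """(sensitivity, specificity) with malignant as the positive class."""
    tp, tn, fp, fn = _confusion(pred_labels, true_labels)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return float(sens), float(spec)


def auc(scores, labels) -> float:
    """Rank-based AUC of malignant-class scores (ties count one half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = (labels == POSITIVE_LABEL).astype(int)
    if y.min() == y.max():
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(y, scores))


# --- statistics ---------------------------------------------------------------


def paired_t_test(values_a, values_b) -> float:
    """Two-tailed paired t-test p-value; identical sequences give p = 1.0."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t_test needs two equal-length sequences, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def welch_t_test(group_a, group_b) -> float:
    """Two-tailed Welch (unequal-variance) t-test p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test needs >= 2 values per group")
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


# --- cross-fold aggregation ---------------------------------------------------


@dataclass
class FoldResults:
    """Per-fold metric values of one model across a k-fold evaluation."""

    model: str
    metrics: dict = field(default_factory=dict)  # metric name -> list of fold values

    def __post_init__(self):
        lengths = {len(v) for v in self.metrics.values()}
        if len(lengths) > 1:
            raise ValueError("all metrics must cover the same folds")

    @property
    def n_folds(self) -> int:
        return next(iter(len(v) for v in self.metrics.values()), 0)


@dataclass
class AggregateReport:
    model: str
    mean: dict
    sd: dict
    decimals: int = 3

    def rounded_mean(self, metric: str) -> float:
        return round(self.mean[metric], self.decimals)


def fold_aggregate(results: FoldResults, decimals: int = 3) -> AggregateReport:
    """Arithmetic mean and sample SD (ddof=1) of each metric across folds."""
    if results.n_folds < 2:
        raise ValueError("fold_aggregate needs >= 2 folds")
    mean = {k: float(np.mean(v)) for k, v in results.metrics.items()}
    sd = {k: float(np.std(v, ddof=1)) for k, v in results.metrics.items()}
    return AggregateReport(model=results.model, mean=mean, sd=sd, decimals=decimals)


def load_published_folds() -> dict:
    """Per-fold values from the published five-fold PET/CT ovarian-tumor
    evaluation, shipped as package data (used to check that aggregation and
    significance testing reproduce the published summary rows)."""
    with resources.files("kitefusion.data").joinpath("published_folds.json").open() as f:
        return json.load(f)
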