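"""Segmentation-agreement metrics between predicted and reference masks.

Voxel-level metrics (precision, recall, overall Dice) treat the whole
volume as one set comparison.  Voxel-wise Dice averages a per-lesion Dice
over reference lesions, where each reference lesion is compared against
the union of predicted components that touch it; unmatched lesions
contribute 0.  Lesion-wise Dice works on lesion identities: a reference
lesion counts as a true positive when the prediction covers at least one
of its voxels, and

    lesionwise_dice = 2 TP / (2 TP + FP + FN)

with FP the predicted components that touch no reference lesion.  Count
and volume agreement across subjects use Spearman rank correlation and
Lin's concordance correlation coefficient with population (1/n) moments:

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import VoxelGrid3D, check_geometry
from .morphology import label_components

__all__ = [
    "SegEvalResult",
    "overlap_metrics",
    "voxelwise_dice",
    "lesionwise_dice",
    "lin_ccc",
    "agreement_stats",
    "evaluate_pair",
]


@dataclass
class SegEvalResult:
    """Agreement metrics for one prediction/reference mask pair."""

    precision: float | None
    recall: float | None
    overall_dice: float | None
    voxelwise_dice: float | None
    lesionwise_dice: float | None
    n_pred_lesions: int
    n_truth_lesions: int


def _check_pair(pred: VoxelGrid3D, truth: VoxelGrid3D) -> None:
    pred.require_binary("pred mask")
    truth.require_binary("truth mask")
    report = check_geometry([pred, truth])
    if not report:
        raise ValueError("pred/truth geometry mismatch: " + "; ".join(report.messages))


def overlap_metrics(
    pred: VoxelGrid3D, truth: VoxelGrid3D
) -> tuple[float | None, float | None, float | None]:
    """(precision, recall, overall Dice) over the whole volume.

    An empty denominator yields None (missing), not 0; both masks empty
    leaves every metric missing.
    """
    _check_pair(pred, truth)
    p = pred.astype_bool()
    t = truth.astype_bool()
    tp = int((p & t).sum())
    n_p, n_t = int(p.sum()), int(t.sum())
    precision = tp / n_p if n_p else None
    recall = tp / n_t if n_t else None
    dice = 2 * tp / (n_p + n_t) if (n_p + n_t) else None
    return precision, recall, dice


def voxelwise_dice(pred: VoxelGrid3D, truth: VoxelGrid3D, connectivity: int = 26) -> float:
    """Mean per-reference-lesion Dice against the union of touching
    predicted components; lesions missed entirely contribute 0."""
    _check_pair(pred, truth)
    t_lab, n_t = label_components(truth, connectivity)
    if n_t == 0:
        raise ValueError("truth mask has no lesions")
    p_lab, _ = label_components(pred, connectivity)
    scores = []
    p_sizes = np.bincount(p_lab.ravel())
    for i in range(1, n_t + 1):
        lesion = t_lab == i
        touching = np.unique(p_lab[lesion])
        touching = touching[touching > 0]
        if len(touching) == 0:
            scores.append(0.0)
            continue
        p_union_size = int(p_sizes[touching].sum())
        overlap = int(np.isin(p_lab[lesion], touching).sum())
        scores.append(2 * overlap / (p_union_size + int(lesion.sum())))
    return float(np.mean(scores))


def lesionwise_dice(pred: VoxelGrid3D, truth: VoxelGrid3D, connectivity: int = 26) -> float:
    """Dice over lesion identities: 2TP / (2TP + FP + FN)."""
    _check_pair(pred, truth)
    t_lab, n_t = label_components(truth, connectivity)
    p_lab, n_p = label_components(pred, connectivity)
    if n_t == 0 and n_p == 0:
        raise ValueError("both masks have no lesions")
    p_bool = p_lab > 0
    t_bool = t_lab > 0
    hit_truth = np.unique(t_lab[p_bool & t_bool])
    hit_truth = hit_truth[hit_truth > 0]
    tp = len(hit_truth)
    fn = n_t - tp
    hit_pred = np.unique(p_lab[p_bool & t_bool])
    hit_pred = hit_pred[hit_pred > 0]
    fp = n_p - len(hit_pred)
    return 2 * tp / (2 * tp + fp + fn)


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient, population moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired lists must have equal length")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both inputs constant and equal")
    return float(2 * cov / denom)


def agreement_stats(
    pred_values: np.ndarray, truth_values: np.ndarray
) -> tuple[float | None, float]:
    """(Spearman rho, Lin's CCC) between paired per-subject measurements.

    Spearman is missing (None) when either input is constant.
    """
    x = np.asarray(pred_values, dtype=float)
    y = np.asarray(truth_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired lists must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho = None
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    return rho, lin_ccc(x, y)


def evaluate_pair(pred: VoxelGrid3D, truth: VoxelGrid3D, connectivity: int = 26) -> SegEvalResult:
    """All mask-level metrics for one prediction/reference pair."""
    precision, recall, dice = overlap_metrics(pred, truth)
    _, n_t = label_components(truth, connectivity)
    _, n_p = label_components(pred, connectivity)
    vw = voxelwise_dice(pred, truth, connectivity) if n_t else None
    lw = lesionwise_dice(pred, truth, connectivity) if (n_t or n_p) else None
    return SegEvalResult(
        precision=precision,
        recall=recall,
        overall_dice=dice,
        voxelwise_dice=vw,
        lesionwise_dice=lw,
        n_pred_lesions=n_p,
        n_truth_lesions=n_t,
    )
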