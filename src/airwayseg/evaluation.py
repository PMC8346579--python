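"""Airway-segmentation evaluation metrics on skeletonized centerlines.

Five measures compare a binary prediction P with a ground truth G:

- **Tree length detected (TL)**: ground-truth centerline voxels inside
  P, as a percentage of the full ground-truth centerline length — a
  completeness/sensitivity measure.
- **Centerline leakage (CL)**: predicted-centerline voxels outside G,
  as a percentage of the ground-truth centerline length — a
  specificity measure.
- **False positive rate (FPR)**: voxels of P outside G as a percentage
  of |G| (unbounded above; no clamping).
- **Dice coefficient (DSC)**: 2|P∩G| / (|P|+|G|), defined as 1 when
  both masks are empty.
- **Total tree length**: detected ground-truth centerline voxels times
  the geometric mean of the voxel sizes, in mm.

Centerlines are obtained by 3D medial-axis thinning (Lee et al.) unless
supplied. The trachea and main bronchi are excluded from all measures:
the central-airway mask, dilated by one voxel to absorb boundary
voxels, is removed from predictions, ground truth and centerlines
before anything is counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .grid import VolumeGrid

__all__ = [
    "EvalResult",
    "EvalInputs",
    "UndefinedMetricError",
    "skeletonize_mask",
    "exclude_central_airways",
    "tree_length_detected",
    "centerline_leakage",
    "false_positive_rate",
    "dice_coefficient",
    "total_tree_length",
    "evaluate",
    "results_table",
]


class UndefinedMetricError(ValueError):
    """A metric's reference set is empty (e.g. no ground-truth centerline)."""


@dataclass
class EvalResult:
    tree_length_pct: float
    centerline_leakage_pct: float
    false_positive_rate_pct: float
    dice: float
    total_tree_length_mm: float


@dataclass
class EvalInputs:
    """Aligned grids entering the evaluation.

    ``truth_centerline`` may be None, in which case it is computed by
    thinning the (exclusion-filtered) ground truth. ``central_mask`` is
    the trachea + main-bronchi exclusion region (may be empty).
    """

    prediction: VolumeGrid
    truth: VolumeGrid
    truth_centerline: Optional[VolumeGrid] = None
    central_mask: Optional[VolumeGrid] = None

    def __post_init__(self) -> None:
        ref = self.prediction
        for grid in (self.truth, self.truth_centerline, self.central_mask):
            if grid is not None and grid.shape != ref.shape:
                raise ValueError("evaluation grids must share one shape")


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Medial-axis thinning of a 3D binary mask (Lee et al. 1994).

    Returns a mask of <= 1-voxel-wide curves contained in the input;
    empty input gives an empty skeleton.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    return skeletonize(mask).astype(bool)


def exclude_central_airways(inputs: EvalInputs, dilate: int = 1) -> EvalInputs:
    """Zero the (dilated) central-airway mask out of every grid.

    Dilation by one voxel absorbs skeleton voxels sitting exactly on
    the root boundary, which would otherwise leak into the metrics.
    """
    if inputs.central_mask is None or not inputs.central_mask.values.any():
        return inputs
    excl = inputs.central_mask.values.astype(bool)
    if dilate > 0:
        excl = ndimage.binary_dilation(
            excl, structure=ndimage.generate_binary_structure(3, 3), iterations=dilate
        )
    keep = ~excl

    def strip(grid: Optional[VolumeGrid]) -> Optional[VolumeGrid]:
        if grid is None:
            return None
        return grid.with_values((grid.values.astype(bool) & keep).astype(np.uint8))

    return EvalInputs(
        prediction=strip(inputs.prediction),
        truth=strip(inputs.truth),
        truth_centerline=strip(inputs.truth_centerline),
        central_mask=inputs.central_mask,
    )


def tree_length_detected(pred: np.ndarray, truth_centerline: np.ndarray) -> float:
    """Percent of ground-truth centerline voxels inside the prediction."""
    cl = np.asarray(truth_centerline).astype(bool)
    n = int(cl.sum())
    if n == 0:
        raise UndefinedMetricError("tree length: empty ground-truth centerline")
    detected = int((np.asarray(pred).astype(bool) & cl).sum())
    return 100.0 * detected / n


def centerline_leakage(
    pred_centerline: np.ndarray, truth: np.ndarray, truth_centerline_length: int
) -> float:
    """Predicted-centerline voxels outside the truth, as a percent of the
    ground-truth centerline length."""
    if truth_centerline_length <= 0:
        raise UndefinedMetricError("centerline leakage: zero reference length")
    pc = np.asarray(pred_centerline).astype(bool)
    outside = int((pc & ~np.asarray(truth).astype(bool)).sum())
    return 100.0 * outside / truth_centerline_length


def false_positive_rate(pred: np.ndarray, truth: np.ndarray) -> float:
    """|P \\ G| as a percent of |G| (may exceed 100)."""
    g = np.asarray(truth).astype(bool)
    n = int(g.sum())
    if n == 0:
        raise UndefinedMetricError("false positive rate: empty ground truth")
    fp = int((np.asarray(pred).astype(bool) & ~g).sum())
    return 100.0 * fp / n


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|P∩G| / (|P|+|G|); 1.0 when both are empty."""
    p = np.asarray(pred).astype(bool)
    g = np.asarray(truth).astype(bool)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def total_tree_length(
    pred: np.ndarray,
    truth_centerline: np.ndarray,
    spacing: Tuple[float, float, float],
) -> float:
    """Detected centerline voxels times the geometric-mean voxel size (mm)."""
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    detected = int(
        (np.asarray(pred).astype(bool) & np.asarray(truth_centerline).astype(bool)).sum()
    )
    factor = float(np.prod(spacing)) ** (1.0 / 3.0)
    return detected * factor


def evaluate(inputs: EvalInputs) -> EvalResult:
    """All five metrics for one prediction/ground-truth pair.

    Applies the central-airway exclusion, skeletonizes the prediction
    (and the truth, when no centerline is supplied), then counts.
    """
    stripped = exclude_central_airways(inputs)
    pred = stripped.prediction.values.astype(bool)
    truth = stripped.truth.values.astype(bool)
    if stripped.truth_centerline is not None:
        truth_cl = stripped.truth_centerline.values.astype(bool)
    else:
        truth_cl = skeletonize_mask(truth)
    pred_cl = skeletonize_mask(pred)
    n_cl = int(truth_cl.sum())
    return EvalResult(
        tree_length_pct=tree_length_detected(pred, truth_cl),
        centerline_leakage_pct=centerline_leakage(pred_cl, truth, n_cl),
        false_positive_rate_pct=false_positive_rate(pred, truth),
        dice=dice_coefficient(pred, truth),
        total_tree_length_mm=total_tree_length(
            pred, truth_cl, stripped.prediction.spacing
        ),
    )


def results_table(results: Iterable[Tuple[str, EvalResult]]) -> pd.DataFrame:
    """One row per case plus a median / quartile summary row."""
    rows = []
    for case_id, r in results:
        rows.append(
            {
                "case": case_id,
                "tree_length_pct": r.tree_length_pct,
                "centerline_leakage_pct": r.centerline_leakage_pct,
                "false_positive_rate_pct": r.false_positive_rate_pct,
                "dice": r.dice,
                "total_tree_length_mm": r.total_tree_length_mm,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        med = df.drop(columns="case").median(numeric_only=True)
        q1 = df.drop(columns="case").quantile(0.25, numeric_only=True)
        q3 = df.drop(columns="case").quantile(0.75, numeric_only=True)
        for name, series in (("median", med), ("q1", q1), ("q3", q3)):
            row = dict(series)
            row["case"] = name
            df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    return df
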