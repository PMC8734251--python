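"""BraTS-convention per-region evaluation metrics.

For each nested region (ET, TC, WT) of a predicted and a reference
label map: Dice = 2TP/(FN+FP+2TP), Sensitivity = TP/(TP+FN),
Specificity = TN/(TN+FP), and the 95th-percentile symmetrized surface
distance (HD95). Surfaces are the 6-connectivity boundary voxels of
each mask (mask voxels with at least one background face-neighbor;
voxels on the array border count as boundary). Directed distances are
Euclidean, scaled by the voxel spacing, and HD95 is the maximum of the
two directed 95th percentiles; percentile 100 recovers the classical
sup-inf Hausdorff distance.

Empty-mask conventions (surfaced via flags in the report): both masks
empty -> dice 1, hd95 0; exactly one empty -> dice 0, hd95 set to the
volume diagonal as a sentinel. An all-positive reference leaves
specificity undefined (no negatives); it is reported as 1 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .preprocess import labels_to_regions

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice_score",
    "sensitivity_score",
    "specificity_score",
    "surface_points",
    "hausdorff95",
    "evaluate_case",
    "reports_to_frame",
]

REGIONS = ("ET", "TC", "WT")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exhaustive voxel counts over two equal-shape binary masks."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def dice_score(c: ConfusionCounts) -> float:
    """2TP/(FN+FP+2TP); both masks empty -> 1 by convention."""
    den = c.FN + c.FP + 2 * c.TP
    if den == 0:
        return 1.0
    return 2.0 * c.TP / den


def sensitivity_score(c: ConfusionCounts) -> float:
    """TP/(TP+FN); empty reference (no positives) -> 1 by convention."""
    den = c.TP + c.FN
    if den == 0:
        return 1.0
    return c.TP / den


def specificity_score(c: ConfusionCounts) -> float:
    """TN/(TN+FP); all-positive reference (no negatives) -> 1 by convention."""
    den = c.TN + c.FP
    if den == 0:
        return 1.0
    return c.TN / den


def surface_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates (k, 3) of boundary voxels: mask voxels with a
    background face-neighbor (outside the array counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3), dtype=np.intp)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff95(pred: np.ndarray, gt: np.ndarray,
                spacing=(1.0, 1.0, 1.0), percentile: float = 95.0,
                ) -> tuple[float, str]:
    """Percentile symmetrized surface distance; returns (value, flag).

    flag is "" normally, "both_empty" or "one_empty" for the convention
    cases (sentinel = spacing-scaled volume diagonal).
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    sp = np.asarray(spacing, dtype=float)
    if not pred.any() and not gt.any():
        return 0.0, "both_empty"
    if not pred.any() or not gt.any():
        diag = float(np.linalg.norm(sp * np.asarray(pred.shape)))
        return diag, "one_empty"
    sp_pred = surface_points(pred) * sp
    sp_gt = surface_points(gt) * sp
    d_pred_to_gt = cKDTree(sp_gt).query(sp_pred)[0]
    d_gt_to_pred = cKDTree(sp_pred).query(sp_gt)[0]
    value = max(
        float(np.percentile(d_pred_to_gt, percentile)),
        float(np.percentile(d_gt_to_pred, percentile)),
    )
    return value, ""


@dataclass
class MetricsReport:
    """Per-region metrics for one case."""

    case_id: str
    dice: dict[str, float]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    hd95: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)

    def rows(self):
        for region in REGIONS:
            yield {
                "case_id": self.case_id,
                "region": region,
                "dice": self.dice[region],
                "sensitivity": self.sensitivity[region],
                "specificity": self.specificity[region],
                "hd95": self.hd95[region],
                "flag": self.flags.get(region, ""),
            }


def evaluate_case(pred_labels: np.ndarray, gt_labels: np.ndarray,
                  spacing=(1.0, 1.0, 1.0), case_id: str = "case",
                  percentile: float = 95.0) -> MetricsReport:
    """All four metrics for the three nested regions of one case."""
    pred_regions = labels_to_regions(pred_labels)
    gt_regions = labels_to_regions(gt_labels)
    dice, sens, spec, hd, flags = {}, {}, {}, {}, {}
    for region in REGIONS:
        pm, gm = pred_regions[region], gt_regions[region]
        c = confusion(pm, gm)
        dice[region] = dice_score(c)
        sens[region] = sensitivity_score(c)
        spec[region] = specificity_score(c)
        hd_val, flag = hausdorff95(pm, gm, spacing=spacing,
                                   percentile=percentile)
        hd[region] = hd_val
        conventions = []
        if flag:
            conventions.append(flag)
        if c.TP + c.FN == 0:
            conventions.append("empty_reference")
        if c.TN + c.FP == 0:
            conventions.append("all_positive_reference")
        if conventions:
            flags[region] = ",".join(conventions)
    return MetricsReport(case_id=case_id, dice=dice, sensitivity=sens,
                         specificity=spec, hd95=hd, flags=flags)


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack per-case reports into a tidy frame plus mean/median summary
    rows (layout mirrors per-region challenge tables)."""
    rows = [row for rep in reports for row in rep.rows()]
    df = pd.DataFrame(rows)
    summaries = []
    for stat, fn in (("mean", np.mean), ("median", np.median)):
        for region in REGIONS:
            sub = df[df.region == region]
            summaries.append({
                "case_id": f"__{stat}__",
                "region": region,
                "dice": fn(sub.dice),
                "sensitivity": fn(sub.sensitivity),
                "specificity": fn(sub.specificity),
                "hd95": fn(sub.hd95),
                "flag": "",
            })
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
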