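"""Segmentation evaluation: overlap metrics, contour distances, paired t-test.

Per mask pair the suite reports the Dice coefficient kappa_D = 2*TP/(2*TP+FN+FP),
sensitivity kappa_st = TP/(TP+FN) (under-segmentation), sensibility
kappa_sb = 1 - FP/(TP+FN) (over-segmentation penalty; may be negative and is
reported unclamped), the Hausdorff distance delta_h between the prediction and
ground-truth contours, and the average Hausdorff distance delta_ah, both in mm.

Contours are extracted per slice with a 4-neighbor interior test and unioned
into a 3-D point set of boundary-voxel centers at ``index * spacing``; distances
are 3-D Euclidean, so anisotropic voxels are handled in physical space.
The average Hausdorff distance is the symmetric mean of the two directed
average nearest-neighbor distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .io_preprocess import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ContourPointSet:
    """Boundary-voxel centers of a mask in physical (mm) coordinates."""

    points: np.ndarray  # (n, 3) float64, mm

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError(f"expected an (n, 3) point array, got shape {p.shape}")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MetricReport:
    dice: float
    sensitivity: float
    sensibility: float
    hausdorff_mm: float
    avg_hausdorff_mm: float
    counts: ConfusionCounts


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    v = mask.voxels if isinstance(mask, BinaryMask) else np.asarray(mask)
    return v.astype(bool)


def _check_shapes(sp, gt) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_bool(sp), _as_bool(gt)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: prediction {a.shape} vs ground truth {b.shape}")
    return a, b


def confusion_counts(sp: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray) -> ConfusionCounts:
    """Voxelwise TP/FP/FN/TN between a prediction and a ground-truth mask."""
    a, b = _check_shapes(sp, gt)
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    tn = a.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice(sp: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray) -> float:
    """Dice coefficient 2*TP / (2*TP + FN + FP); 1.0 when both masks are empty."""
    c = confusion_counts(sp, gt)
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def sensitivity(sp: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray) -> float:
    """TP / (TP + FN); requires a non-empty ground truth."""
    c = confusion_counts(sp, gt)
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined for empty ground truth")
    return c.tp / (c.tp + c.fn)


def sensibility(sp: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray) -> float:
    """1 - FP / (TP + FN); unclamped, so heavy over-segmentation goes negative."""
    c = confusion_counts(sp, gt)
    if c.tp + c.fn == 0:
        raise ValueError("sensibility undefined for empty ground truth")
    return 1.0 - c.fp / (c.tp + c.fn)


def extract_contour(mask: BinaryMask | np.ndarray,
                    spacing_mm: Sequence[float] | None = None) -> ContourPointSet:
    """In-plane boundary voxels of a mask mapped to mm coordinates.

    A foreground voxel is a boundary voxel iff at least one of its in-plane
    4-neighbors is background or lies outside the image; voxel centers sit at
    ``index * spacing`` (0-based).
    """
    if isinstance(mask, BinaryMask):
        v = mask.voxels.astype(bool)
        spacing = mask.spacing_mm
    else:
        v = np.asarray(mask).astype(bool)
        if spacing_mm is None:
            raise ValueError("spacing_mm required for a bare array")
        spacing = tuple(spacing_mm)
    if v.ndim == 2:
        v = v[None]
    if not v.any():
        raise ValueError("cannot extract a contour from an empty mask")
    interior = v.copy()
    # 4-neighbor test with out-of-image treated as background
    padded = np.pad(v, ((0, 0), (1, 1), (1, 1)), constant_values=False)
    interior = (padded[:, :-2, 1:-1] & padded[:, 2:, 1:-1]
                & padded[:, 1:-1, :-2] & padded[:, 1:-1, 2:])
    boundary = v & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    idx *= np.asarray(spacing, dtype=np.float64)
    return ContourPointSet(points=idx)


def _directed_nn(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distances from every point of a to the set b."""
    d, _ = cKDTree(b).query(a, k=1)
    return d


def hausdorff(a: ContourPointSet, b: ContourPointSet) -> float:
    """Symmetric Hausdorff distance in mm between two contour point sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Hausdorff distance undefined for empty point sets")
    return float(max(_directed_nn(a.points, b.points).max(),
                     _directed_nn(b.points, a.points).max()))


def average_hausdorff(a: ContourPointSet, b: ContourPointSet) -> float:
    """Symmetric mean of the two directed average nearest-neighbor distances."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("average Hausdorff distance undefined for empty point sets")
    return float((_directed_nn(a.points, b.points).mean()
                  + _directed_nn(b.points, a.points).mean()) / 2.0)


def evaluate_pair(sp: BinaryMask, gt: BinaryMask) -> MetricReport:
    """All five metrics for one aligned prediction / ground-truth pair."""
    if sp.shape != gt.shape:
        raise ValueError(f"shape mismatch: {sp.shape} vs {gt.shape}")
    if sp.spacing_mm != gt.spacing_mm:
        raise ValueError(f"spacing mismatch: {sp.spacing_mm} vs {gt.spacing_mm}")
    c = confusion_counts(sp, gt)
    if c.tp + c.fn == 0:
        raise ValueError("ground-truth mask is empty")
    d = 1.0 if 2 * c.tp + c.fn + c.fp == 0 else 2.0 * c.tp / (2 * c.tp + c.fn + c.fp)
    ga = extract_contour(gt)
    sa = extract_contour(sp)  # raises for an empty prediction, by design
    return MetricReport(
        dice=d,
        sensitivity=c.tp / (c.tp + c.fn),
        sensibility=1.0 - c.fp / (c.tp + c.fn),
        hausdorff_mm=hausdorff(sa, ga),
        avg_hausdorff_mm=average_hausdorff(sa, ga),
        counts=c,
    )


def evaluate_cohort(pairs: Sequence[tuple[BinaryMask, BinaryMask]],
                    subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-subject metric table with a trailing mean and std summary row."""
    rows = []
    for i, (sp, gt) in enumerate(pairs):
        r = evaluate_pair(sp, gt)
        sid = subject_ids[i] if subject_ids is not None else (sp.subject_id or f"subject{i:03d}")
        rows.append({"subject_id": sid, "dice": r.dice, "sensitivity": r.sensitivity,
                     "sensibility": r.sensibility, "hausdorff_mm": r.hausdorff_mm,
                     "avg_hausdorff_mm": r.avg_hausdorff_mm})
    df = pd.DataFrame(rows)
    metric_cols = ["dice", "sensitivity", "sensibility", "hausdorff_mm", "avg_hausdorff_mm"]
    summary = pd.DataFrame([
        {"subject_id": "mean", **{c: df[c].mean() for c in metric_cols}},
        {"subject_id": "std", **{c: df[c].std(ddof=1) if len(df) > 1 else 0.0
                                 for c in metric_cols}},
    ])
    return pd.concat([df, summary], ignore_index=True)


def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on per-subject score differences.

    Returns (t statistic, two-tailed p). Raises ``ValueError`` on length
    mismatch or when the differences have zero variance (including all-equal
    inputs), where the statistic is undefined.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test requires two equal-length score vectors")
    if len(a) < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate differences: zero variance")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
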