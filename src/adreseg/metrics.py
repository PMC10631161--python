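"""Segmentation evaluation metrics.

Five per-case metrics: Dice score (DSC), intersection over union (IOU),
Hausdorff distance, average surface distance (ASD) and mean absolute
voxel error (MAE).  Overlap metrics are exact voxel counts; surface
metrics operate on the 6-connectivity boundary voxels of each mask, with
distances measured between voxel centers in physical millimetres (voxel
units optionally, by passing unit spacing).  ASD is directed,
prediction -> truth, as defined; a symmetrized variant is available
behind a flag.  The Hausdorff distance is the full maximum (not a
percentile variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "CaseMetrics",
    "dice",
    "iou",
    "mae",
    "surface_voxels",
    "hausdorff",
    "asd",
    "evaluate_case",
]


@dataclass
class CaseMetrics:
    dsc: float
    iou: float
    hausdorff: float
    asd: float
    mae: float
    case_id: str = ""
    surface_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "dsc": self.dsc,
            "iou": self.iou,
            "hausdorff": self.hausdorff,
            "asd": self.asd,
            "mae": self.mae,
        }


def _check_grids(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    return x, y


def dice(x, y) -> float:
    """2|X n Y| / (|X| + |Y|); two empty masks agree perfectly (1.0)."""
    x, y = _check_grids(x, y)
    sx, sy = int(x.sum()), int(y.sum())
    if sx + sy == 0:
        return 1.0
    return 2.0 * int(np.logical_and(x, y).sum()) / (sx + sy)


def iou(x, y) -> float:
    """|X n Y| / |X u Y|; two empty masks give 1.0."""
    x, y = _check_grids(x, y)
    union = int(np.logical_or(x, y).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(x, y).sum()) / union


def mae(pred, truth) -> float:
    """Mean absolute voxelwise error — the mislabeled-voxel fraction for
    binary masks."""
    pred, truth = _check_grids(pred, truth)
    return float(np.abs(pred.astype(np.float64) - truth.astype(np.float64)).mean())


def surface_voxels(mask, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Centers (mm) of foreground voxels with a 6-neighbour background voxel
    (out-of-grid counts as background).  Shape (n, 3); empty mask -> (0, 3).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.empty((0, 3))
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    surf = m & ~interior
    return np.argwhere(surf).astype(np.float64) * np.asarray(spacing, np.float64)


def _directed_max(a: np.ndarray, b: np.ndarray) -> float:
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(np.max(d))


def _directed_mean(a: np.ndarray, b: np.ndarray) -> float:
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(np.mean(d))


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """H(A,B) = max(h(A,B), h(B,A)) with h the directed maximal minimal
    Euclidean distance between point sets."""
    a, b = np.atleast_2d(np.asarray(a, np.float64)), np.atleast_2d(np.asarray(b, np.float64))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Hausdorff distance is undefined for an empty point set")
    return max(_directed_max(a, b), _directed_max(b, a))


def asd(x: np.ndarray, y: np.ndarray, symmetric: bool = False) -> float:
    """Average surface distance, directed X -> Y (mean over x of the minimal
    distance to Y).  ``symmetric=True`` averages both directions."""
    x, y = np.atleast_2d(np.asarray(x, np.float64)), np.atleast_2d(np.asarray(y, np.float64))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("ASD is undefined for an empty point set")
    d = _directed_mean(x, y)
    if symmetric:
        d = 0.5 * (d + _directed_mean(y, x))
    return d


def evaluate_case(
    pred,
    truth,
    spacing=(1.0, 1.0, 1.0),
    case_id: str = "",
    symmetric_asd: bool = False,
) -> CaseMetrics:
    """All five metrics for one aligned prediction/truth mask pair.

    If either mask is empty the surface metrics are undefined and reported
    as NaN with ``surface_defined=False``; the overlap metrics are still
    computed.
    """
    pred_b, truth_b = _check_grids(pred, truth)
    d = dice(pred_b, truth_b)
    j = iou(pred_b, truth_b)
    m = mae(pred_b, truth_b)
    sp = surface_voxels(pred_b, spacing)
    st = surface_voxels(truth_b, spacing)
    if len(sp) == 0 or len(st) == 0:
        return CaseMetrics(d, j, float("nan"), float("nan"), m, case_id, surface_defined=False)
    h = hausdorff(sp, st)
    a = asd(sp, st, symmetric=symmetric_asd)
    return CaseMetrics(d, j, h, a, m, case_id)
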