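"""Segmentation accuracy metrics: Dice, Jaccard, Hausdorff, ASSD.

Surface voxels are mask voxels with at least one non-mask 6-neighbor
(voxels at the image border count as surface). Distances are Euclidean
between surface-voxel centers in physical millimetres, respecting
anisotropic spacing. The Hausdorff distance is the exact maximum (not a
percentile variant); the ASSD pools all directed surface distances from
both masks, i.e. a surface-size-weighted symmetric mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import BinaryMask, check_geometry_match

_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegMetricsResult:
    dsc: float
    jc: float
    hd_mm: float
    assd_mm: float


def overlap_metrics(pred: BinaryMask, ref: BinaryMask) -> tuple[float, float]:
    """Dice and Jaccard overlap coefficients."""
    check_geometry_match(pred, ref)
    p, r = pred.data, ref.data
    np_, nr = int(p.sum()), int(r.sum())
    if np_ == 0 and nr == 0:
        raise ValueError("both masks are empty; overlap undefined")
    inter = int((p & r).sum())
    dsc = 2.0 * inter / (np_ + nr)
    jc = inter / (np_ + nr - inter)
    return dsc, jc


def _surface_points_mm(mask: BinaryMask) -> np.ndarray:
    data = mask.data
    eroded = ndimage.binary_erosion(data, structure=_CONN6, border_value=0)
    surface = data & ~eroded
    idx = np.argwhere(surface)
    return idx * np.asarray(mask.spacing_mm)


def surface_metrics(pred: BinaryMask, ref: BinaryMask) -> tuple[float, float]:
    """Hausdorff distance and average symmetric surface distance in mm."""
    check_geometry_match(pred, ref)
    if not pred.data.any() or not ref.data.any():
        raise ValueError("surface distance undefined for an empty mask")
    sp = _surface_points_mm(pred)
    sr = _surface_points_mm(ref)
    d_pr = cKDTree(sr).query(sp, k=1)[0]
    d_rp = cKDTree(sp).query(sr, k=1)[0]
    hd = float(max(d_pr.max(), d_rp.max()))
    assd = float(np.concatenate([d_pr, d_rp]).mean())
    return hd, assd


def evaluate_segmentation(pred: BinaryMask, ref: BinaryMask) -> SegMetricsResult:
    """All four metrics between a predicted and a reference mask."""
    dsc, jc = overlap_metrics(pred, ref)
    hd, assd = surface_metrics(pred, ref)
    return SegMetricsResult(dsc=dsc, jc=jc, hd_mm=hd, assd_mm=assd)
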