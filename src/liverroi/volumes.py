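"""NIfTI volume I/O, orientation canonicalization, resampling, and mask postprocessing.

The measurement pipeline assumes a canonical in-memory layout: axis 0
increases toward the patient's left, axis 1 toward posterior, axis 2 toward
superior ("LPS" index order). Under this convention an axial slice is
``data[:, :, z]`` and the "leftmost pixel of the liver edge" is the minimum
index along axis 0 (the lateral margin of the right hepatic lobe under the
radiological display convention).

Voxels are point samples at their centers; all physical distances are
computed between voxel centers using the per-axis spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

CANONICAL_AXCODES = ("L", "P", "S")

# anatomical code -> (RAS world axis, sign of increasing index)
_CODE_TO_WORLD = {
    "R": (0, 1.0), "L": (0, -1.0),
    "A": (1, 1.0), "P": (1, -1.0),
    "S": (2, 1.0), "I": (2, -1.0),
}
_OPPOSITE = {"R": "L", "L": "R", "A": "P", "P": "A", "S": "I", "I": "S"}


@dataclass
class CTVolume:
    """3D scalar grid in Hounsfield units with voxel spacing and orientation."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: tuple[str, str, str] = CANONICAL_AXCODES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim} dimensions")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        self.orientation = tuple(self.orientation)
        _validate_axcodes(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """Boolean grid sharing a CTVolume's geometry (a liver segmentation)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: tuple[str, str, str] = CANONICAL_AXCODES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {self.data.ndim} dimensions")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        self.orientation = tuple(self.orientation)
        _validate_axcodes(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _validate_axcodes(axcodes: tuple[str, str, str]) -> None:
    if len(axcodes) != 3 or any(c not in _CODE_TO_WORLD for c in axcodes):
        raise ValueError(f"unrecognized orientation codes {axcodes!r}")
    world = sorted(_CODE_TO_WORLD[c][0] for c in axcodes)
    if world != [0, 1, 2]:
        raise ValueError(f"orientation codes {axcodes!r} do not span three anatomical axes")


def check_geometry_match(a: CTVolume | BinaryMask, b: CTVolume | BinaryMask) -> None:
    """Raise if two grids differ in shape, spacing, or orientation."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.spacing_mm, b.spacing_mm, rtol=1e-5, atol=1e-5):
        raise ValueError(f"spacing mismatch: {a.spacing_mm} vs {b.spacing_mm}")
    if a.orientation != b.orientation:
        raise ValueError(f"orientation mismatch: {a.orientation} vs {b.orientation}")


# ---------------------------------------------------------------------------
# I/O


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D single-channel volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or not np.isfinite(affine).all() or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: missing or degenerate affine")
    axcodes = nib.aff2axcodes(affine)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, axcodes


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume (HU) from NIfTI; spacing/orientation decoded from the header."""
    data, spacing, axcodes = _load_nifti(path)
    return CTVolume(np.asarray(data, dtype=np.float32), spacing, axcodes)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a segmentation from NIfTI and binarize it (values > 0.5 are foreground)."""
    data, spacing, axcodes = _load_nifti(path)
    return BinaryMask(np.asarray(data, dtype=np.float32) > 0.5, spacing, axcodes)


def _affine_from_geometry(spacing: tuple, axcodes: tuple) -> np.ndarray:
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for i, code in enumerate(axcodes):
        world, sign = _CODE_TO_WORLD[code]
        affine[world, i] = sign * spacing[i]
    return affine


def write_volume(vol: CTVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 (masks as uint8)."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = _affine_from_geometry(vol.spacing_mm, vol.orientation)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Canonicalization


def canonicalize(vol):
    """Permute/flip axes to the canonical LPS index order; voxel values unchanged.

    Idempotent: an already-canonical grid is returned unchanged (same data).
    """
    axcodes = vol.orientation
    if tuple(axcodes) == CANONICAL_AXCODES:
        return vol
    perm = []
    flips = []
    for target in CANONICAL_AXCODES:
        for i, code in enumerate(axcodes):
            if code == target or code == _OPPOSITE[target]:
                perm.append(i)
                flips.append(code != target)
                break
        else:  # pragma: no cover - excluded by axcode validation
            raise ValueError(f"unrecognized orientation {axcodes!r}")
    data = np.transpose(vol.data, perm)
    for ax, flip in enumerate(flips):
        if flip:
            data = np.flip(data, axis=ax)
    spacing = tuple(vol.spacing_mm[i] for i in perm)
    return replace(vol, data=np.ascontiguousarray(data), spacing_mm=spacing,
                   orientation=CANONICAL_AXCODES)


# ---------------------------------------------------------------------------
# Resampling


def resample(vol, target_spacing_mm: tuple[float, float, float] = (0.7, 0.7, 2.5)):
    """Resample to a target spacing, aligning grids at the first-voxel center.

    CT volumes use trilinear interpolation; masks use nearest-neighbor and
    are re-binarized. Output shape is ``round(n * spacing / target)`` per
    axis (at least 1), preserving physical extent within one voxel.
    """
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    spacing = vol.spacing_mm
    if np.allclose(spacing, target, rtol=0, atol=1e-9):
        return vol
    is_mask = isinstance(vol, BinaryMask)
    shape = vol.data.shape
    new_shape = tuple(max(1, int(round(n * s / t))) for n, s, t in zip(shape, spacing, target))
    axes = [np.arange(m) * (t / s) for m, s, t in zip(new_shape, spacing, target)]
    coords = np.meshgrid(*axes, indexing="ij")
    src = vol.data.astype(np.uint8) if is_mask else np.asarray(vol.data, dtype=np.float64)
    out = ndimage.map_coordinates(src, np.stack(coords), order=0 if is_mask else 1,
                                  mode="nearest")
    if is_mask:
        return replace(vol, data=out.astype(bool), spacing_mm=target)
    return replace(vol, data=out.astype(np.float32), spacing_mm=target)


# ---------------------------------------------------------------------------
# Mask postprocessing

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected component of the mask.

    Ties are broken toward the component containing the smallest flattened
    (C-order) raster index, so the result is deterministic.
    """
    if not mask.data.any():
        raise ValueError("empty segmentation")
    labels, n = ndimage.label(mask.data, structure=_CONN26)
    if n == 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        flat = labels.ravel()
        # first occurrence in raster order decides the tie
        first = {lab: np.argmax(flat == lab) for lab in best}
        keep = min(best, key=lambda lab: first[lab])
    else:
        keep = best[0]
    return replace(mask, data=labels == keep)


def slice_area_profile(mask: BinaryMask) -> list[tuple[int, float]]:
    """Per-axial-slice in-plane mask area in mm² (canonical orientation).

    Returns one ``(slice_index, area_mm2)`` entry per slice intersecting the
    mask; an empty mask yields an empty list.
    """
    if mask.orientation != CANONICAL_AXCODES:
        raise ValueError("slice_area_profile requires canonical orientation")
    pixel_area = mask.spacing_mm[0] * mask.spacing_mm[1]
    counts = mask.data.sum(axis=(0, 1))
    return [(int(z), float(c * pixel_area)) for z, c in enumerate(counts) if c > 0]
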