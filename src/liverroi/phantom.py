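"""Synthetic chest-CT liver phantoms with known ground truth.

The phantom is an ellipsoidal liver compartment embedded in uniform soft
tissue. Parenchyma voxels draw from Normal(mu, sd); vessels are straight
cylinders along randomized interior chords, offset by a fixed HU delta —
the simplest structure reproducing the heterogeneity (hepatic veins, bile
ducts) a manual measurement protocol avoids. With ``vessel_placement =
"central"`` the vessel tree keeps a configurable clearance from the liver's
leftmost margin so that automatically placed parenchymal ROIs are
vessel-free by construction.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, CTVolume, write_volume

_AXIS_NAMES = ("left-right (axis 0)", "anterior-posterior (axis 1)", "cranio-caudal (axis 2)")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic liver phantom.

    Defaults emulate the unenhanced-chest-CT regime the measurement stack
    targets: a ~56 HU parenchyma (the normal-liver cohort regime) with
    10 HU Gaussian noise on the canonical 0.7 x 0.7 x 2.5 mm grid, and 5%
    of the liver occupied by vessels +45 HU above parenchyma.
    """

    grid_shape: tuple[int, int, int] = (160, 192, 56)
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 2.5)
    liver_center_mm: tuple[float, float, float] | None = None  # default: grid center
    liver_semiaxes_mm: tuple[float, float, float] = (45.0, 55.0, 55.0)
    parenchyma_mu_hu: float = 56.0
    noise_sd_hu: float = 10.0
    vessel_delta_hu: float = 45.0
    vessel_fraction: float = 0.05
    vessel_radius_mm: float = 2.5
    vessel_placement: str = "central"
    vessel_clearance_mm: float = 30.0
    background_hu: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.vessel_fraction <= 0.3):
            raise ValueError(f"vessel_fraction must be in [0, 0.3], got {self.vessel_fraction}")
        if self.noise_sd_hu < 0:
            raise ValueError(f"noise_sd_hu must be >= 0, got {self.noise_sd_hu}")
        if any(a <= 0 for a in self.liver_semiaxes_mm):
            raise ValueError(f"semiaxes must be positive, got {self.liver_semiaxes_mm}")
        if self.vessel_placement not in ("central", "uniform"):
            raise ValueError(f"vessel_placement must be 'central' or 'uniform', got {self.vessel_placement!r}")

    @property
    def center_mm(self) -> tuple[float, float, float]:
        if self.liver_center_mm is not None:
            return tuple(float(c) for c in self.liver_center_mm)
        return tuple((n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    parenchyma_mean_hu: float
    realized_vessel_fraction: float
    liver_mask: BinaryMask
    vessel_mask: BinaryMask


def _physical_axes(spec: PhantomSpec) -> list[np.ndarray]:
    return [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    center = spec.center_mm
    for ax, (c, a, n, s) in enumerate(
        zip(center, spec.liver_semiaxes_mm, spec.grid_shape, spec.spacing_mm)
    ):
        if c - a < 0 or c + a > (n - 1) * s:
            raise ValueError(
                f"liver ellipsoid extends beyond the grid along the {_AXIS_NAMES[ax]} axis"
            )
    axes = _physical_axes(spec)
    u0 = ((axes[0] - center[0]) / spec.liver_semiaxes_mm[0]) ** 2
    u1 = ((axes[1] - center[1]) / spec.liver_semiaxes_mm[1]) ** 2
    u2 = ((axes[2] - center[2]) / spec.liver_semiaxes_mm[2]) ** 2
    return (u0[:, None, None] + u1[None, :, None] + u2[None, None, :]) <= 1.0


def _sample_interior_point(rng: np.random.Generator, spec: PhantomSpec,
                           x_min_mm: float | None) -> np.ndarray:
    """Rejection-sample a point inside the 0.85-scaled liver ellipsoid."""
    center = np.array(spec.center_mm)
    semi = 0.85 * np.array(spec.liver_semiaxes_mm)
    for _ in range(10000):
        p = center + semi * rng.uniform(-1.0, 1.0, size=3)
        if np.sum(((p - center) / semi) ** 2) <= 1.0 and (x_min_mm is None or p[0] >= x_min_mm):
            return p
    raise RuntimeError("could not sample a vessel endpoint inside the liver; "
                       "vessel clearance leaves no admissible central region")


def _rasterize_vessels(rng: np.random.Generator, spec: PhantomSpec,
                       liver: np.ndarray) -> np.ndarray:
    """Add cylinders until the vessel compartment holds exactly the target voxel count."""
    n_liver = int(liver.sum())
    target = int(round(spec.vessel_fraction * n_liver))
    vessels = np.zeros_like(liver)
    if target == 0:
        return vessels
    x_min_mm = None
    if spec.vessel_placement == "central":
        leftmost_mm = np.flatnonzero(liver.any(axis=(1, 2)))[0] * spec.spacing_mm[0]
        x_min_mm = leftmost_mm + spec.vessel_clearance_mm + spec.vessel_radius_mm
    axes = _physical_axes(spec)
    r = spec.vessel_radius_mm
    count = 0
    for _ in range(10000):
        if count >= target:
            break
        p0 = _sample_interior_point(rng, spec, x_min_mm)
        p1 = _sample_interior_point(rng, spec, x_min_mm)
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        if seg_len2 < 1e-6:
            continue
        lo = np.minimum(p0, p1) - r
        hi = np.maximum(p0, p1) + r
        sl = tuple(
            slice(int(np.searchsorted(ax, l)), int(np.searchsorted(ax, h, side="right")))
            for ax, l, h in zip(axes, lo, hi)
        )
        if any(s.start >= s.stop for s in sl):
            continue
        grid = np.meshgrid(*(ax[s] for ax, s in zip(axes, sl)), indexing="ij")
        pts = np.stack(grid, axis=-1)
        t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
        closest = p0 + t[..., None] * seg
        inside = np.sum((pts - closest) ** 2, axis=-1) <= r * r
        new = inside & liver[sl] & ~vessels[sl]
        if x_min_mm is not None:
            new &= grid[0] >= leftmost_mm + spec.vessel_clearance_mm
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if count + n_new > target:
            # trim the cylinder tail (largest axial parameter t) for an exact count
            excess = count + n_new - target
            t_new = t[new]
            order = np.argsort(t_new, kind="stable")
            keep_flat = np.zeros(n_new, dtype=bool)
            keep_flat[order[: n_new - excess]] = True
            idx = np.nonzero(new)
            trimmed = np.zeros_like(new)
            trimmed[idx[0][keep_flat], idx[1][keep_flat], idx[2][keep_flat]] = True
            new = trimmed
            n_new = target - count
        vessels[sl] |= new
        count += n_new
    if count < target:
        raise RuntimeError(f"vessel rasterization stalled at {count}/{target} voxels")
    return vessels


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate a phantom CT volume and its ground-truth record.

    The CT grid equals ``background_hu`` outside the liver; parenchyma
    voxels draw from Normal(mu, sd) and vessel voxels from
    Normal(mu + delta, sd). Output is bit-identical for equal specs.
    """
    rng = np.random.default_rng(spec.seed)
    liver = _ellipsoid_mask(spec)
    vessels = _rasterize_vessels(rng, spec, liver)
    ct = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    n_liver = int(liver.sum())
    values = spec.parenchyma_mu_hu + spec.noise_sd_hu * rng.standard_normal(n_liver)
    ct[liver] = values
    ct[vessels] += spec.vessel_delta_hu
    truth = PhantomTruth(
        parenchyma_mean_hu=float(spec.parenchyma_mu_hu),
        realized_vessel_fraction=float(vessels.sum() / n_liver),
        liver_mask=BinaryMask(liver, spec.spacing_mm),
        vessel_mask=BinaryMask(vessels, spec.spacing_mm),
    )
    return CTVolume(ct.astype(np.float32), spec.spacing_mm), truth


# ---------------------------------------------------------------------------
# Mask perturbation fixtures

_CONN6 = ndimage.generate_binary_structure(3, 1)


def perturb_mask(mask: BinaryMask, mode: str, magnitude: int, seed: int = 0) -> BinaryMask:
    """Produce a controlled degradation of a mask for metric testing.

    Modes: ``dilate`` / ``erode`` (morphology, ``magnitude`` iterations of
    the 6-connected structuring element), ``shift`` (rigid translation by
    ``magnitude`` voxels along a seed-chosen axis, zero fill), and
    ``drop_component`` (adds a spurious blob of roughly ``magnitude`` voxels
    per side disconnected from the mask, so largest-component filtering has
    something to remove).
    """
    if not mask.data.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    data = mask.data
    if magnitude == 0 and mode != "drop_component":
        out = data.copy()
    elif mode == "dilate":
        out = ndimage.binary_dilation(data, structure=_CONN6, iterations=magnitude)
    elif mode == "erode":
        out = ndimage.binary_erosion(data, structure=_CONN6, iterations=magnitude)
    elif mode == "shift":
        axis = int(rng.integers(0, 3))
        sign = 1 if rng.integers(0, 2) else -1
        shift = [0, 0, 0]
        shift[axis] = sign * magnitude
        out = ndimage.shift(data.astype(np.uint8), shift, order=0, cval=0).astype(bool)
    elif mode == "drop_component":
        out = _add_spurious_blob(data, max(1, magnitude), rng)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    if not out.any():
        raise ValueError(f"perturbation mode={mode} magnitude={magnitude} emptied the mask")
    return BinaryMask(out, mask.spacing_mm, mask.orientation)


def _add_spurious_blob(data: np.ndarray, side: int, rng: np.random.Generator) -> np.ndarray:
    forbidden = ndimage.binary_dilation(data, structure=np.ones((3, 3, 3), dtype=bool))
    shape = data.shape
    for _ in range(1000):
        corner = [int(rng.integers(0, max(1, n - side))) for n in shape]
        sl = tuple(slice(c, min(c + side, n)) for c, n in zip(corner, shape))
        if not forbidden[sl].any():
            out = data.copy()
            out[sl] = True
            return out
    raise RuntimeError("no room for a spurious component disconnected from the mask")


# ---------------------------------------------------------------------------
# Serialization


def save_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Generate a phantom and write CT + masks as NIfTI with a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, truth = generate_phantom(spec)
    write_volume(ct, out / "ct.nii.gz")
    write_volume(truth.liver_mask, out / "liver_mask.nii.gz")
    write_volume(truth.vessel_mask, out / "vessel_mask.nii.gz")
    record = {
        "spec": asdict(spec),
        "parenchyma_mean_hu": truth.parenchyma_mean_hu,
        "realized_vessel_fraction": truth.realized_vessel_fraction,
        "liver_voxels": int(truth.liver_mask.data.sum()),
        "vessel_voxels": int(truth.vessel_mask.data.sum()),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(record, fh, indent=2)
    return record
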