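"""End-to-end case processing: preprocess -> measure -> classify.

The liver segmentation is an input (produced upstream by any segmentation
model); preprocessing canonicalizes orientation, optionally resamples both
grids to the target spacing, and keeps the largest connected component of
the mask. All three attenuation estimators run on the preprocessed pair
and the parenchymal value drives the steatosis category.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import attenuation as att
from . import volumes
from .config import PipelineConfig

log = logging.getLogger("liverroi")


def preprocess_pair(ct, mask, config: PipelineConfig):
    """Canonicalize, resample to the target grid, keep the largest mask component."""
    ct = volumes.canonicalize(ct)
    mask = volumes.canonicalize(mask)
    if config.resample:
        ct = volumes.resample(ct, config.target_spacing_mm)
        mask = volumes.resample(mask, config.target_spacing_mm)
    mask = volumes.largest_component(mask)
    return ct, mask


def run_case(ct_path, mask_path, config: PipelineConfig | None = None,
             case_id: str | None = None) -> dict:
    """Process one CT/mask pair into a JSON-serializable case report."""
    config = config or PipelineConfig()
    case_id = case_id or Path(ct_path).name.split(".")[0]
    t0 = time.perf_counter()
    stage = "read"
    try:
        ct = volumes.read_volume(ct_path)
        mask = volumes.read_mask(mask_path)
        stage = "preprocess"
        ct, mask = preprocess_pair(ct, mask, config)
        stage = "measure"
        vol = att.measure_volumetric(ct, mask)
        axial = att.measure_axial(ct, mask)
        paren = att.measure_parenchymal(ct, mask, config.roi)
        stage = "classify"
        category = att.classify_steatosis(paren.value_hu, config.threshold_hu)
    except Exception as exc:
        raise RuntimeError(f"case {case_id}: stage '{stage}' failed: {exc}") from exc
    report = {
        "case_id": case_id,
        "volumetric_hu": round(vol.value_hu, 4),
        "axial_hu": round(axial.value_hu, 4),
        "axial_slice_index": axial.slice_index,
        "parenchymal_hu": round(paren.value_hu, 4),
        "threshold_hu": config.threshold_hu,
        "category": category,
        "rois": [
            {
                "slice_index": p.slice_index,
                "center": [int(p.center[0]), int(p.center[1])],
                "radius_mm": round(p.radius_mm, 4),
                "n_pixels": int(len(p.member_pixels)),
                "in_mask_fraction": round(p.in_mask_fraction, 4),
                "mean_hu": round(p.mean_hu, 4),
            }
            for p in paren.rois
        ],
        "warnings": list(paren.warnings),
    }
    log.info("case=%s stage=done duration=%.2fs warnings=%d",
             case_id, time.perf_counter() - t0, len(paren.warnings))
    return report


def run_batch(pairs: list[tuple[str, str, str]], config: PipelineConfig | None = None) -> pd.DataFrame:
    """Process (case_id, ct_path, mask_path) tuples into a per-case table."""
    rows = []
    for case_id, ct_path, mask_path in pairs:
        rep = run_case(ct_path, mask_path, config, case_id=case_id)
        rows.append({
            "id": rep["case_id"],
            "volumetric_hu": rep["volumetric_hu"],
            "axial_hu": rep["axial_hu"],
            "parenchymal_hu": rep["parenchymal_hu"],
            "category": rep["category"],
        })
    return pd.DataFrame(rows, columns=["id", "volumetric_hu", "axial_hu", "parenchymal_hu", "category"])
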