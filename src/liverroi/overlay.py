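"""Visual QC: render ROI placements on their axial slices as PNG."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .attenuation import ROIPlacement
from .volumes import CTVolume


def save_roi_overlay(ct: CTVolume, rois: list[ROIPlacement], path: str | Path,
                     window: tuple[float, float] = (-20.0, 120.0)) -> None:
    """One panel per ROI-bearing slice, circle drawn at the placed ROI.

    Slices are shown transposed so the vertical axis is anterior-posterior
    and the horizontal axis is the left-right axis, with a soft-tissue
    display window (default -20..120 HU).
    """
    if not rois:
        raise ValueError("no ROIs to draw")
    s0, s1, _ = ct.spacing_mm
    fig, axes = plt.subplots(1, len(rois), figsize=(4 * len(rois), 4))
    if len(rois) == 1:
        axes = [axes]
    for ax, roi in zip(axes, rois):
        img = ct.data[:, :, roi.slice_index].T
        ax.imshow(img, cmap="gray", vmin=window[0], vmax=window[1], origin="lower",
                  aspect=s1 / s0)
        ax.add_patch(Circle((roi.center[0], roi.center[1] * 1.0), roi.radius_mm / s0,
                            fill=False, color="tab:red", linewidth=1.5))
        label = f"z={roi.slice_index}"
        if roi.mean_hu is not None:
            label += f"  {roi.mean_hu:.1f} HU"
        ax.set_title(label, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
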