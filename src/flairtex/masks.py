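"""WMH segmentation, NAWM construction and lesion-volume summaries.

White matter hyperintensities are seeded by a relative intensity threshold:
a voxel is lesional when its (bias-corrected) intensity exceeds ``k`` times
the median over in-brain non-zero voxels, with k = 1.2 by default, and the
candidate set is intersected with the white matter mask so that bright
grey-matter or CSF partial-volume voxels cannot leak in.

Normal-appearing white matter is WM minus WMH, eroded per axial slice with
a 2x2 square structuring element to trim partial-volume rims.  A 2x2 kernel
has no centre element; the anchor here is fixed at its top-left element, so
a voxel v survives erosion iff v, v+(1,0), v+(0,1) and v+(1,1) are all set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, MaskVolume, check_aligned

__all__ = ["VolumeSummary", "segment_wmh", "build_nawm", "erode_2x2",
           "summarize_volumes"]


def segment_wmh(img: ImageVolume, brain: MaskVolume, wm: MaskVolume,
                k: float = 1.2, min_size_voxels: int = 1) -> MaskVolume:
    """Threshold-based WMH seed segmentation at k x median intensity.

    Parameters
    ----------
    img : bias-corrected FLAIR volume (background exactly zero).
    brain, wm : aligned binary masks.
    k : relative threshold; 1.2 is the standard choice.
    min_size_voxels : connected components (26-connectivity, 3D) smaller
        than this are dropped; the default of 1 disables the filter.
    """
    if k <= 0:
        raise ValueError(f"threshold factor k must be positive, got {k}")
    check_aligned(img, brain, "image", "brain mask")
    check_aligned(img, wm, "image", "wm mask")
    if not brain.data.any():
        raise ValueError("brain mask is empty")
    if not wm.data.any():
        raise ValueError("wm mask is empty")
    inb = brain.data & (img.data != 0)
    med = np.median(img.data[inb])
    wmh = (img.data > k * med) & wm.data
    if min_size_voxels > 1 and wmh.any():
        lab, n = ndimage.label(wmh, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_size_voxels
        keep[0] = False
        wmh = keep[lab]
    return MaskVolume(wmh, "wmh", img.voxel_size_mm, img.affine.copy())


def erode_2x2(mask2d: np.ndarray) -> np.ndarray:
    """2x2 square erosion of a 2D mask, anchored at the top-left element."""
    out = np.zeros_like(mask2d, dtype=bool)
    out[:-1, :-1] = (mask2d[:-1, :-1] & mask2d[1:, :-1]
                     & mask2d[:-1, 1:] & mask2d[1:, 1:])
    return out


def build_nawm(wm: MaskVolume, wmh: MaskVolume) -> MaskVolume:
    """NAWM = per-axial-slice 2x2 erosion of (WM minus WMH)."""
    check_aligned(wm, wmh, "wm mask", "wmh mask")
    base = wm.data & ~wmh.data
    out = np.zeros_like(base)
    for z in range(base.shape[2]):
        out[:, :, z] = erode_2x2(base[:, :, z])
    return MaskVolume(out, "nawm", wm.voxel_size_mm, wm.affine.copy())


@dataclasses.dataclass
class VolumeSummary:
    """Lesion load normalized by head size.

    ``wmh_pct_etiv`` is 100 * WMH volume / eTIV; its cube root is the
    skew-reduced quantity the statistical models use.
    """

    wmh_volume_mm3: float
    etiv_mm3: float
    wmh_pct_etiv: float
    wmh_pct_etiv_cuberoot: float


def summarize_volumes(wmh: MaskVolume, etiv_mm3: float) -> VolumeSummary:
    if etiv_mm3 <= 0:
        raise ValueError(f"eTIV must be positive, got {etiv_mm3}")
    vol = wmh.volume_mm3
    pct = 100.0 * vol / etiv_mm3
    return VolumeSummary(vol, float(etiv_mm3), pct, float(np.cbrt(pct)))
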