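"""Bias-field estimation and intensity normalization for FLAIR volumes.

The multiplicative bias (shading) field of an MR image is modelled here as
the exponential of a low-order 3D polynomial fitted by least squares to
log-intensities inside a homogeneous-tissue fit mask (white matter in this
pipeline, with lesion voxels robustly trimmed).  This corrects smooth
polynomial shading exactly (up to the fitted degree) and is the bias class
emulated by the synthetic generator; users with scanner data corrected by
an external tool can simply skip this stage.

First-order features downstream are computed on min-max normalized
intensities: the minimum over non-zero (foreground) voxels is subtracted and
the result divided by the range of non-zero values, so foreground lands in
[0, 1] while the exactly-zero background stays zero.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np

from .volumes import ImageVolume, MaskVolume, check_aligned

logger = logging.getLogger(__name__)

__all__ = ["BiasField", "estimate_bias_field", "correct_bias",
           "normalize_intensities"]


@dataclasses.dataclass
class BiasField:
    """A strictly positive multiplicative shading field on the image grid."""

    data: np.ndarray
    degree: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if (self.data <= 0).any():
            raise ValueError("bias field must be strictly positive")


def _poly_design(shape: tuple[int, int, int], degree: int,
                 where: np.ndarray) -> np.ndarray:
    """Monomial design matrix (total degree <= degree) on [-1, 1]^3 coords."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    cols = []
    for px, py, pz in itertools.product(range(degree + 1), repeat=3):
        if px + py + pz <= degree:
            cols.append((xx**px * yy**py * zz**pz)[where])
    return np.column_stack(cols)


def estimate_bias_field(img: ImageVolume, fit_mask: MaskVolume,
                        degree: int = 2, trim_mad: float = 3.5) -> BiasField:
    """Fit exp(polynomial) shading to log-intensities inside ``fit_mask``.

    ``fit_mask`` should delineate a nominally homogeneous tissue class
    (white matter in this pipeline): within such a region the log-intensity
    is log(tissue mean) + log(bias) + noise, so a low-order polynomial fit
    recovers the shading without absorbing anatomy.  Fitting over the whole
    brain would let the polynomial track the CSF/GM/WM contrast itself.
    Voxels whose log-intensity sits more than ``trim_mad`` median absolute
    deviations from the mask median (e.g. hyperintense lesions inside WM)
    are trimmed from the fit; non-positive voxels are excluded with a
    logged count.

    The returned field has mean 1 over the fit mask, so division by it
    preserves the overall intensity scale.
    """
    if degree < 1:
        raise ValueError(f"bias polynomial degree must be >= 1, got {degree}")
    check_aligned(img, fit_mask, "image", "fit mask")
    inb = fit_mask.data
    if not inb.any():
        raise ValueError("bias fit mask is empty")
    pos = inb & (img.data > 0)
    n_excluded = int(inb.sum() - pos.sum())
    if n_excluded:
        logger.info("bias fit: excluded %d non-positive voxels", n_excluded)
    if not pos.any():
        raise ValueError("no positive intensities in bias fit mask")
    if trim_mad > 0:
        logv = np.log(img.data[pos])
        med = np.median(logv)
        mad = np.median(np.abs(logv - med))
        if mad > 0:
            keep = np.abs(logv - med) <= trim_mad * 1.4826 * mad
            idx = np.argwhere(pos)
            drop = idx[~keep]
            pos = pos.copy()
            pos[drop[:, 0], drop[:, 1], drop[:, 2]] = False

    A = _poly_design(img.data.shape, degree, pos)
    coef, *_ = np.linalg.lstsq(A, np.log(img.data[pos]), rcond=None)

    full = np.ones(img.data.shape, dtype=bool)
    log_field = (_poly_design(img.data.shape, degree, full) @ coef
                 ).reshape(img.data.shape)
    field = np.exp(log_field - log_field[pos].max())  # guard overflow
    field /= field[inb].mean()
    return BiasField(field, degree)


def correct_bias(img: ImageVolume, field: BiasField) -> ImageVolume:
    """Divide the image by the shading field; background zeros stay zero."""
    out = img.data / field.data
    out[img.data == 0] = 0.0
    return img.copy_with(out)


def normalize_intensities(img: ImageVolume,
                          mask: MaskVolume | None = None) -> ImageVolume:
    """Min-max normalize foreground intensities into [0, 1].

    Foreground is the set of non-zero voxels (the skull-stripped brain),
    unless an explicit mask is supplied.  The minimum over foreground maps
    to 0 and the range of foreground values divides; background stays 0.
    """
    if mask is not None:
        check_aligned(img, mask, "image", "mask")
        fg = mask.data
    else:
        fg = img.data != 0
    vals = img.data[fg]
    if vals.size < 2:
        raise ValueError("fewer than 2 foreground voxels")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("zero intensity range: constant foreground")
    out = np.zeros_like(img.data)
    out[fg] = (img.data[fg] - lo) / (hi - lo)
    return img.copy_with(out)
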