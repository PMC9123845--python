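"""Voxel-wise GLCM texture maps and first/second-order feature extraction.

The method: quantize the whole skull-stripped volume to N grey levels
(default 8) with one global set of equal-width bins, then, for every voxel,
build a grey-level co-occurrence matrix from its 3x3 in-plane (axial)
neighbourhood by counting ordered level pairs at distance one in all eight
directions, sum the eight directional tables, normalize, and evaluate four
Haralick statistics:

    contrast    = sum p(i,j) (i-j)^2
    energy      = sum p(i,j)^2
    entropy     = -sum p(i,j) ln p(i,j)        (0 ln 0 := 0)
    homogeneity = sum p(i,j) / (1 + |i-j|)

This yields four texture *maps* aligned with the source grid, so regions of
interest are applied after texture computation — the quantization (and hence
the level scale) never depends on the ROI.  Pairs involving background
(level 0) voxels are excluded: zeros outside the brain are padding, not a
grey level.  Voxels whose 3x3 in-plane neighbourhood leaves the grid, or
whose patch contains no valid pair, are flagged invalid rather than given a
value.

Quantization convention: N equal-width bins over [min, max] of in-brain
intensities; a value at a bin edge goes to the upper bin and the maximum is
clamped into bin N, so the in-brain minimum maps to level 1 and the maximum
to level N.  Because binning uses the global in-brain min/max, every feature
is invariant to increasing affine rescaling of the intensities.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple

import numpy as np

from .volumes import ImageVolume, MaskVolume, check_aligned

logger = logging.getLogger(__name__)

__all__ = ["QuantizedVolume", "GLCM", "TextureMaps", "HaralickFeatures",
           "DIRECTIONS", "quantize", "patch_glcm", "haralick_features",
           "make_texture_maps", "extract_roi_features", "transform_features",
           "TEXTURE_FEATURES", "FIRST_ORDER_FEATURES", "SECOND_ORDER_FEATURES"]

#: the eight in-plane unit offsets (E, W, S, N and the four diagonals)
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1))

FIRST_ORDER_FEATURES = ("mean", "std")
SECOND_ORDER_FEATURES = ("contrast", "energy", "entropy", "homog")
TEXTURE_FEATURES = FIRST_ORDER_FEATURES + SECOND_ORDER_FEATURES


@dataclasses.dataclass
class QuantizedVolume:
    """Integer grey-level volume: in-brain voxels in 1..n_levels, else 0."""

    data: np.ndarray
    n_levels: int
    voxel_size_mm: tuple[float, float, float] = (0.43, 0.43, 4.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("quantized volume must be 3D")
        if self.data.min() < 0 or self.data.max() > self.n_levels:
            raise ValueError("quantized values must lie in 0..n_levels")
        if self.affine is None:
            vs = self.voxel_size_mm
            self.affine = np.diag([vs[0], vs[1], vs[2], 1.0])


@dataclasses.dataclass
class GLCM:
    """An N x N co-occurrence table; symmetric when all 8 directions sum."""

    table: np.ndarray
    normalized: bool = False

    def normalize(self) -> "GLCM":
        s = self.table.sum()
        if s <= 0:
            raise ValueError("cannot normalize an empty GLCM")
        return GLCM(self.table / s, True)


class HaralickFeatures(NamedTuple):
    contrast: float
    energy: float
    entropy: float
    homogeneity: float


@dataclasses.dataclass
class TextureMaps:
    """Per-voxel Haralick feature volumes sharing the source grid.

    ``valid`` marks voxels with a full in-plane 3x3 neighbourhood containing
    at least one foreground co-occurrence pair; the feature maps hold NaN
    wherever invalid.
    """

    contrast: np.ndarray
    energy: np.ndarray
    entropy: np.ndarray
    homogeneity: np.ndarray
    valid: np.ndarray
    n_levels: int
    voxel_size_mm: tuple[float, float, float] = (0.43, 0.43, 4.0)
    affine: np.ndarray | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"contrast": self.contrast, "energy": self.energy,
                "entropy": self.entropy, "homog": self.homogeneity}


def quantize(img: ImageVolume, brain: MaskVolume, n_levels: int = 8
             ) -> QuantizedVolume:
    """Global equal-width quantization of in-brain intensities to 1..N."""
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    check_aligned(img, brain, "image", "brain mask")
    inb = brain.data
    if not inb.any():
        raise ValueError("brain mask is empty")
    vals = img.data[inb]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("constant in-brain intensity: cannot quantize")
    q = np.zeros(img.data.shape, dtype=np.int64)
    bins = np.floor((img.data[inb] - lo) / (hi - lo) * n_levels).astype(np.int64)
    q[inb] = np.clip(bins, 0, n_levels - 1) + 1
    return QuantizedVolume(q, n_levels, img.voxel_size_mm, img.affine.copy())


def patch_glcm(q: QuantizedVolume, center: tuple[int, int, int],
               directions: tuple[tuple[int, int], ...] = DIRECTIONS,
               normalize: bool = True) -> GLCM:
    """GLCM of the 3x3 axial patch centred at ``center``.

    For each direction offset, every ordered pair (a, a+d) with both members
    inside the patch and both foreground (level > 0) contributes one count.
    """
    x, y, z = center
    nx, ny, nz = q.data.shape
    if not (1 <= x <= nx - 2 and 1 <= y <= ny - 2 and 0 <= z <= nz - 1):
        raise ValueError(f"center {center} lacks a full in-plane 3x3 "
                         "neighbourhood")
    patch = q.data[x - 1:x + 2, y - 1:y + 2, z]
    n = q.n_levels
    counts = np.zeros((n, n), dtype=np.float64)
    for dx, dy in directions:
        for ax in range(3):
            for ay in range(3):
                bx, by = ax + dx, ay + dy
                if 0 <= bx < 3 and 0 <= by < 3:
                    la, lb = patch[ax, ay], patch[bx, by]
                    if la > 0 and lb > 0:
                        counts[la - 1, lb - 1] += 1
    g = GLCM(counts, False)
    if normalize and counts.sum() > 0:
        g = g.normalize()
    return g


def haralick_features(glcm: GLCM) -> HaralickFeatures:
    """Contrast, energy, entropy (natural log) and homogeneity of a GLCM."""
    if not glcm.normalized:
        raise ValueError("GLCM must be normalized before feature extraction")
    p = glcm.table
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("normalized GLCM entries must sum to 1")
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    w_contrast = ((i - j) ** 2).astype(np.float64)
    w_homog = 1.0 / (1.0 + np.abs(i - j))
    # reduction expressions mirror make_texture_maps exactly, so the
    # vectorized maps and this per-patch path agree bit-for-bit
    flat = p.reshape(1, -1)
    contrast = float((flat * w_contrast.ravel()).sum(axis=1)[0])
    energy = float((flat ** 2).sum(axis=1)[0])
    entropy = float(-np.sum(np.where(flat > 0,
                                     flat * np.log(np.where(flat > 0, flat,
                                                            1.0)),
                                     0.0), axis=1)[0])
    homogeneity = float((flat * w_homog.ravel()).sum(axis=1)[0])
    return HaralickFeatures(contrast, energy, entropy, homogeneity)


def _direction_spans(dx: int, dy: int):
    """Relative patch positions whose neighbour at (dx,dy) is also in-patch."""
    xs = [o for o in (-1, 0, 1) if -1 <= o + dx <= 1]
    ys = [o for o in (-1, 0, 1) if -1 <= o + dy <= 1]
    return [(ox, oy) for ox in xs for oy in ys]


def make_texture_maps(q: QuantizedVolume) -> TextureMaps:
    """Vectorized per-slice computation of the four voxel-wise feature maps.

    Equivalent by construction to calling :func:`patch_glcm` +
    :func:`haralick_features` at every voxel (the test-suite enforces exact
    agreement with that brute-force path).
    """
    nx, ny, nz = q.data.shape
    n = q.n_levels
    nn = n * n
    shape = (nx, ny, nz)
    maps = {k: np.full(shape, np.nan) for k in
            ("contrast", "energy", "entropy", "homog")}
    valid = np.zeros(shape, dtype=bool)

    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    w_contrast = ((i - j)**2).ravel().astype(np.float64)
    w_homog = (1.0 / (1.0 + np.abs(i - j))).ravel()

    XX, YY = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    interior = ((XX >= 1) & (XX <= nx - 2) & (YY >= 1) & (YY <= ny - 2))

    for z in range(nz):
        qs = q.data[:, :, z]
        hist = np.zeros((nx * ny, nn), dtype=np.float64)
        flat = hist.ravel()
        for dx, dy in DIRECTIONS:
            # pair-code image: code of (a, a+d) stored at a; -1 where invalid
            code = np.full((nx, ny), -1, dtype=np.int64)
            ax = slice(max(0, -dx), nx - max(0, dx))
            ay = slice(max(0, -dy), ny - max(0, dy))
            bx = slice(max(0, dx), nx + min(0, dx))
            by = slice(max(0, dy), ny + min(0, dy))
            a = qs[ax, ay]
            b = qs[bx, by]
            ok = (a > 0) & (b > 0)
            sub = np.where(ok, (a - 1) * n + (b - 1), -1)
            code[ax, ay] = sub
            # scatter each pair into every centre whose patch contains it
            for ox, oy in _direction_spans(dx, dy):
                vx = slice(max(0, -ox), nx - max(0, ox))
                vy = slice(max(0, -oy), ny - max(0, oy))
                sx = slice(max(0, ox), nx + min(0, ox))
                sy = slice(max(0, oy), ny + min(0, oy))
                shifted = code[sx, sy]
                m = shifted >= 0
                if not m.any():
                    continue
                centres = (XX[vx, vy][m] * ny + YY[vx, vy][m])
                np.add.at(flat, centres * nn + shifted[m], 1.0)

        total = hist.sum(axis=1).reshape(nx, ny)
        ok = interior & (total > 0)
        if not ok.any():
            continue
        idx = ok.ravel()
        p = hist[idx] / total.ravel()[idx, None]
        feats = {
            "contrast": (p * w_contrast).sum(axis=1),
            "energy": (p**2).sum(axis=1),
            "entropy": -np.sum(np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)),
                                        0.0), axis=1),
            "homog": (p * w_homog).sum(axis=1),
        }
        for k, v in feats.items():
            plane = np.full(nx * ny, np.nan)
            plane[idx] = v
            maps[k][:, :, z] = plane.reshape(nx, ny)
        valid[:, :, z] = ok

    return TextureMaps(maps["contrast"], maps["energy"], maps["entropy"],
                       maps["homog"], valid, n, q.voxel_size_mm,
                       None if q.affine is None else q.affine.copy())


def extract_roi_features(img_norm: ImageVolume, maps: TextureMaps,
                         roi: MaskVolume) -> dict[str, float]:
    """First- and second-order features of one ROI.

    mean/std come from the normalized intensity image over all ROI voxels
    (std with the unbiased n-1 estimator); the four Haralick features are
    means of the corresponding texture maps over ROI voxels flagged valid.
    An empty ROI yields NaNs (subjects without any lesion must flow through
    a cohort run), and a warning is logged when more than half of the ROI
    falls outside the valid map region.
    """
    check_aligned(img_norm, roi, "image", "roi")
    r = roi.data
    nvox = int(r.sum())
    out: dict[str, float] = {}
    if nvox == 0:
        logger.warning("empty ROI '%s': features set to NaN", roi.role)
        return {k: np.nan for k in TEXTURE_FEATURES}
    vals = img_norm.data[r]
    out["mean"] = float(vals.mean())
    if nvox >= 2:
        out["std"] = float(vals.std(ddof=1))
    else:
        logger.warning("single-voxel ROI '%s': std undefined", roi.role)
        out["std"] = np.nan
    rv = r & maps.valid
    n_valid = int(rv.sum())
    if n_valid == 0:
        logger.warning("ROI '%s' has no valid texture-map voxels", roi.role)
        for k in SECOND_ORDER_FEATURES:
            out[k] = np.nan
        return out
    dropped = 1.0 - n_valid / nvox
    if dropped > 0.5:
        logger.warning("ROI '%s': %.0f%% of voxels outside valid map region",
                       roi.role, 100 * dropped)
    for k, m in maps.as_dict().items():
        out[k] = float(m[rv].mean())
    return out


def transform_features(features: dict[str, float],
                       keep_raw: bool = True) -> dict[str, float]:
    """Signed cube-root transform of every textural measure (skew reduction).

    Returns a new dict with each value replaced by cbrt(value); raw values
    are retained under ``<name>_raw`` keys when ``keep_raw``.
    """
    out: dict[str, float] = {}
    for k, v in features.items():
        out[k] = float(np.cbrt(v))
        if keep_raw:
            out[f"{k}_raw"] = v
    return out
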