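"""Synthetic FLAIR-like phantoms and cohorts with planted effects.

The phantom is a skull-stripped axial FLAIR stand-in: nested ellipsoids
carve the brain into a central CSF compartment, a white-matter shell and a
cortical grey-matter rim, with FLAIR-like tissue means (CSF darkest,
lesions brightest).  Hyperintense WM lesions are spheres (in physical mm)
intersected with WM, given an intensity offset above WM plus an optional
spatially correlated heterogeneity field — the one knob that maps
monotonically onto within-lesion GLCM contrast/homogeneity.  A smooth
multiplicative polynomial bias field and additive Gaussian noise complete
the image; the background outside the brain is exactly zero.

The cohort generator draws per-subject covariates mirroring a midlife
observational sample (age ~52 +/- 5, ~70% female, education 16 +/- 3.4
years, CAIDE-like risk score, eTIV ~1485 +/- 150 cm^3), varies lesion
count/size/brightness/heterogeneity across subjects, and plants linear
covariate-texture-outcome effects: each ``(feature, outcome, slope)``
triple adds ``slope * (true feature - cohort mean)`` to the outcome, where
the true feature value is computed from the generated image and the
ground-truth masks on the cube-root-transformed scale used by the
downstream models.  All planted slopes and true feature values land in a
ground-truth sidecar table.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .layers import build_layers
from .masks import build_nawm
from .preprocessing import correct_bias, estimate_bias_field, \
    normalize_intensities
from .texture import (extract_roi_features, make_texture_maps, quantize,
                      transform_features)
from .volumes import ImageVolume, MaskVolume, write_image, write_mask

__all__ = ["PhantomSpec", "LesionSpec", "CohortSpec", "Subject",
           "CohortResult", "generate_phantom", "generate_cohort",
           "write_cohort"]

_LAYER_RE = re.compile(r"^layer(\d+)_(mean|std|contrast|energy|entropy|homog)$")
_ROI_RE = re.compile(r"^(WMHT|NAWMT)_(mean|std|contrast|energy|entropy|homog)$")
_OUTCOMES = ("reaction_time_ms", "risk_score")


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, tissue intensities and noise/bias model of one phantom.

    ``*_frac`` parameters are ellipsoid semi-axes as fractions of the grid
    half-extent per axis: CSF inside ``csf_frac``, WM between ``csf_frac``
    and ``wm_frac``, GM between ``wm_frac`` and ``brain_frac``.  With the
    defaults WM holds ~48% of brain voxels, so the in-brain median intensity
    is the WM mean and the relative WMH threshold separates lesions cleanly.
    ``bias_amplitude`` is the peak-to-trough multiplicative range of the
    shading field (0 disables it).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 27)
    voxel_size_mm: tuple[float, float, float] = (0.43, 0.43, 4.0)
    tissue_means: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"csf": 30.0, "gm": 120.0, "wm": 100.0})
    brain_frac: float = 0.92
    wm_frac: float = 0.80
    csf_frac: float = 0.52
    noise_sd: float = 2.0
    bias_amplitude: float = 0.1
    bias_order: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be strictly positive")
        if not 0 < self.csf_frac < self.wm_frac < self.brain_frac <= 1:
            raise ValueError("need 0 < csf_frac < wm_frac < brain_frac <= 1")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be >= 0")
        if self.bias_order < 1:
            raise ValueError("bias_order must be >= 1")


@dataclasses.dataclass
class LesionSpec:
    """Spherical hyperintense WM lesions with controllable heterogeneity.

    ``heterogeneity`` is the standard deviation (intensity units) of a
    spatially correlated Gaussian random field added inside lesions;
    ``correlation_length_mm`` sets the smoothing kernel width, hence the
    spatial grain the GLCM sees.  heterogeneity = 0 gives internally
    constant lesions (before bias/noise).
    """

    centers: list[tuple[int, int, int]] = dataclasses.field(default_factory=list)
    radii_mm: list[float] = dataclasses.field(default_factory=list)
    intensity_offset: float = 40.0
    heterogeneity: float = 10.0
    correlation_length_mm: float = 1.0

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.radii_mm):
            raise ValueError("centers and radii_mm must have equal length")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii_mm must be positive")
        if self.intensity_offset <= 0:
            raise ValueError("intensity_offset must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be positive")

    @property
    def n_lesions(self) -> int:
        return len(self.centers)


def _ellipsoid(shape, fracs) -> np.ndarray:
    grids = []
    for n, f in zip(shape, fracs):
        c = (n - 1) / 2.0
        half = n / 2.0
        grids.append(((np.arange(n) - c) / (f * half)) ** 2)
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    return (xx + yy + zz) <= 1.0


def tissue_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean CSF/WM/GM/brain masks from the nested-ellipsoid geometry."""
    shape = spec.grid_shape
    brain = _ellipsoid(shape, (spec.brain_frac,) * 3)
    wm_outer = _ellipsoid(shape, (spec.wm_frac,) * 3)
    csf = _ellipsoid(shape, (spec.csf_frac,) * 3)
    return {"brain": brain, "gm": brain & ~wm_outer,
            "wm": wm_outer & ~csf, "csf": csf}


def _smooth_field(rng: np.random.Generator, shape, voxel_size_mm,
                  correlation_length_mm: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    sigma = [max(correlation_length_mm / v, 1e-6) for v in voxel_size_mm]
    return ndimage.gaussian_filter(white, sigma=sigma)


def _bias_field(rng: np.random.Generator, spec: PhantomSpec,
                brain: np.ndarray) -> np.ndarray:
    # random polynomial rescaled so the in-brain peak-to-trough range equals
    # bias_amplitude, centred on 1
    shape = spec.grid_shape
    axes = [np.linspace(-1, 1, n) if n > 1 else np.zeros(n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    poly = np.zeros(shape)
    d = spec.bias_order
    for px in range(d + 1):
        for py in range(d + 1 - px):
            for pz in range(d + 1 - px - py):
                if px + py + pz == 0:
                    continue
                poly += rng.uniform(-1, 1) * xx**px * yy**py * zz**pz
    if spec.bias_amplitude == 0:
        return np.ones(shape)
    vals = poly[brain]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.ones(shape)
    scaled = (poly - lo) / (hi - lo)          # [0, 1] in-brain
    return 1.0 + spec.bias_amplitude * (scaled - 0.5)


def generate_phantom(spec: PhantomSpec, lesions: LesionSpec | None = None,
                     return_parts: bool = False):
    """Generate one phantom: (ImageVolume, dict of MaskVolumes[, parts]).

    Intensities are tissue means + lesion field, multiplied by the bias
    field, plus Gaussian noise; background is exactly zero.  ``parts``
    (optional) exposes the noise-free unbiased image, the bias field and the
    noise realization for oracle-style tests.
    """
    lesions = lesions or LesionSpec()
    rng = np.random.default_rng(spec.rng_seed)
    tm = tissue_masks(spec)
    brain = tm["brain"]
    shape = spec.grid_shape

    clean = np.zeros(shape)
    for name in ("csf", "gm", "wm"):
        clean[tm[name]] = spec.tissue_means[name]

    wmh = np.zeros(shape, dtype=bool)
    coords = [np.arange(n) * v for n, v in zip(shape, spec.voxel_size_mm)]
    for idx, (center, r_mm) in enumerate(zip(lesions.centers, lesions.radii_mm)):
        cx, cy, cz = center
        if not tm["wm"][cx, cy, cz]:
            raise ValueError(f"lesion {idx} center {center} lies outside WM")
        d2 = ((coords[0][:, None, None] - coords[0][cx]) ** 2
              + (coords[1][None, :, None] - coords[1][cy]) ** 2
              + (coords[2][None, None, :] - coords[2][cz]) ** 2)
        wmh |= (d2 <= r_mm**2) & tm["wm"]

    clean[wmh] = spec.tissue_means["wm"] + lesions.intensity_offset
    if lesions.n_lesions > 0:
        # draw the field regardless of amplitude so noise streams match
        # across heterogeneity settings at a fixed seed
        field = _smooth_field(rng, shape, spec.voxel_size_mm,
                              lesions.correlation_length_mm)
        if lesions.heterogeneity > 0 and wmh.sum() >= 2:
            v = field[wmh]
            sd = v.std()
            if sd > 0:
                clean[wmh] += (v - v.mean()) / sd * lesions.heterogeneity

    bias = _bias_field(rng, spec, brain)
    noise = rng.standard_normal(shape) * spec.noise_sd
    img = clean * bias + noise
    img[~brain] = 0.0

    vs, aff = spec.voxel_size_mm, None
    masks = {name: MaskVolume(tm[name], name, vs) for name in
             ("brain", "gm", "wm", "csf")}
    masks["wmh"] = MaskVolume(wmh, "wmh", vs)
    vol = ImageVolume(img, vs)
    if return_parts:
        parts = {"clean": clean * brain, "bias": bias, "noise": noise * brain}
        return vol, masks, parts
    return vol, masks


@dataclasses.dataclass
class CohortSpec:
    """Cohort size, covariate distributions, lesion variation and effects.

    ``effect_map`` is a list of ``(feature, outcome, slope)`` triples;
    features must be names the pipeline computes (``WMHT_*``, ``NAWMT_*``
    or ``layer{k}_*`` with the six feature suffixes), outcomes are
    ``reaction_time_ms`` or ``risk_score``.  ``penumbra_heterogeneity_range``
    (optional) adds a per-subject correlated texture field to the WM ring
    within ``penumbra_extent_voxels`` (in-plane) of the lesions, so effects
    can be planted that live only in the inner peri-WMH layers.
    """

    n_subjects: int = 50
    effect_map: list[tuple[str, str, float]] = dataclasses.field(
        default_factory=list)
    outcome_noise_sd: float = 20.0
    rng_seed: int = 0
    # covariates (midlife observational-cohort defaults)
    age_mean: float = 51.9
    age_sd: float = 5.4
    female_frac: float = 0.699
    education_mean: float = 16.0
    education_sd: float = 3.4
    risk_score_mean: float = 5.8
    risk_score_sd: float = 2.9
    reaction_time_base_ms: float = 341.0
    etiv_mean_mm3: float = 1_485_100.0
    etiv_sd_mm3: float = 150_200.0
    diabetes_frac: float = 0.02
    smoking_frac: float = 0.05
    hypertension_frac: float = 0.142
    # per-subject lesion variation
    n_lesions_range: tuple[int, int] = (1, 4)
    lesion_radius_mm_range: tuple[float, float] = (2.0, 5.0)
    intensity_offset_range: tuple[float, float] = (25.0, 55.0)
    heterogeneity_range: tuple[float, float] = (5.0, 15.0)
    correlation_length_mm: float = 1.0
    noise_sd_jitter: float = 0.2
    penumbra_heterogeneity_range: tuple[float, float] | None = None
    penumbra_extent_voxels: int = 6
    penumbra_correlation_length_mm: float = 0.2
    # fixed geometry (all subjects share these lesions) removes lesion
    # position/size as a cross-subject variance source; used for
    # experiments isolating spatially local texture effects
    fixed_lesion_centers: list[tuple[int, int, int]] | None = None
    fixed_lesion_radii_mm: list[float] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3 (regression stages "
                             "need residual degrees of freedom)")
        if self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be >= 0")
        for feat, outcome, _slope in self.effect_map:
            if outcome not in _OUTCOMES:
                raise ValueError(f"unknown effect outcome '{outcome}'")
            if not (_ROI_RE.match(feat) or _LAYER_RE.match(feat)):
                raise ValueError(
                    f"effect feature '{feat}' is not a feature the pipeline "
                    "computes (WMHT_*/NAWMT_*/layer{k}_*)")


@dataclasses.dataclass
class Subject:
    subject_id: str
    image: ImageVolume
    masks: dict[str, MaskVolume]
    seed: int
    params: dict


@dataclasses.dataclass
class CohortResult:
    subjects: list[Subject]
    covariates: pd.DataFrame
    ground_truth: pd.DataFrame
    phantom_template: PhantomSpec
    cohort_spec: CohortSpec


def _needed_features(effect_map) -> set[str]:
    return {feat for feat, _o, _s in effect_map}


def _true_features(subject_img: ImageVolume, masks: dict[str, MaskVolume],
                   needed: set[str], bias_free: bool = False
                   ) -> dict[str, float]:
    """Ground-truth feature values (cube-root scale) from the true masks."""
    if not needed:
        return {}
    # ground truth = the pipeline's own features computed with the true
    # masks: bias-correct exactly as the default pipeline does, so planted
    # slopes are recoverable by the full run up to segmentation error
    if not bias_free:
        field = estimate_bias_field(subject_img, masks["wm"], degree=2)
        subject_img = correct_bias(subject_img, field)
    norm = normalize_intensities(subject_img)
    need_maps = any(not f.endswith(("_mean", "_std")) for f in needed)
    need_layers = any(_LAYER_RE.match(f) for f in needed)
    maps = None
    if need_maps:
        q = quantize(subject_img, masks["brain"])
        maps = make_texture_maps(q)

    def roi_feats(roi: MaskVolume) -> dict[str, float]:
        if maps is not None:
            return transform_features(extract_roi_features(norm, maps, roi),
                                      keep_raw=False)
        vals = norm.data[roi.data]
        mean = float(vals.mean()) if vals.size else np.nan
        std = float(vals.std(ddof=1)) if vals.size >= 2 else np.nan
        return transform_features({"mean": mean, "std": std}, keep_raw=False)

    rois: dict[str, MaskVolume] = {}
    if any(f.startswith("WMHT_") for f in needed):
        rois["WMHT"] = masks["wmh"]
    if any(f.startswith("NAWMT_") for f in needed):
        rois["NAWMT"] = build_nawm(masks["wm"], masks["wmh"])
    out: dict[str, float] = {}
    for prefix, roi in rois.items():
        for k, v in roi_feats(roi).items():
            out[f"{prefix}_{k}"] = v
    if need_layers:
        ks = {int(_LAYER_RE.match(f).group(1)) for f in needed
              if _LAYER_RE.match(f)}
        lset = build_layers(masks["wmh"], masks["wm"],
                            n_layers=max(ks), increment=2)
        for k in ks:
            for name, v in roi_feats(lset.layers[k - 1]).items():
                out[f"layer{k}_{name}"] = v
    return {k: v for k, v in out.items() if k in needed}


def generate_cohort(phantom_template: PhantomSpec,
                    cohort: CohortSpec) -> CohortResult:
    """Generate a multi-subject cohort with known planted effects."""
    rng = np.random.default_rng(cohort.rng_seed)
    template_masks = tissue_masks(phantom_template)
    wm_idx = np.argwhere(template_masks["wm"])
    needed = _needed_features(cohort.effect_map)

    subjects: list[Subject] = []
    truth_rows: list[dict] = []
    cov_rows: list[dict] = []
    for i in range(cohort.n_subjects):
        sid = f"sub-{i + 1:03d}"
        seed = int(rng.integers(0, 2**31 - 1))
        srng = np.random.default_rng(seed)
        noise_sd = phantom_template.noise_sd * (
            1.0 + cohort.noise_sd_jitter * srng.uniform(-1, 1))
        spec = dataclasses.replace(phantom_template, noise_sd=noise_sd,
                                   rng_seed=seed)
        if cohort.fixed_lesion_centers is not None:
            centers = [tuple(c) for c in cohort.fixed_lesion_centers]
            radii = list(cohort.fixed_lesion_radii_mm
                         or [np.mean(cohort.lesion_radius_mm_range)]
                         * len(centers))
            n_les = len(centers)
        else:
            n_les = int(srng.integers(cohort.n_lesions_range[0],
                                      cohort.n_lesions_range[1] + 1))
            centers = [tuple(wm_idx[srng.integers(len(wm_idx))]) for _ in
                       range(n_les)]
            radii = list(srng.uniform(*cohort.lesion_radius_mm_range,
                                      size=n_les))
        offset = float(srng.uniform(*cohort.intensity_offset_range))
        het = float(srng.uniform(*cohort.heterogeneity_range))
        lesions = LesionSpec(centers=centers, radii_mm=radii,
                             intensity_offset=offset, heterogeneity=het,
                             correlation_length_mm=cohort.correlation_length_mm)
        img, masks, parts = generate_phantom(spec, lesions, return_parts=True)

        pen = np.nan
        if cohort.penumbra_heterogeneity_range is not None and n_les > 0:
            pen = float(srng.uniform(*cohort.penumbra_heterogeneity_range))
            ring = _penumbra_ring(masks["wmh"].data, masks["wm"].data,
                                  cohort.penumbra_extent_voxels)
            if ring.sum() >= 2 and pen > 0:
                field = _smooth_field(srng, spec.grid_shape,
                                      spec.voxel_size_mm,
                                      cohort.penumbra_correlation_length_mm)
                v = field[ring]
                clean = parts["clean"].copy()
                clean[ring] += (v - v.mean()) / v.std() * pen
                data = clean * parts["bias"] + parts["noise"]
                data[~masks["brain"].data] = 0.0
                img = img.copy_with(data)

        subjects.append(Subject(sid, img, masks, seed, {
            "n_lesions": n_les, "intensity_offset": offset,
            "heterogeneity": het, "penumbra_heterogeneity": pen,
            "noise_sd": noise_sd}))
        truth_rows.append({
            "subject_id": sid, "seed": seed, "n_lesions": n_les,
            "intensity_offset": offset, "heterogeneity": het,
            "penumbra_heterogeneity": pen, "noise_sd": noise_sd,
            **{f"true_{k}": v for k, v in
               _true_features(img, masks, needed,
                              bias_free=spec.bias_amplitude == 0).items()}})

        cov_rows.append({
            "subject_id": sid,
            "age": float(srng.normal(cohort.age_mean, cohort.age_sd)),
            "sex": int(srng.uniform() < cohort.female_frac),  # female = 1
            "education_years": float(srng.normal(cohort.education_mean,
                                                 cohort.education_sd)),
            "risk_score": float(srng.normal(cohort.risk_score_mean,
                                            cohort.risk_score_sd)),
            "etiv_mm3": float(abs(srng.normal(cohort.etiv_mean_mm3,
                                              cohort.etiv_sd_mm3))),
            "diabetes": int(srng.uniform() < cohort.diabetes_frac),
            "smoking": int(srng.uniform() < cohort.smoking_frac),
            "hypertension": int(srng.uniform() < cohort.hypertension_frac),
        })

    truth = pd.DataFrame(truth_rows)
    covars = pd.DataFrame(cov_rows)

    # outcomes: baseline + planted linear effects on cohort-centred true
    # features + Gaussian noise
    rt = np.full(cohort.n_subjects, cohort.reaction_time_base_ms)
    rs = covars["risk_score"].to_numpy().copy()
    for feat, outcome, slope in cohort.effect_map:
        col = truth[f"true_{feat}"].to_numpy()
        centred = col - np.nanmean(col)
        centred = np.nan_to_num(centred)
        if outcome == "reaction_time_ms":
            rt = rt + slope * centred
        else:
            rs = rs + slope * centred
        truth[f"slope_{outcome}__{feat}"] = slope
    rt = rt + rng.normal(0.0, cohort.outcome_noise_sd, cohort.n_subjects)
    covars["reaction_time_ms"] = rt
    covars["risk_score"] = rs

    return CohortResult(subjects, covars, truth, phantom_template, cohort)


def _penumbra_ring(wmh: np.ndarray, wm: np.ndarray,
                   extent_voxels: int) -> np.ndarray:
    ring = np.zeros_like(wmh)
    for z in range(wmh.shape[2]):
        s = wmh[:, :, z]
        if s.any():
            d = ndimage.distance_transform_edt(~s)
            ring[:, :, z] = (d > 0) & (d <= extent_voxels)
    return ring & wm


def write_cohort(result: CohortResult, outdir: str | Path) -> None:
    """Write NIfTI volumes, covariate/ground-truth CSVs and a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in result.subjects:
        d = outdir / sub.subject_id
        d.mkdir(exist_ok=True)
        write_image(sub.image, d / "flair.nii.gz")
        for name, mask in sub.masks.items():
            write_mask(mask, d / f"{name}.nii.gz")
    result.covariates.to_csv(outdir / "covariates.csv", index=False)
    result.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    sidecar = {
        "phantom": dataclasses.asdict(result.phantom_template),
        "cohort": dataclasses.asdict(result.cohort_spec),
    }
    (outdir / "simulation.json").write_text(
        json.dumps(sidecar, indent=2, default=str))
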