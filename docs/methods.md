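# Methods

This note documents the models, conventions and design choices behind
`flairtex`, in the order the pipeline applies them.

## Texture model

**Quantization.** In-brain intensities are binned into N equal-width levels
over [min, max] of the in-brain values (N = 8 by default).  A value on a
bin edge goes to the upper bin; the maximum is clamped into bin N, so the
minimum maps to level 1 and the maximum to level N.  Binning is global per
volume — never per ROI — which makes every downstream feature invariant to
increasing affine rescalings of the intensities and keeps the level scale
identical across ROIs within a subject.  Background voxels (exactly zero
after skull-stripping) carry level 0 and never enter co-occurrence counts:
treating them as a grey level would fabricate an artificial level at brain
edges.

**Per-voxel GLCM.** For each voxel with a full 3×3 in-plane neighbourhood,
ordered level pairs (a, a+d) are counted for the eight unit directions d,
requiring both members inside the patch and both foreground.  The eight
directional tables are summed (making the table symmetric) and normalized.
Analysis is strictly 2D within axial slices: with 4 mm slices against
0.43 mm in-plane spacing, through-plane neighbours are not comparable
neighbours.  Voxels on slice borders, or whose patch contains no valid
pair, are flagged invalid and carry NaN in the maps; ROI means silently
drop invalid voxels and log a warning when more than half an ROI is
dropped.

**Features.** contrast Σp(i−j)², energy Σp², entropy −Σp ln p (natural
log; the base only rescales entropy and affects no association), and
homogeneity Σp/(1+|i−j|), with 0·ln 0 := 0.  At every valid voxel
energy, homogeneity ∈ (0, 1], contrast ∈ [0, (N−1)²] and entropy
∈ [0, 2 ln N].  The vectorized map builder and the naive per-patch path
use identical reduction expressions and agree bit-for-bit; the test-suite
enforces this exhaustively on a seeded volume.

**First-order features.** Mean and SD (unbiased, n−1) of min-max
normalized intensities, where the minimum and range are taken over
non-zero voxels of the skull-stripped volume.  All texture measures are
cube-root transformed (signed cube root) before modelling, to reduce
skew; raw values are kept alongside under `*_raw`.

## Preprocessing

The multiplicative shading field is modelled as exp of a low-order 3D
polynomial (degree 2 by default, ≤ 3 recommended) fitted by least squares
to log-intensities **within a homogeneous tissue class** — white matter in
this pipeline — with voxels more than 3.5 MADs from the mask median
trimmed so hyperintense lesions cannot bend the fit.  Fitting over the
whole brain is not an option: a low-order polynomial happily absorbs the
CSF/GM/WM contrast itself (verified on phantoms, where the whole-brain fit
"corrects" anatomy by a factor of 2 while the true bias is ±5%).  The
fitted field is normalized to mean 1 over the fit mask; correction divides
by it and leaves background zeros untouched.  This estimator corrects
exactly the polynomial bias class the synthetic generator produces; for
scanner data corrected externally (e.g. by N4), the stage can be skipped.

## Segmentation and ROIs

WMH: voxels above k × median of in-brain non-zero intensity (k = 1.2),
intersected with the WM mask.  The median is taken per volume, not per
slice.  An optional minimum-component-size filter (26-connectivity)
defaults to off.  The WM intersection replaces the manual lesion review a
human rater would perform; it prevents bright GM/CSF partial-volume voxels
from entering the lesion mask.

NAWM: (WM − WMH) eroded per axial slice with a 2×2 square kernel.  A 2×2
kernel has no centre; the anchor is fixed at the top-left element (voxel v
survives iff v, v+(1,0), v+(0,1), v+(1,1) are all set), chosen for
bit-exact reproducibility over convention ambiguity.

Peri-WMH layers: per axial slice, D_k = dilation of WMH by the exact
Euclidean disk {(dx,dy): dx²+dy² ≤ (2k)²}; layer k = (D_k − D_{k−1}) ∩ WM
with D_0 = WMH.  Implementation uses the per-slice Euclidean distance
transform thresholded at 2k voxels, which is the same operation computed
in one pass.  Layers intersect the *un-eroded* WM mask (they are not
NAWM-eroded).  At 0.43 mm in-plane voxels each layer is 0.86 mm thick;
layer 3 ends at 2.58 mm, layer 4 at 3.44 mm, layer 10 at 8.6 mm.

WMH volume is reported as voxel count × voxel volume, normalized by an
externally supplied eTIV ([WMH/eTIV] × 100%), cube-root transformed.

## Statistics

OLS throughout, classical standard errors, continuous predictors
mean-centred per model (binary 0/1 columns, e.g. sex with female = 1, left
uncentred); listwise deletion within a model, pairwise for Spearman.
Interaction models centre both moderators before forming the product, so
interaction t-statistics are invariant to location shifts; a 3×3
marginal-means grid (mean, ±1 SD) is exported for plotting.  Paired
comparisons are two-sided paired t-tests with a degenerate-variance guard
(zero-variance nonzero differences are reported as infinite-t degenerate
results, not errors).  Benjamini–Hochberg FDR is applied within model
families — the WMH-volume family, the reaction-time family, the risk-score
family, the interaction family, each risk-factor column of the exploratory
battery, and each per-layer association separately over its 11 ROIs (WMH
plus 10 layers).  Subjects with empty lesion masks flow through with
missing WMH features.

## Synthetic data

Phantoms are nested ellipsoids (CSF core, WM shell, GM rim) with FLAIR-like
means (CSF 30, WM 100, GM 120 by default) on a 96×96×27 grid of
0.43×0.43×4 mm voxels; desk-scale experiments shrink the grid (32–64
in-plane, 6–10 slices), which changes nothing structurally.  The default
geometry makes WM ~48% of brain voxels, so the in-brain median is the WM
mean and the 1.2×median threshold cleanly separates lesions (+25 to +55
offset) from GM.  Ellipsoids are defined in voxel coordinates; the phantom
is a geometric stand-in, not an anatomical template.

Lesions are spheres in physical mm intersected with WM; their internal
texture is a Gaussian random field (white noise smoothed with an isotropic
Gaussian of width `correlation_length_mm`, standardized within the lesion
to the requested SD).  Heterogeneity = 0 yields internally constant
lesions.  Bias is a random polynomial rescaled to a requested in-brain
peak-to-trough range, centred on 1; noise is additive Gaussian (magnitude-
MRI Rician corrections are irrelevant at the simulated SNRs and Gaussian
keeps the oracles closed-form).  Background is exactly zero.  A fixed seed
reproduces a phantom or cohort bit-for-bit.

Cohorts draw covariates matching a midlife observational sample (age
51.9 ± 5.4, 69.9% female, education 16 ± 3.4 y, risk score 5.8 ± 2.9,
eTIV 1485 ± 150 cm³, reaction time baseline 341 ms, diabetes 2%, smoking
5%, hypertension 14.2%) and vary lesion count, size, brightness and
heterogeneity per subject.  Planted effects add
`slope × (true feature − cohort mean)` to an outcome, where the *true*
feature is the pipeline's own feature computed with the ground-truth masks
on the same cube-root scale the models analyse — so a downstream
regression estimate is directly comparable to the planted slope, and any
shortfall isolates segmentation error.  When the phantom carries bias, the
truth computation applies the same WM-fit polynomial correction as the
default pipeline.  All slopes and true feature values are recorded in the
ground-truth sidecar table.

### What the generator does and does not emulate

It emulates: skull-stripped axial FLAIR geometry and anisotropy, tissue
contrast ordering, smooth multiplicative shading, additive noise,
hyperintense lesions with controllable internal texture, and known
feature–outcome couplings.  It does not emulate real cortical folding,
partial-volume mixing, scanner-specific noise correlation, registration
error, or the intensity distribution of any particular scanner.
Consequently, passing tests demonstrate that the *measurement chain and
inference machinery* are correct and well calibrated — not that any
specific effect size measured on real scans would replicate.

## Planted-effect experiment conditions

`flairtex.experiments` freezes the conditions of the validation
experiments:

- **Slope recovery**: 40×40×8 phantoms, noise SD 2, bias range 0.1,
  cohorts of 30, lesion offsets 35–55 and heterogeneity 2–5 (cleanly
  separable, Dice ≈ 1), slope −2000 ms per cube-root-mean unit against
  outcome noise of 5 ms.  Recovery = correct sign and planted slope inside
  the estimate's 95% CI.
- **Layer specificity**: 64×64×8 phantoms; every subject carries the same
  fixed lesion, constant brightness, zero internal heterogeneity, noise SD
  1, no bias and no noise jitter — so the only cross-subject texture
  variation is a fine-grained (0.2 mm correlation length) heterogeneity
  field confined to the WM ring within 6 in-plane voxels of the lesion,
  with per-subject amplitude 1–4.  The outcome loads on true layer 1–3
  contrast with decaying slopes (1600/800/400).  The fixed geometry and
  the mid-bin placement of the WM mean (offset 55 puts WM at level-bin
  centre) are essential: lesion geometry and quantization bin-edge
  placement are *global* variance sources that otherwise propagate a
  local effect into every layer.  Layers beyond the ring then carry no
  texture variance at all; regressions on such constant columns are
  reported as "no measurable association".  Detection = FDR-significant in
  layers 1–3 (layer 4 may respond via 3×3-patch spillover across the ring
  boundary) and not in layers 8–10.
- **Sign pattern**: 48×48×8 phantoms, 50 subjects, lesion heterogeneity
  8–15 against WM noise SD 2 — lesions are brighter and internally more
  variable than NAWM, reproducing the higher mean/std/contrast/entropy and
  lower energy/homogeneity lesion signature in paired t-tests.
- **Type-I calibration**: tabular nulls (independent Gaussian outcome and
  predictor, age/sex covariates, n = 50), 1000–2000 replicates against the
  binomial band around the nominal 0.05.

## Numerical conventions and degenerate inputs

- Quantization edges: upper-bin ties, top clamp (documented above).
- 0·ln 0 := 0 in entropy; GLCMs must be normalized before features.
- Single-voxel ROIs: mean defined, SD missing (n−1 convention), flagged.
- Empty ROIs/layers: all-NaN features with a logged warning; cohort runs
  never crash on lesion-free subjects.
- Degenerate paired differences: t = ±inf, p = 0, flagged degenerate.
- Rank-deficient designs raise errors naming the suspect columns.
- The pipeline driver is resumable per subject and isolates per-subject
  failures; identical config + seed reproduces byte-identical feature
  tables.

## Known limitations

- The bias estimator corrects low-order polynomial shading only; it is not
  a histogram-sharpening method and needs a homogeneous-tissue fit mask.
- 2D-only texture (axial); no distance-2+ co-occurrence offsets; only the
  four Haralick features above (no correlation, cluster shade, run-length
  or spectral features).
- No cross-subject intensity standardization: first-order features remain
  acquisition-dependent, exactly as the normalization formula implies.
- Layer construction uses Euclidean, not WM-geodesic, distance.
- Absolute synthetic feature values are not comparable to any real-scan
  values; only directions, calibrations and recovery rates are
  interpretable.
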