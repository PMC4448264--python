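# Methods

This note documents the models, parameters and design choices behind
nestquant, and what its synthetic benchmarks do and do not establish.

## Synthetic HE fields

The generator renders a 200×-like field as stain optical densities (OD)
converted to RGB by Beer–Lambert with the package's fixed HE stain matrix,
so color deconvolution inverts the rendering exactly up to noise. Tumor
nests are unions of 1–4 overlapping ellipses with jittered lobes, giving the
irregular perimeters the fractal-dimension features need. Nuclei are
flat-topped super-Gaussian hematoxylin blobs (OD `peak·exp(−0.9 d⁶)` in
normalized elliptical radius `d`, support 1.34× the radius, peak OD
0.55–0.75): a flat chromatin plateau with a fast falloff keeps the Otsu
threshold covering most of each nucleus while preserving a deep saddle
between adjacent nuclei, which the plain Gaussian profile we tried first
does not. Eosin is a smooth field (stroma ≈ 0.38, nest cytoplasm ≈ 0.25
OD). The only corruptions are Gaussian pixel noise (sd 3 intensity levels)
and a linear illumination ramp (5% across the width) — enough to exercise
preprocessing without modeling scanner physics.

Default composition (256×256 px): 4 nests of mean area 5000 px²; epithelial
nuclei at 0.0015 per px² of nest; stromal round at 0.0003 and non-round at
0.00045 per px² of stroma; nucleus area ~N(200, 900) px². The densities and
nucleus areas sit in the mid-range of the three-level categories such
studies print for these quantities, so category boundaries are exercised at
realistic scales. Nucleus placement enforces a minimum centroid separation
of 1.1× the summed effective radii (relaxed 1% per retry, floor 0.5×);
a request whose total nucleus area would exceed 80% of the available
compartment raises "infeasible density".

What the generator does **not** emulate: chromatin texture, nucleoli,
overlapping nuclei in thick sections, stain batch variation, necrosis, DCIS,
tissue folds, or the 1360×1024 field size of production scanners. Passing
segmentation benchmarks here therefore demonstrate algorithmic correctness
and internal consistency, not clinical-grade accuracy on real slides.

## Preprocessing and stain separation

Median filter: 3×3, edge replication. Contrast stretch: per-channel linear
map of the (1, 99) percentiles to [0, 255] (constant channels pass through
with a warning). Color normalization: Reinhard-style mean/sd matching in
CIELAB against a reference image — one reasonable choice among several; it
is optional and off unless a reference is supplied. The 8-bit OD transform
floors intensities at 1 (capping OD at log₁₀255 per channel) so pixels
saturated to black by the stretch cannot produce unbounded densities.
Deconvolution solves OD = C·M for the standard unit-norm HE vectors with the
residual channel as their normalized cross product; negative concentrations
are clipped to zero. Round-tripping OD → RGB → OD through 8-bit storage
carries ≤ 0.03 OD error per stain (quantization amplified by the unmixing
inverse at dark pixels).

## Nuclei segmentation

Threshold: Otsu on hematoxylin OD (override via `od_threshold`); opening
with a radius-2 disk; hole filling. Markers: h-maxima of the σ=1.5 Gaussian
smoothed OD restricted to the mask — equivalently the regional minima of the
h-minima-suppressed inverted OD — with h defaulting to 3% of the smoothed OD
range. We initially used 10%: at that depth the maxima of faint nuclei
adjacent to bright ones are absorbed and recall drops to ~0.85 on default
scenarios; 3% sits above the noise floor of the smoothed map and restores
precision/recall ≈ 0.97/0.95. Watershed runs on the negated OD inside the
mask; an unseeded nonempty mask is returned as a single flagged region.
Spurious-region gates: area in [30, 3000] px², solidity ≥ 0.7, mean Sobel
boundary gradient ≥ 5 on a 0–255-scaled OD. All thresholds were tuned on
the synthetic generator and are exposed in the pipeline config. Segmented
areas systematically undershoot the rendered ellipse area by ~15–30% on
noisy images (the profile skirt falls below Otsu); on noise-free fields the
mean relative area error is ≤ 20%.

## Nest/stroma segmentation

Per-pixel features over a 9-px window: local homogeneity `1 − sd_w/127.5`
per RGB channel, raw color, and a texture block of the 8 uniform LBP
pattern frequencies (P=8, R=1; non-uniform codes pooled) plus normalized
local gray variance — 15 features. The texture descriptor is a pragmatic
fixed-length choice; any fixed-length descriptor can be substituted by
recomputing features. Classifier: RBF SVM, C=1, γ=1/15, features z-scored
with training statistics; training pixels are sampled from ground truth
(synthetic) or supplied labels (real data). Postprocessing is deterministic
— closing (radius 3) then removal of nest components and stroma holes under
500 px² — replacing interactive expert editing; an externally supplied
correction mask, when given, simply overrides the result, which keeps the
expert-in-the-loop path reproducible. The closing dilates nest boundaries
by a few pixels; at synthetic nest sizes this inflates the epithelial class
by a handful of boundary nuclei (nest-area bias ~5%, epithelial-count bias
up to ~20% of small per-image counts). On production-size nests the same
radius is negligible relative to nest area.

## Cell classes and the feature catalog

Nest membership is decided by the centroid pixel (cheap, deterministic,
matches the pseudo-color rendering); stromal nuclei split at eccentricity
0.8. The catalog is constructive: 4 regions × 10 channels × 10 statistics =
400 pixel-level; 4 object classes × 11 shape descriptors × 7 aggregates =
308, plus 6 topological = 314 object-level; 16 semantic densities/ratios.
Variances are population variances; all geometry is in pixel units. The
"stromal cell structure" parameter is implemented as the mean Delaunay edge
length over stromal non-round nuclei centroids — an interpretation, since
only its name and cutpoints are conventionally printed. Delaunay statistics
are computed per image (not per nest); densities use pixel areas. Fractal
dimension: box counting over power-of-two box sizes from 2 to min(H,W)/4 on
the 8-connected nest contour, −slope of the log–log least-squares fit,
clipped to [0, 2]. Pixel-level parameters are extracted but excluded from
survival modeling, where only the interpretable object- and semantic-level
parameters are used.

## Composites

The two printed formulas are stored as frozen coefficient manifests and
applied to z-scored parameters; whether the original coefficients were meant
for raw or standardized inputs is not documented, so both modes exist and
standardized is the default (the printed category boundaries of the
composites are near zero, which is only consistent with centered inputs).
PCA refits z-score each block, take first-PC loadings (unit norm), and fix
the sign so the largest-magnitude loading is positive.

## Survival analysis

The cutpoint search scans all ordered pairs of midpoints between distinct
observed values, maximizing the 3-group log-rank χ² subject to every group
holding ≥ 10% of patients (the k-group statistic is a vectorized in-package
implementation, verified against lifelines). The selection is deliberately
uncorrected, mirroring common practice; the optional Miller–Siegmund-style
adjusted p-value treats √χ² of the two-cutpoint maximum as a single scanned
statistic and is an approximate optimism adjustment, not an exact reference
distribution. `examples/cutpoint_optimism.py` measures the consequence: on
null cohorts (n = 40) the naive p < 0.05 rate is an order of magnitude
above nominal, and even the adjusted rate stays inflated — cutpoint-derived
categories need independent validation. Cox fits use lifelines (Efron
ties), require ≥ 10 events and non-constant covariates, and raise on
non-convergence. ROC AUC is the trapezoidal concordance probability with a
Hanley–McNeil rank-based CI. Two-sided α = 0.05 with no multiple-testing
correction is the reporting convention; a Benjamini–Hochberg step is
available via statsmodels upstream if needed. Survival times are months;
medians are the first time S(t) ≤ 0.5 and are reported missing when the
curve never reaches it.

## Cohort generator

Features are standard normal (or Bernoulli(0.5) for names listed as
binary); event times are exponential with hazard λ·exp(Σβx), λ = 0.012
events/month by default, giving roughly a two-thirds event fraction over the
96-month (8-year) follow-up window typical of a node-mixed cohort.
Censoring is the minimum of an exponential draw and the follow-up cap; the
censor-draw rate is λ·c/(1−c), which makes c the probability of being
censored before the event under the null model. The pipeline's synthetic
mode instead draws times from hazards on the *extracted*, z-scored
per-patient image features, so the end-to-end run carries a genuine
image → outcome dependency.

## Problem sizes and determinism

Tests and the acceptance script run on 256×256 default fields (two
scenarios for Dice/F1), 50 seeds × n = 1000 for Cox recovery, n ≤ 60 for
the exhaustive cutpoint oracle, and a 3-patient 144×144 study for
end-to-end determinism — sizes chosen so the whole suite completes in a few
minutes on one CPU while keeping every statistical check adequately
powered. All randomness flows through explicit integer seeds; the pipeline
manifest hashes the config and all CSV outputs, and reruns with the same
seed reproduce the hash bit-for-bit.

## Known limitations

- Overlapping-nucleus resolution is limited to what watershed separates; no
  concave-splitting or mitosis handling.
- The epithelial/stromal assignment at nest borders inherits the closing
  radius of postprocessing (see above).
- The catalog reproduces the printed level counts and every conventionally
  named parameter, but the full 730-name list of the original supplementary
  material is not public; names beyond the printed ones are constructive.
- Real-slide performance is untested by construction; the synthetic
  benchmarks bound algorithmic, not biological, validity.
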