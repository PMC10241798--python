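# Methods

This note records the models, conventions and calibrations behind
`petromics`, in the order data flows through the pipeline.

## SUV and volume handling

Volumes are NIfTI-1, stored as 32-bit float, 3D only. Body-weight SUV is
computed as activity concentration (Bq/mL) divided by injected activity
(Bq) times body weight (g); the injected activity is assumed already
decay-corrected to scan time, since acquisition protocols typically start
a fixed ~60 min post-injection and correct upstream. The conversion is
linear, so phantoms may carry SUV directly; `SUVVolume.provenance` records
which path produced the values.

## Delineation

The MTV is delineated at a fixed fraction (default 0.35) of the maximum
SUV inside an operator-style search region (a voxel bounding box; for
phantoms, the ground-truth box plus margin). Voxels **at** the threshold
are included — the tie rule is undocumented in clinical tools, so it is
fixed here for determinism. The result is reduced to the largest
26-connected component, which removes dim or bright satellites.

A fixed 35% threshold systematically overestimates a PSF-blurred sphere:
the half-maximum surface of a blurred step edge coincides with the true
boundary, so any sub-50% level lies outside it. Numerically the bias is
about +25% in volume for a 15 mm sphere at 6 mm FWHM with unit background;
the segmentation tests assert this measured behavior rather than an
idealized zero bias.

## Surface area and asphericity

Two surface estimators are provided. The default extracts a
marching-cubes iso-surface at the 0.5 level from the binary mask after a
1-voxel Gaussian anti-aliasing (a raw binary mesh overestimates curved
areas ~9%; smoothing restores a digitized sphere's area to within ~1%, and
tiny masks that lose the level crossing fall back to the raw field). The
voxel-face estimator sums exposed cuboid faces and carries the well-known
~1.5× staircase bias on curved surfaces; it is retained as a closed-form
oracle.

Asphericity is (S³/(36πV²))^⅓ − 1. S and V are measured **on the same
iso-surface** (V via the divergence theorem over the oriented triangles),
which guarantees ASP ≥ 0 by the isoperimetric inequality and scores ≈0.003
on a digitized r = 15 mm sphere at 1 mm voxels. Mixing the mesh surface
with the voxel-count volume — superficially attractive because MTV uses
voxel counts — breaks that bound badly on textured masks (ASP ≈ −0.19) and
was rejected. MTV itself remains the voxel-count volume.

## First-order features

SUVmean/SD use the sample (n−1) convention everywhere, matching the
bias-corrected skewness and excess-kurtosis formulas implemented verbatim
(the −3 correction makes the normal distribution score 0). A single-voxel
mask has no sample SD: COV is reported missing (NaN), never zero. Entropy
is the Shannon entropy of the equal-width-binned in-mask histogram, in
bits; there is no binning-free convention for continuous SUV, so the bin
count is a config knob (default 64, a common radiomics choice) and the
range defaults to the in-mask min–max.

## GLCM texture

In-mask SUV is binned to G equal-width levels over the in-mask range (max
maps to G; a constant signal maps to level 1 and is flagged). Pairs at
unit displacement are accumulated over 13 unique 3D directions (or 4
in-plane directions in `2d-axial` mode), symmetrized, merged into a single
matrix and normalized before feature computation; merging rather than
per-direction averaging avoids empty-matrix edge cases on small masks.
Contrast, correlation (marginal-moment form), energy and homogeneity
follow the classical sums. Correlation is undefined for a constant image
and reported missing with a reason.

**Gray-level default.** G defaults to 8, not the 64 sometimes used with
higher-resolution modalities. A 35%-threshold mask at 4 × 4 × 5 mm holds a
few hundred voxels — roughly 2 000 voxel pairs — which cannot populate a
64 × 64 = 4 096-cell matrix: at G = 64 the energy statistic degenerates
into pair-count noise, and all four features are dominated by mask size.
G = 8 is also the long-standing default of the classic 2D co-occurrence
tools. Both 8 and 64 are exercised in the tests; G and the direction mode
are sensitivity axes in the pipeline config.

## Statistics

- Shapiro–Wilk for normality screening (per feature and timepoint).
- Paired Wilcoxon signed-rank with zero differences discarded (classic
  Wilcoxon; the Pratt variant is a config option), tie-corrected rank
  variance, and a signed normal-approximation Z whose positive direction
  means *pre exceeds post* — i.e. the feature decreased after therapy.
  All-zero differences are degenerate (p = 1), not an error. Empirical
  type-I error at nominal 0.05 measures ≈0.037–0.05 over 2 000 null
  simulations at n = 25.
- Spearman correlation with average ranks for ties and the
  t-approximation p-value; strength bands on |ρ|: (0, 0.3) low,
  [0.3, 0.5) moderate, [0.5, 0.7) strong, [0.7, 0.9) very strong,
  [0.9, 1] full (the closed upper end is a documented extension), exactly
  0 → none.
- Mann–Whitney U with tie-corrected asymptotic p for two-group outcome
  comparisons (group variable configurable; default any-recurrence vs
  none).
- No multiple-testing correction is applied to the primary p-values — a
  Benjamini–Hochberg column is emitted alongside, clearly labeled as an
  extension. α defaults to 0.05 and is configurable; p-values below 0.001
  are displayed as "<0.001" rather than 0.000.
- Recurrence enters the correlation analysis binary (any vs none) by
  default; ordinal none < local < distant is a config option. FIGO is
  ordinally coded IIIC1 < IIIC2 < IVB.

## The phantom generator

A tumor is an ellipsoid (semi-axes in mm) of peak SUV in a uniform
background on a 4 × 4 × 5 mm grid. Intra-tumor texture is a log-normal
multiplicative Gaussian random field: white noise smoothed to a
correlation length (default 10 mm), standardized, exponentiated with mean
1 and SD `heterogeneity_sd` (default 0.5). An optional focal hot spot — a
small ellipsoid at 0.45 of the radius along a fixed diagonal, uptake
multiplied by `hotspot_factor` — models the high-uptake subregions real
tumors show. The volume is blurred with a Gaussian PSF (default 6 mm
FWHM), Gaussian noise is added (cohorts scale it to ~5% of peak SUV, since
PET noise grows with activity), and values are clipped at zero. All
randomness comes from one seeded generator with a documented draw order;
identical (spec, seed) is bit-identical.

Cohorts draw per-patient covariates with the composition of an 83-patient
IIIC1–IVB cervical-cancer chemotherapy cohort (median age ~55, range
24–76; FIGO 2/52/29; recurrence 45/13/25; regimen 77/3/2/1; 60%
responders — a typical NACT response rate, chosen here since the emulated
study does not publish one). Pre-therapy tumors have radii 17–22 mm
(MTV ≈ 10–70 cm³, bulky locally advanced disease); responders lose 35–65%
of MTV and 25–50% of peak SUV post-therapy, non-responders 10–40% and
5–25% — everyone received chemotherapy, so mild shrinkage is universal.

**Planted effects.** A planted effect requests a Spearman correlation
between a named pipeline feature (e.g. `post_glcm_energy`) and a covariate
(age, response, recurrence). Five latent channels drive each patient's
physical parameters: texture heterogeneity, texture smoothness, relative
noise, focality, and a shared pre/post size multiplier (shared so planted
size effects can never invert a patient's pre → post shrinkage). A
least-squares solver distributes covariate loadings over these channels
using a frozen, Monte-Carlo-measured sensitivity matrix of each feature to
each channel, corrected by (a) the rank attenuation of observing a binary
covariate instead of its latent (√(3p(1−p))), (b) measured baselines where
the physical responder effects already couple a feature to response, and
(c) a measured per-feature efficiency of the linearized model. All
calibration tables were estimated once under the default cohort conditions
and frozen; over 20 cohorts of n = 200 the realized mean ρ lands within
about ±0.07 of targets of magnitude 0.30–0.54, with the correct sign in
essentially every cohort.

## What the phantoms do and do not show

The phantoms emulate SUV-space appearance, not scanner physics: no
sinograms, reconstruction artifacts, scatter/randoms, respiratory motion,
bladder spill-in, or inter-scanner variation. Tumors are ellipsoids with
stationary texture; real cervical tumors have irregular margins, necrotic
cores and adjacent physiological uptake. Passing the recovery tests
therefore shows the *pipeline* faithfully measures and statistically
detects associations that exist in the images at clinical magnitudes — it
does not validate the clinical associations themselves, whose raw data are
not public.

Known behavioral limits, measured and asserted in the tests rather than
idealized away: the 35% threshold over-segments blurred spheres (~+25%);
entropy rises with heterogeneity only in the weak-texture regime (beyond
SD ≈ 0.4 the log-normal tail stretches the min–max binning range and
reverses the trend); GLCM features are strongly coupled to lesion size at
coarse PET resolution — a real and well-documented confound of PET
radiomics, which is why mask size is itself a planting channel.

## Problem sizes

The default test run generates 20 cohorts × 200 patients × 2 timepoints
(~8 000 volumes of 32 × 32 × 26 voxels) for the recovery experiment, 2 000
null simulations per rank test, 200 random masks for the texture oracle
and 100 vectors for the moment oracles; the whole suite completes in about
two minutes on one CPU, and `scripts/acceptance.py` in about three.
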