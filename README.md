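# petromics

Radiomic analysis of [¹⁸F]FDG-PET tumor volumes, built for paired
pre/post-chemotherapy cohort studies and exercised end-to-end on synthetic
PET phantoms with known ground truth.

## The problem

In locally advanced cervical cancer, neoadjuvant chemotherapy response and
later recurrence are hard to predict from visual PET reading alone.
Quantitative descriptors of the primary tumor — metabolic burden, shape,
and intra-tumor texture — carry prognostic signal, but every one of them
depends on delineation and discretization conventions that are rarely
reported. `petromics` implements the full chain as a reproducible,
parameterized pipeline:

1. **Delineation** — the metabolic tumor volume (MTV) is the largest
   26-connected component of voxels at or above a fixed fraction
   (Th = 35% by default) of the lesion's SUVmax.
2. **Metabolic / volumetric features** — SUVmax, SUVmean, MTV (cm³),
   TLG = SUVmean · MTV, COV = SD/SUVmean, and asphericity

   ASP = ( S³ / (36π V²) )^⅓ − 1,

   zero for a perfect sphere (S and V measured on one anti-aliased
   iso-surface of the mask).
3. **First-order histogram features** — bias-corrected sample skewness

   SKE = n/((n−1)(n−2)) · Σ(xᵢ−x̄)³ / SD³,

   bias-corrected excess kurtosis

   K = n(n+1)/((n−1)(n−2)(n−3)) · Σ(xᵢ−x̄)⁴ / SD⁴ − 3(n−1)²/((n−2)(n−3)),

   and empirical Shannon entropy E = −Σ p(xᵢ) log₂ p(xᵢ) of the binned
   in-mask SUV histogram.
4. **GLCM texture** — in-mask SUV is discretized to G gray levels, voxel
   pairs at unit displacement are accumulated (13 directions in 3D, or 4
   in-plane) into a normalized co-occurrence matrix P(i,j), from which
   contrast Σ|i−j|²P, correlation Σ(i−μᵢ)(j−μⱼ)P/σᵢσⱼ, energy ΣP², and
   homogeneity ΣP/(1+|i−j|) are computed.
5. **Cohort statistics** — Shapiro–Wilk normality screening, paired
   Wilcoxon signed-rank tests of pre vs post therapy (Z > 0 = decrease
   after therapy), Spearman correlations of every feature against clinical
   covariates with conventional strength bands
   (0.3 ≤ |R| < 0.5 moderate, 0.5 ≤ |R| < 0.7 strong, …), and
   Mann–Whitney U comparisons between outcome groups.

Because clinical scans cannot be redistributed, the package ships a
first-class phantom generator: ellipsoidal tumors with log-normal
Gaussian-random-field texture, focal hot spots, PSF blur and noise on a
4 × 4 × 5 mm grid, plus whole paired cohorts with clinical covariates and
*planted*, calibrated feature–covariate associations — so every pipeline
claim is testable against ground truth.

## Worked example

```python
import petromics as pm

spec = pm.PhantomSpec(suv_peak=12.0, heterogeneity_sd=0.5)
volume, truth = pm.generate_phantom(spec, seed=7)
features = pm.extract_features(volume, truth.true_mask.bounding_box(margin=3))
```

Running `python examples/01_single_tumor_features.py` prints:

```
true MTV        : 14.08 cm^3 (ground truth)
delineated MTV  : 14.00 cm^3 (35% threshold)
SUVmax / SUVmean: 16.35 / 10.12
TLG             : 141.7  (SUVmean x MTV)
COV             : 0.237 (SD/mean, heterogeneity index)
asphericity     : 0.017 (0 = perfect sphere)
entropy         : 5.56 bits (64-bin histogram)
GLCM            : contrast 3.49, correlation 0.46, energy 0.027, homogeneity 0.506
```

The delineated MTV lands within 1% of truth for this tumor: PSF blur pushes
the 35% level slightly outside the true edge while texture peaks raise
SUVmax (hence the threshold), and the two biases nearly cancel.

The other `examples/` scripts cover SUV conversion and NIfTI I/O, a full
cohort simulation + statistics run (with a planted COV–recurrence
correlation recovered and banded), and the sensitivity of MTV and texture
to the delineation threshold.

## Command line

```bash
petromics simulate --n-patients 30 --seed 1 --out cohort/
petromics extract  --input cohort/ --out features.csv
petromics analyze  --features features.csv --clinical cohort/clinical.csv --out report/
petromics run      --out results/ --n-patients 30 --seed 1   # all of the above
```

Exit codes: 0 success, 1 data error, 2 configuration error. All analysis
knobs (threshold fraction, gray levels, GLCM mode, entropy bins, recurrence
coding, alpha) live in a YAML config passed via `--config`.

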