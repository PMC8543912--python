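# Methods

`mbdwi` implements a complete multi-b-value diffusion-weighted MRI (DWI)
analysis for benign/malignant breast-lesion discrimination: voxel-wise
fitting of four diffusion signal models, radiomics feature extraction from
the resulting quantitative maps, and a paired comparison of radiomics-based
classifiers against lesion-mean diffusion metrics.  Because no patient data
ship with the package, a first-class synthetic-phantom module generates
cohorts with the statistical structure the analysis assumes; this note
documents the models, the generator, the numerical choices, and what the
bundled tests do and do not demonstrate.

## Signal models

For the normalized signal ratio S_b/S_0 at diffusion weighting b (s/mm²):

| model | equation | parameters |
|---|---|---|
| mono-exponential (ME) | exp(−b·ADC) | ADC (mm²/s) |
| biexponential IVIM (BE) | (1−f)·exp(−b·D) + f·exp(−b·D\*) | D, D\* (mm²/s), f ∈ [0,1] |
| stretched exponential (SE) | exp(−(b·DDC)^α) | DDC (mm²/s), α ∈ (0,1] |
| kurtosis (DKI) | exp(−b·D + b²·D²·K/6) | D (mm²/s), K ≥ 0 |

All four reduce exactly to the mono-exponential at their degenerate
parameter (f = 0, α = 1, K = 0); this is enforced by property tests.  The
kurtosis exponent turns upward at b = 3/(D·K); the forward function
evaluates everywhere, but the *fitted* model plateaus at the curve minimum
beyond the turnover, the standard way to keep the quadratic approximation
physical.  The conventional identifiability constraint D ≤ D\* is imposed
on IVIM parameters.

## Acquisition scheme

The default scheme is 13 b-values {0, 10, 30, 50, 100, 150, 200, 500, 800,
1000, 1500, 2000, 2500} s/mm² — a dense low-b segment to resolve perfusion,
a mid segment for tissue diffusion, and a high-b tail for non-Gaussian
behaviour.  It is a configurable stand-in for a clinical multi-b breast
protocol, not a claim about any particular scanner product sequence.

## Fitting

Volumes are pre-smoothed with a 3 mm-FWHM Gaussian (σ = FWHM/(2√(2 ln 2)),
converted per-axis to voxels via the voxel spacing; 3D isotropic in mm)
before pixel-by-pixel fitting.  Nine maps are produced: ME ADC_all-b (all
13 b) and ADC_0-1000 (b = 0 and 1000 only), IVIM D/D\*/f, SE DDC/α, DKI
D/K.

Numerical choices:

* **S0 is a free per-voxel scale** in every fit rather than being pinned to
  the measured b = 0 volume, so b = 0 noise does not propagate into all
  parameters.
* **ME** is closed-form log-linear least squares.  **DKI** is seeded by a
  log-quadratic linear fit, then polished by bounded trust-region least
  squares with an analytic Jacobian; it uses all 13 b-values.  **SE** is
  seeded from the ME solution with α = 0.9.
* **IVIM** uses the segmented strategy — D and an amplitude from the
  b ≥ 200 s/mm² mono-exponential tail, then (S0, f, D\*) with D fixed —
  whose output initializes a joint bounded refinement of all four
  parameters.  The joint polish makes noiseless recovery exact to the
  optimizer tolerance (a pure two-step fit leaves a few-percent bias in D
  because the perfusion term contaminates the high-b tail), while the
  segmented initialization keeps the refinement stable at realistic noise.
  A pure two-step mode (`segmented-raw`) and a joint-only mode (`full`)
  remain available.
* **IVIM b-range**: by default only b ≤ 1000 s/mm² enters the IVIM fit.
  Beyond ~1000 s/mm² the biexponential stops describing tissue signal
  (kurtosis effects), and at SNR ≈ 30 the high-b tail of fast-diffusing
  (benign) lesions sinks below the Rician noise floor, which would bias D
  downward class-dependently.  Configurable (`ivim_b_max`).
* **Bounds**: ADC/D/DDC ∈ [10⁻⁶, 4×10⁻³] mm²/s, D\* ∈ [D, 0.5] mm²/s,
  f ∈ [0,1], α ∈ (0,1], K ∈ [0,3].  Diffusivities are scaled to
  10⁻³ mm²/s internally for conditioning.
* Voxels with non-positive or non-finite b = 0 signal are flagged invalid
  (NaN in every map); radiomics masks intersect with the valid-voxel map.

Goodness of fit is R² = 1 − SS_res/SS_tot between observed and predicted
signals over the fitted b-subset.  The lesion-level QC rule excludes a
lesion when the mean R² over its mask is *strictly below* 0.8 (0.80 exactly
passes).

## Synthetic phantoms

Each subject is an ellipsoidal lesion (semi-axes drawn 4–9 mm in-plane,
3.5–6 mm through-plane; irregular margins via a correlated random
perturbation of the boundary radius) inside a smooth tissue "body", on a
32×32×14 grid at 1.5×1.5×2.5 mm.  Per-voxel ground-truth (D, D\*, f, S0)
fields are the subject-level draw modulated by spatially correlated
Gaussian random fields (correlation length 3 mm), and the noiseless signal
is generated from the IVIM forward model.  Because the signal is a mixture
of two exponentials with intra-lesion heterogeneity, the SE and DKI fits
are well-posed, and the expected class ordering (malignant: higher K, lower
α) emerges from the malignant class's lower D and higher f rather than from
an explicit kurtosis field.

Class-conditional defaults (subject-level means ± SD; chosen once from the
breast-DWI literature range, exposed in config, and *not* validated against
any patient cohort):

| parameter | malignant | benign |
|---|---|---|
| D (10⁻³ mm²/s) | 0.95 ± 0.15 | 1.55 ± 0.20 |
| D\* (10⁻³ mm²/s) | 9 ± 2 | 11 ± 2 |
| f | 0.10 ± 0.03 | 0.06 ± 0.02 |
| S0 (a.u.) | 500 ± 50 | 450 ± 50 |
| intra-lesion field (rel. SD) | 0.15 | 0.07 |
| boundary irregularity | 0.15 | 0.05 |

Noise is Rician — each voxel becomes √((S+n₁)² + n₂²) with n₁, n₂ Gaussian
of SD = (mean lesion S0)/SNR — because magnitude MR data is Rician and the
distinction matters in the low-signal high-b regime.  The default cohort is
542 subjects with 333 malignant (SNR 30); tests and the acceptance script
use a 200-subject cohort with the same 333:209 class ratio to stay at desk
scale.  Second-reader masks for reproducibility analyses are produced by
adding a correlated random offset (amplitude in mm) to the signed distance
transform of the lesion mask.

What the phantoms do **not** emulate: anatomy, coil sensitivity profiles,
EPI distortion, partial-volume fat, motion.  Passing tests therefore
demonstrate the correctness of the computational chain and its behaviour
under the stated statistical assumptions — not clinical performance.

## Radiomics

Each (map, lesion mask) pair yields exactly 100 features: 18 first-order,
14 3D shape, 22 GLCM, 16 GLRLM, 16 GLSZM and 14 GLDM, following the
standard published radiomics formulary; nine maps give 900 features per
subject, named `<map>__<group>__<feature>`.

* **Discretization**: fixed bin width per map, pinned so each map's
  physiological range spans ≈ 25 bins (e.g. 1.6×10⁻⁴ mm²/s for
  diffusivity maps, 0.12 for K); recorded per run.
* **Texture geometry**: 26-connectivity; GLCM and GLRLM features are
  computed per direction over the 13 unique offsets and averaged; GLSZM
  zones use 26-connected components; GLDM dependence counts the center
  voxel plus its |Δgray| ≤ 0 neighbors (sizes 1–27).
* **Shape**: surface quantities come from marching cubes on the zero-padded
  mask, with a σ = 0.6 voxel anti-aliasing smooth first — a raw binary
  mesh overestimates surface area by ~8–10% at any resolution (stair-step
  artifact), which would bias sphericity low; the smoothing costs < 1% in
  mesh volume.  Axis lengths are 4√λ of the physical-coordinate covariance
  eigenvalues.
* Single-voxel masks raise an error naming the undefined groups; the
  first-order Mean is identical to the lesion-mean metric of the same map.

The nine lesion-mean diffusion metrics (mADC_all-b, mADC_0-1000, mD, mD\*,
mf, mDDC, mα, mK, mD_kurt) are plain arithmetic means over the valid mask.

Inter-reader reproducibility uses ICC(2,1) — two-way random effects,
absolute agreement, single rater — computed in closed form from the ANOVA
mean squares, vectorized over features; features with ICC > 0.80 are
flagged reproducible, and zero between-subject variance yields NaN
(flagged, not silently dropped).

## Classification

The cohort is split 50/50 with exact stratification (542 → 271 train / 271
test).  Four scorers run per map on that identical split:

* **RF** — random forest, 100 trees, max depth 3, raw features (trees are
  scale-invariant).
* **L1R-LR** — standardized features, L1-penalized linear (logistic) model
  (C = 1); the penalty performs implicit feature selection, and the
  continuous score (not a hard label) feeds ROC analysis.
* **PCA-LR** — standardize → keep the 100 features with the lowest
  two-sample Mann–Whitney P values (training folds only) → 10 principal
  components → linear model.
* **SVM-RBF** — standardize → RBF SVM with C ∈ {0.1, 1, 10, 100} and
  γ ∈ {scale, 10⁻², 10⁻³} grid-searched by 3-fold CV on the training set;
  the decision margin is the score.

Repeated stratified k-fold CV (10 folds, reshuffled per repeat; 100 repeats
at full scale, fewer at desk scale) is used for stability and
feature-selection-frequency reporting; the reported test score comes from a
single model refit on the full training half.  Standardization, prefilter
and PCA are all refit inside each training fold — no test-set leakage, and
a dedicated test asserts that training artifacts are byte-identical
regardless of the test half.  RF feature importance is mean decrease in
impurity, normalized to sum 1, reported as a top-20 table per map.

## Evaluation

* **AUC** is the midrank Mann–Whitney statistic normalized by n₁·n₀ (ties
  half credit); verified against brute-force pair enumeration.
* **95% CI** by stratified bootstrap (resampling within class; 2000
  replicates by default, percentile interval, widened if needed to contain
  the point estimate).  Coverage measured at ≈ 95% over 500 simulated
  binormal datasets with known AUC.
* **Operating points** (sensitivity, specificity, PPV, NPV) at the
  Youden-index-maximal threshold of the same scores.
* **Paired comparisons**: McNemar's test compares classifications, not
  AUCs, so each method's continuous scores are dichotomized at its own
  Youden threshold; the test is exact binomial for ≤ 25 discordant pairs
  and continuity-corrected χ² above.  Comparisons are repeated over
  bootstrap resamples of the test half and the mean P value is reported;
  zero discordant pairs give P = 1.  The family-wise threshold is
  Bonferroni α/m with m = 23 comparisons by default (a configuration
  input — the package does not re-derive the comparison count).
* **Image quality** on the b = 2500 volume: SNR = mean lesion / SD
  background, CNR = (mean lesion − mean background)/SD background, contrast
  = mean lesion / mean background, with an automatically placed air-corner
  background box.  In signal-free background the noise is Rayleigh, whose
  SD is σ√(2 − π/2); the acceptance script rescales accordingly when
  comparing to the generator's σ-convention SNR target.

## Pipeline and problem sizes

`run_pipeline` executes simulate → fit → features → classify → evaluate
under one run directory; every stage reads/writes plain files (NIfTI, CSV,
JSON), a manifest records artifact checksums and the configuration hash,
stages are resumable, and every random draw descends from the single config
seed (two runs with equal configs are numerically identical).

The bundled analyses run at desk scale as the package's own choice of
problem size: the numbered scripts use a 60-subject cohort with five CV
repeats; the acceptance script and the cohort-level tests use 200 subjects
(123 malignant, matching the 333:209 ratio), 1000 bootstrap replicates, and
500 coverage simulations.  The full-scale configuration (542 subjects, 100
CV repeats, 2000 replicates) is a config change, not a code change.

## Known limitations

* Radiomics feature values follow the standard formulary but are not
  certified bit-identical to any specific extraction package (binning and
  aggregation conventions differ subtly between implementations).
* The segmented IVIM D estimate retains a small positive bias under heavy
  smoothing near lesion boundaries (partial volume with the body
  compartment); the classification analyses are unaffected because all
  subjects share the processing.
* The ME ADC_all-b map is noise-floor biased at b ≥ 1500 by construction of
  magnitude noise; this mirrors real acquisitions and is why the
  ADC_0-1000 variant exists.
* McNemar-on-dichotomized-scores is one of several defensible bridges from
  continuous scores to a paired test; the dichotomization rule and the
  comparison count m are parameters, not claims.
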