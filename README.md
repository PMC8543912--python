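# mbdwi — multi-b-value diffusion MRI radiomics for breast-lesion classification

`mbdwi` is an end-to-end analysis package for quantitative multi-b-value
diffusion-weighted MRI (DWI) of breast lesions.  It addresses a practical
question in breast imaging: given a multi-b acquisition (13 b-values,
0–2500 s/mm²) and a 3D lesion segmentation, do high-dimensional radiomics
features computed from quantitative diffusion maps separate benign from
malignant lesions better than the lesion-mean diffusion metrics
radiologists conventionally read?

It is written for imaging scientists who want a tested, reproducible
implementation of the full chain:

1. **Signal models** — the four standard descriptions of diffusion decay
   S_b/S_0: mono-exponential `exp(−b·ADC)`; biexponential intravoxel
   incoherent motion `(1−f)·exp(−b·D) + f·exp(−b·D*)`; stretched
   exponential `exp(−(b·DDC)^α)`; and diffusion kurtosis
   `exp(−b·D + b²D²K/6)`.
2. **Voxel-wise fitting** — 3 mm-FWHM Gaussian pre-smoothing, bounded
   nonlinear least squares with a free per-voxel S0, producing nine maps
   (ADC_all-b, ADC_0-1000, D, D\*, f, DDC, α, K, D_kurt) with per-model R²
   maps and an R² ≥ 0.8 lesion QC gate.
3. **Radiomics** — exactly 100 features per (map, lesion) pair
   (18 first-order / 14 shape / 22 GLCM / 16 GLRLM / 16 GLSZM / 14 GLDM),
   900 per subject, plus the nine lesion-mean metrics and inter-reader
   ICC(2,1).
4. **Classification** — stratified 50/50 split (542 → 271/271 at full
   scale), four scorers per map (random forest with 100 trees / depth 3,
   L1-regularized linear model, rank-filter + 10-component PCA + linear
   model, grid-searched RBF SVM), repeated stratified 10-fold CV, and RF
   mean-decrease-in-impurity feature importances.
5. **Evaluation** — midrank AUC with stratified-bootstrap 95% CIs, Youden
   operating points (sensitivity/specificity/PPV/NPV), paired McNemar tests
   at Bonferroni-adjusted significance (0.05/23 = 0.00217), and b=2500
   image-quality metrics (SNR/CNR/lesion contrast).

No patient data are included: a first-class synthetic-phantom module
generates labeled cohorts (ellipsoidal textured lesions, class-conditional
IVIM parameters, Rician noise at SNR ≈ 30, default 542 subjects with
333 malignant) whose ground truth makes every stage testable.  See
`docs/methods.md` for models, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the study at desk scale
(60 subjects, 37 malignant, SNR 30; seed 7) and write their tables to
`results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_parameter_maps.py
python analysis/03_extract_features.py
python analysis/04_classify.py
python analysis/05_evaluate.py
```

Output of the last step:

```
held-out AUC per map (RF radiomics vs lesion-mean metric):
method      mean_metric     rf
image_set
ADC_0-1000        0.976  0.976
ADC_all-b         0.976  1.000
D                 0.990  0.952
D*                0.823  0.885
DDC               0.976  0.981
D_kurt            0.957  0.976
K                 0.943  0.952
alpha             0.837  0.888
f                 0.431  0.727
Bonferroni-adjusted significance threshold: 0.00217 (alpha=0.05, m=23)
```

Reading the table: each row is one of the nine quantitative maps; `rf` is
the held-out AUC of a random forest trained on that map's 100 radiomics
features, `mean_metric` the AUC of the single lesion-mean value of the same
map.  On this synthetic cohort the diffusivity maps separate classes
almost perfectly by construction (the generator draws malignant
D = 0.95±0.15 vs benign 1.55±0.20 ×10⁻³ mm²/s), while weakly informative
maps such as the perfusion fraction f show the expected gap in favour of
radiomics (0.727 vs 0.431).  Earlier stages print the fit quality (mean R²
0.98–0.999 per model, no QC exclusions at SNR 30), the 60×900 feature
matrix, second-reader ICCs (100/100 IVIM-D features above 0.80), and the
top-20 RF features of the IVIM-D map.

The same pipeline is scriptable through one config:

```bash
mbdwi run-all --config config.yaml --out run/
mbdwi simulate --n 542 --n-malignant 333 --snr 30 --seed 1 --out run/
```

## Layout

```
src/mbdwi/            library: signal_models, fitting, synthetic,
                      radiomics/, classification, evaluation, pipeline, cli
analysis/             numbered narrative drivers (desk-scale study)
results/              tables written by the analysis + acceptance outputs
tests/                pytest suite (unit, property and acceptance tests)
docs/methods.md       models, defaults, numerical choices, limitations
```
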