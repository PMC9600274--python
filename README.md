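# hcc-radiomics

Radiomics texture analysis for non-invasive grading of hepatocellular
carcinoma (HCC) from volumetric MRI maps.

HCC histologic grade (well / moderately / poorly differentiated,
Edmondson–Steiner) strongly conditions treatment and prognosis, but the
pre-operative gold standard is biopsy. This package implements the
image-analysis alternative: per lesion, two co-registered 3D scalar maps —
an apparent-diffusion-coefficient (ADC) map in 10⁻³ mm²/s and a
portal-venous-phase enhancement (VE) map — are sampled inside a binary
lesion mask, reduced to a 95-feature texture panel, and fed to a random
forest that predicts grade. The question the pipeline answers is whether
spatial texture adds grading information over the two masked means (mean
ADC, mean VE) alone.

## What is computed

**Discretization.** Within-mask intensities are relabeled to Ng ∈
{16, 32, 64, 128, 256} gray levels by equal-width min–max binning,
`label(v) = ⌊Ng·(v−m)/(M−m)⌋ + 1` (default operating point Ng = 64).

**Feature panel (95).** 9 global features (masked mean/max/min of each
map; mask solidity, surface area, volume) and, per map, 43 texture
features: 3 histogram moments, 9 gray-level co-occurrence (GLCM, four
in-plane directions pooled), 13 run-length (GLRLM), 13 size-zone (GLSZM,
26-connected 3D zones), and 5 neighborhood gray-tone difference (NGTDM:
coarseness, contrast, busyness, complexity, strength). Run
`hcc-radiomics feature-dictionary` for the full list.

**Classification and evaluation.** Bagged Gini CART trees (500 trees,
minimum leaf 9, mtry 44 clipped to the predictor count). Evaluation is
out-of-bag (OOB): misclassification rate with its error-vs-trees curve,
well-vs-rest ROC AUC by the Mann–Whitney identity with a DeLong
confidence interval, and variable importance as the mean minimal depth of
the shallowest split on each predictor (smaller = more important). The
mean-only baseline (2 predictors) and the full 95-feature model are
compared with the DeLong test for correlated ROC curves and a chi-square
test on OOB misclassification counts, for a two-class task (well vs
moderate/poor) and a three-class task.

**Synthetic phantoms.** Patient MRI of this kind is not publicly
deposited, so the package ships a phantom generator producing 3-class
cohorts of masked ADC/VE lesion pairs: deformed-ellipsoid masks and
Gaussian random fields whose class means and spatial correlation lengths
are controlled independently. Two pre-registered regimes — `mean+texture`
(both signals) and `texture-only` (equal class means, texture signal
only) — make the pipeline's claims testable end to end.

## Worked example

```bash
hcc-radiomics simulate --preset texture-only --n-per-class 30 --seed 7 --out scratch/demo
hcc-radiomics run --preset texture-only --n-per-class 60 --task multi --seed 7 --out scratch/demo_run
```

or, through the analysis drivers (`analysis/01…04`), which print e.g.:

```
mean+texture / multi_class (n=171): OOB error 0.380 -> 0.082, AUC 0.879 -> 0.961 (DeLong p=7.6e-05)
texture-only / multi_class (n=180): OOB error 0.700 -> 0.144, AUC 0.469 -> 0.943 (DeLong p=5.44e-24)
```

Read: on the mean+texture cohort the mean-only baseline misclassifies 38%
of lesions out-of-bag and the full panel cuts that to 8%, raising the
well-vs-rest AUC from 0.88 to 0.96; on the texture-only cohort the
baseline is at chance (AUC ≈ 0.5, error ≈ 2/3) while the radiomics model
still recovers grade from texture alone — the constructed-signal check
that the panel measures spatial structure, not just intensity level.

`analysis/03_ng_sweep.py` repeats the comparison at each Ng and writes
`results/ng_sweep.csv`; `analysis/04_compare_models.py` also writes the
top-5 minimal-depth predictors per model (`results/top_predictors.csv`).

## Layout

- `src/hcc_radiomics/` — library: `io_model` (NIfTI/CSV data model),
  `synthetic` (phantom cohorts), `discretization`, `texture/` (matrices,
  features, panel), `forest` (training, OOB metrics, DeLong, importance),
  `study`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite, including brute-force oracle cross-checks of
  every texture matrix and feature formula.
- `docs/methods.md` — model, parameter and design documentation.
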