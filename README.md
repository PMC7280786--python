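# brainage

Multimodality brain-age modelling for tabular imaging-derived phenotypes
(IDPs): predict chronological age in healthy adults from six MRI modalities
with L1-penalized regression, select robustly informative phenotypes by
bootstrap confidence intervals, correct the regression-to-the-mean age bias
to form **brain-PAD** (brain-predicted age difference), quantify each
modality's contribution by ablation, and test brain-PAD against biomedical,
lifestyle and cognitive variables with FDR control.

The package is aimed at researchers analyzing population-imaging IDP tables
(subjects × phenotypes, each phenotype tagged T1, T2-FLAIR, T2*, dMRI,
task fMRI or rsfMRI).  Because such cohort data are access-restricted, a
first-class synthetic cohort generator with known ground truth makes every
stage testable end to end.

## The model

With normalized phenotypes x (training-set mean/SD, frozen) and age y, the
age model solves

    min  (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)²  +  λ Σⱼ |βⱼ|

with λ chosen by 10-fold cross-validation under the one-standard-error rule
(**λ.1se**: the largest penalty within one SE of the CV minimum).  1000
bootstrap resamples refit at the fixed λ.1se; a phenotype is *informative*
when its 95% basic-bootstrap interval [2β̂ − q₀.₉₇₅, 2β̂ − q₀.₀₂₅] excludes
zero.  Raw predictions ŷ regress to the mean, so the training-set OLS line
ŷ = b₀ + b₁·age is inverted — corrected = (ŷ − b₀)/b₁ — and

    brain-PAD = corrected prediction − age   (years; positive = older-appearing)

which is exactly uncorrelated with age on the bias-fitting cohort.
Associations are per-variable OLS of brain-PAD on the variable plus age,
age², sex, height, volumetric scaling and head motion, with
Benjamini–Hochberg FDR across the panel and partial η² = t²/(t²+df) effect
sizes.  See `docs/methods.md` for the full account.

## Worked example

```python
from brainage import (
    RunConfig, run_all,
    SimulationConfig, generate_cohort, screen_healthy, split, SplitSpec,
    train_age_model, predict_raw, fit_bias, brain_pad_table, metrics,
)

pheno, cohort, truth = generate_cohort(SimulationConfig(n_subjects=3000, seed=11))
healthy, excluded = screen_healthy(cohort)
train_ids, val_ids = split(healthy, SplitSpec(train_fraction=0.8, seed=12))

cv, model = train_age_model(pheno, cohort, train_ids, seed=13)
print(model.n_nonzero, round(model.lambda_, 3))
# 34 0.443

raw_val = predict_raw(model, pheno, val_ids)
print(metrics(cohort.ages(val_ids), raw_val.to_numpy()))
# PerformanceMetrics(r=0.878, r2=0.771, mae=4.258, age_bias=-0.700, n=478, ...)

bias = fit_bias(cohort.ages(train_ids), predict_raw(model, pheno, train_ids).to_numpy())
pad = brain_pad_table(cohort.data.loc[val_ids, "age"], raw_val, bias)
```

Of 1079 phenotypes the penalized fit keeps 34; held-out age prediction
reaches r = 0.88 with a mean absolute error of 4.3 years, and the raw
predictions show the expected negative age bias (r = −0.70) that the
correction removes.  `pad["brain_pad"]` then holds per-subject
brain-PAD values in years, ready for association testing with
`brainage.run_panel`.

The same analysis runs end to end from one config:

```sh
brainage run-all --seed 11 --out-dir runs/demo
```

writing the phenotype/cohort tables, the model artifact (`model.json`), the
informative-phenotype table, per-modality and leave-one-modality-out
performance tables, the association table and a reproducibility manifest.
Individual stages are also exposed (`brainage simulate|screen|split|fit|
bootstrap|evaluate|ablation|associate`).

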