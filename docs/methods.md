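# Methods

## The problem

Brain-age models learn to predict chronological age from neuroimaging
features in healthy people; applying the model to new individuals yields a
*brain-predicted age*, and the gap between corrected prediction and true age
(brain-PAD, in years) indexes apparently accelerated or decelerated brain
aging.  This package implements the full multimodality tabular-phenotype
version of that analysis: six MRI modalities contribute a fixed inventory of
imaging-derived phenotypes (IDPs) — 165 T1-weighted, 1 T2-FLAIR
(white-matter-hyperintensity volume), 14 T2*, 675 diffusion-MRI, 14 task
fMRI, and 210 resting-state connectivity values (the 21·20/2 distinct
network pairs of a 21-network partial-correlation matrix), 1079 in total.

## Pipeline

1. **Screening.** A subject enters the healthy model-building cohort only if
   no exclusion fires: ICD-10 diagnosis flag, self-reported long-standing
   illness, diabetes, stroke history, or self-rated health worse than good.
   Reasons are reported in that fixed order (first match).
2. **Split.** Seeded random 80/20 train/validation partition of the healthy
   set, round-half-up sizing.
3. **Normalization.** Each phenotype is centered and scaled (sample SD,
   n−1) using training-set statistics only, frozen for all later use;
   zero-variance phenotypes are dropped and missing values mean-imputed
   (exactly 0 after scaling), with counts logged.  Freezing on the training
   split is the leakage-safe reading of "normalize then model".
4. **Age model.** LASSO on the normalized phenotypes with age (years) as
   outcome, objective (1/2n)·Σ(yᵢ−β₀−xᵢᵀβ)² + λ·Σ|βⱼ|.  The λ grid has 100
   log-spaced values from λ_max (the smallest penalty that zeroes every
   coefficient, max_j|x_jᵀ(y−ȳ)|/n) down to 10⁻³·λ_max.  Ten-fold CV (seeded
   random fold assignment, no stratification; fold-level mean-squared error;
   SE across the 10 fold errors) selects **λ.1se**, the largest grid value
   within one SE of the CV minimum; the final model is refit on all training
   rows at that penalty.
5. **Bootstrap selection.** 1000 resamples by default (200 in the reference
   study below), each refit at the *fixed* λ.1se.  Per phenotype the 95%
   basic-bootstrap interval is [2β̂ − q₀.₉₇₅, 2β̂ − q₀.₀₂₅], with β̂ the
   full-data coefficient and q the resample quantiles (type-7 linear
   interpolation).  Resamples in which a phenotype is shrunk to zero
   contribute genuine zeros.  A phenotype is *informative* iff its interval
   excludes zero.  Holding λ fixed across resamples costs 10× less than
   re-running CV per resample and isolates sampling variability of the
   coefficients from penalty-selection variability; the alternative is
   available as `bootstrap_lasso(..., refit_lambda=True)` / `--refit-lambda`.
6. **Bias correction and brain-PAD.**  Raw predictions regress to the mean
   (negative corr(age, prediction−age)).  On the training cohort the OLS
   line of raw prediction on age gives (intercept b₀, slope b₁); corrected
   predictions are (raw − b₀)/b₁ and brain-PAD = corrected − age.  Because
   OLS residuals are orthogonal to the predictor, corr(age, brain-PAD) is
   exactly zero on the fitting cohort — asserted to 1e-10 as the module's
   theorem-like check.  Reported accuracy: Pearson r, R² = r² (squared
   correlation, not 1−SSE/SST), MAE in years, and the raw age bias
   corr(age, prediction−age).
7. **Ablations.**  Single-modality models (each modality's columns only) and
   leave-one-modality-out models, each with its own CV, evaluated on the
   validation set, plus the cross-modality correlation matrix of predicted
   ages.  Ablation CVs use a shallower grid (60 values to 10⁻²·λ_max): the
   chosen penalty sits near 0.07·λ_max, and model-level comparison does not
   need the deep tail of the path, which dominates solver cost.
8. **Associations.**  For each panel variable, OLS of brain-PAD on the
   variable plus covariates age, (age−mean)², sex (0=F, 1=M), height,
   volumetric scaling and head motion; complete-case per variable, with
   "prefer not to answer" codes (alcohol −3) removed.  Binary variables are
   0/1 (estimate = adjusted group difference in years); smoking status and
   alcohol frequency enter as single ordinal integer codes.  Effect size is
   partial η² = t²/(t²+df_resid).  p-values are Benjamini–Hochberg adjusted
   across the 18-variable panel.

## Synthetic cohort generator

The generator emulates a population-imaging cohort so that every stage has
recoverable ground truth.

* **Ages** uniform on 45–80 y.  **Latent brain age** B = age + Σ effects +
  δ, δ ~ N(0, 3.5²).  The 3.5-year latent SD matches the MAE scale
  (3.5–4.5 y) such healthy-cohort models achieve.
* **Injected effects** (years of latent brain age, native codings):
  diabetes +2.115 (prevalence 5.72%), stroke +2.695 (1.37%), smoking
  +0.879 per code (never/previous/current = 0/1/2), alcohol −0.997 per
  code relative to "never" (codes 1–6 inverted, −3 = refusal at 1%),
  diastolic 0.049 and systolic 0.028 per mmHg above the mean.
* **Phenotypes.**  34 informative IDPs load on the standardized latent
  z = (B − 62.5)/10.1: 11 T1, 19 diffusion, 1 T2*, 2 task fMRI, 1
  resting-state; the single T2-FLAIR phenotype is noise.  Within a modality
  the loadings share one magnitude with alternating signs (T1/dMRI 0.36,
  T2* 0.52, rsfMRI 0.58, task 0.28) plus unit noise.  Equal magnitudes
  matter: the informative IDPs are exchangeable proxies of one latent, and
  with a magnitude gradient the penalized selector concentrates stably on
  the strong members and never the weak tail, so no calibration of a
  graded set can make all members stably selectable (a design study showed
  sensitivity saturating near 0.68 for graded loadings at any overall
  scale, vs ≈0.9 for flat ones).  Aggregate signal orders the modalities
  dMRI > T1 ≫ rsfMRI > T2* > taskfMRI > T2-FLAIR.  Uninformative
  phenotypes are pure noise with within-modality equicorrelation 0.3, which
  exercises the penalized fit under collinearity — the situation the
  bootstrap step exists for.
* **Covariates and outcomes.**  Sex-specific heights, volumetric scaling,
  head motion mildly correlated with the latent offset (+0.002·(B−age));
  cognitive scores are generated *from* the latent offset (fluid
  intelligence slope −0.025, alphanumeric-trail duration +7.2, matrix
  puzzles −0.078, tower puzzles −0.042, each plus noise) so an
  older-appearing brain scores worse; BMI, weight, hip circumference,
  facial aging, activity durations, numeric-trail and matrix-duration
  scores are null controls.  Screening fields (ICD-10 3%, long-standing
  illness 3%, self-rated health 25/65/8/2%) are drawn independently.
* **Randomness.**  One seed feeds named `SeedSequence` child streams (age,
  screening, outcomes, latent, phenotypes, covariates, cognitive), so any
  config reproduces bit-for-bit.

What the generator does **not** emulate: realistic spatial covariance among
IDPs (only block equicorrelation), measurement batch effects, non-linear
age trajectories, correlated screening/health structure, longitudinal data.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability under a faithful-but-idealized data-generating
process, not performance on real cohort data.

## Reference study conditions

The bundled reference study (`brainage.study.run_reference_study`, also
driven by `scripts/acceptance.py`) uses n = 3000 subjects (≈1900 train /
≈480 validation after screening), the full 1079-phenotype inventory, 200
bootstrap resamples, and a fresh n = 5000 cohort for the association panel.
These sizes keep a complete run in the ten-minute range on one CPU while
leaving all effects well-identified.  Typical results at these conditions:
validation r ≈ 0.87–0.88 (MAE ≈ 4.3 y, raw age bias ≈ −0.7), 34 nonzero
coefficients at λ.1se, bootstrap selection sensitivity ≈ 0.9 with precision
1.0, diabetes/stroke effects recovered within 2 SE.

## Numerical choices

* Coordinate descent via scikit-learn; duality-gap tolerance 1e-8 for
  single-penalty fits (final model, every bootstrap refit) and 1e-4 for the
  CV fold paths, which only rank penalties (the deep-grid tail at 1e-8
  costs two orders of magnitude more solver time for no change in the
  selected λ).  Max 2·10⁵ iterations.
* λ grid log-spaced; ties in the CV minimum resolve to the larger λ.
* Quantiles are type-7 (linear interpolation) throughout.
* Degenerate correlations (zero variance) are reported as 0 with an
  explicit `degenerate` flag rather than raising inside batch runs.
* Split sizing is round-half-up; both sides of a split are kept non-empty.
* The association design centers age before squaring (conditioning only)
  and refuses condition numbers above 1e10.
* Subject ids are opaque strings; all tabular IO is TSV/CSV with `NA`/empty
  as missing; artifacts (model, normalization, manifest) are JSON with
  sorted keys so equal seeds give byte-identical files.

## Known limitations

* Stable selection of a *graded* redundant informative set is intrinsically
  partial (see above); the generator's equal-magnitude design is the
  regime in which full recovery is a meaningful target.
* The 1-SE rule is conservative; on data with many weak redundant signals
  the main fit can be sparser than the univariately-significant set by an
  order of magnitude — expected behavior, not a defect.
* Exact reproduction of any particular cohort's split sizes or headline
  accuracy on restricted real data is out of scope; single-modality
  calibration is qualitative (ordering), not quantitative.
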