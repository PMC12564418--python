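# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical conventions, and the design decisions that were genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem and the data model

Two-class origin authentication from mid-IR absorbance spectra.  Each
observation is a spectrum on a uniform instrument grid (2 cm⁻¹ spacing,
600–4000 cm⁻¹ by default); each physical sample contributes three
replicate spectra that are arithmetically averaged into one modelling row,
giving the matrix `X (n × p)` with a binary label per row (1 = target
origin).  Wavenumbers are stored ascending; descending files are flipped
on ingestion.  Region selection uses closed intervals; the two standard
windows are the fingerprint region (1800–600 cm⁻¹; the 1800–850 variant is
expressible through `RegionSpec`) and the whole mid-IR window (4000–650
cm⁻¹), both minus the atmospheric CO₂ (2390–2250 cm⁻¹) and water-vapour
(3400–3200 cm⁻¹) bands.  Excising bands leaves gaps in the axis;
axis-dependent filters (Savitzky–Golay, median) therefore operate per
contiguous uniformly spaced segment and never bridge a gap.  No resampling
is performed; mixed grids are an error.

## Synthetic data generator

The study's spectra are not public, so the generator reproduces the
*statistical* structure every stage assumes:

* a library of 14 Gaussian bands at the standard pork-tissue positions
  (3285, 2955, 2920, 2850, 1650, 1540, 1450, 1400, 1330, 1240, 1080, 1030,
  970, 920 cm⁻¹) with widths 8–60 cm⁻¹ and amplitudes 0.1–1.0 AU;
* class-specific intensity: bands reported stronger in the target class
  carry a ×1.15 amplitude factor for class 1 (×1.05 for marginal trends),
  bands stronger in the other class the reciprocal.  1.15 was chosen once
  as "clearly detectable but preprocessing-sensitive": large enough that a
  well-validated model separates the classes, small enough that scatter
  and baseline artifacts matter;
* per-sample artifacts: a linear baseline (offset sd 0.02 AU, slope sd
  5 × 10⁻⁶ AU/cm⁻¹) and a log-normal multiplicative scatter factor
  (log-sd 0.05), emulating pathlength/contact variation;
* per-replicate artifacts: white noise (sd 0.005 AU) and a smooth baseline
  wiggle (sd 0.003 AU, ~50 cm⁻¹ correlation length) standing in for
  repositioning drift between replicate acquisitions.

Defaults are 40 samples per class × 3 replicates.  `null_dataset` forces
every class effect to 1, producing label-free structure for type-I-error
calibration.  What the generator does **not** emulate: Lorentzian/Voigt
line shapes, ATR optics, water-vapour rotational fine structure,
instrument drift across a measurement campaign, and biological covariance
between bands.  Tests passing on this generator therefore demonstrate the
*pipeline's* correctness and calibration, not performance on real meat.

## Preprocessing conventions

* SG derivatives: window 11 / polyorder 2 (1st), window 15 / polyorder 3
  (2nd) — common practice at 2 cm⁻¹ spacing; derivatives are scaled by the
  grid step (units AU per cm⁻¹).
* "Deresolve" is an ambiguous name in the field.  Here it means SG
  smoothing followed by a first derivative ("derivative with smoothing");
  the other reading — deliberate resolution degradation by band
  broadening — is *not* implemented.
* SNV uses the n−1 standard deviation.  MSC regresses each spectrum on the
  training-mean reference; slope magnitudes below 1e-10 are an error.
* Detrend removes the least-squares polynomial (degree 1 alone, degree 2
  inside SNV+detrend, the Barnes convention); degree 0 is mean-centring.
* Median filter: width 5, reflect padding.
* Quantile normalization maps each row's ranks onto the mean-of-sorted
  training reference, averaging reference values over ties.  It is fit on
  training rows only; whether the original study fit it per split is
  unknowable, so the leakage-safe choice is the default.
* OSC: Wold-style NIPALS, one component by default.  The removed score is
  re-orthogonalized against y before deflation, so removed components are
  exactly y-orthogonal.  Components with vanishing variance stop the
  extraction early with a warning.
* ATR correction scales each column by ν/ν_ref (default ν_ref = 1000
  cm⁻¹), compensating the wavelength-proportional penetration depth.
* MSC, OSC and quantile carry fitted state; `apply_pipeline` fits them on
  the training partition only and applies the frozen state to held-out
  rows.  All other transforms are row-local.

## PCA, T², Q, outliers

SVD on column-centred data; deterministic sign (largest-magnitude loading
element positive).  Explained-variance fractions come from the full
singular spectrum, so they sum to 1 over all min(n−1, p) components.
T² uses the training-score covariance (n−1); Q is the squared norm of the
off-model residual.  Outliers: either statistic above its training
mean + 3 SD; thresholds are computed on the same rows the model was fit
on, which is the empirical rule as stated.  The screening model's
component count defaults to the smallest A reaching 95% cumulative
variance, capped at 10.  Screening runs once per (preprocessing × region)
cell, before classification.

## SIMCA

Per-class PCA (component count: ≥ 90% class variance, cap 10, or an
explicit per-class map).  Distance to class k is √Q_k; argmin assigns the
class, ties (to machine equality) go to class 0 with a warning.  Coomans
plots use the empirical 95th percentile of each class's own training
distances as the boundary — the boundary definition was open, and a
percentile matches the "soft" character of the method without
distributional assumptions.

## Discriminants

Both hybrids z-score every column (training mean/sd, sd floor 1e-12),
reduce to at most 10 components — PCA scores, or PLS1 X-scores against the
0/1 label (scikit-learn's `PLSRegression`) — and apply a two-class LDA
with pooled within-class covariance, closed form `S_w⁻¹(μ₁ − μ₀)` and
frequency priors.  A singular `S_w` is ridge-regularized by 1e-8 · mean
diagonal with a warning.  Two classes give exactly one canonical axis;
score plots pair LD1 with the first reducer score, since an "LD1 vs LD2"
plot does not exist for a binary problem.

## PLSR and VIP

NIPALS PLS1 on mean-centred data (no variance scaling — scaling belongs
to the LDA workflows).  The LV count is selected by leave-one-out RMSE
over candidates 1..15 (cap configurable up to min(n−1, p)); each LOO fold
refits the full NIPALS path once and reads predictions at every candidate
count, so selection costs n fits, not n × 15.  Ties take the smaller
count.  β = W(PᵀW)⁻¹q reproduces training predictions exactly.  VIP uses
the standard Wold form with normalized weights under the square root;
s_a is the y-variance absorbed by LV a (q_a²·t_aᵀt_a).  This guarantees
mean(VIP²) = 1, which the "VIP > 1" screening convention presupposes.
Classification assigns class 1 when ŷ > 0.5 (strictly above), the rule
consistent with the 0/1 coding of the response; predictions of exactly
0.5 fall to class 0.

## SVR

`sklearn.svm.SVR`, RBF kernel, grid C {0.1, 1, 10, 100} ×
ε {0.01, 0.1, 0.5, 1.0} × γ {scale, auto} (the conventional definitions
1/(p·var X) and 1/p; the names were used without definition), 5-fold CV
with seeded shuffling, mean R² selection (first maximum wins ties).
A constant-target fit reports R² = 0 with a warning.  LOO RMSE is
computed at the selected hyperparameters only; re-selecting the grid
inside every fold is not done (the excluded-row evaluation does re-select
on its training partition).  Permutation importance: scikit-learn's, R²
scoring, 10 repeats, negatives reported as-is; top-30 by mean.  Note that
importance scored on the training rows is positively biased for every
column (the kernel memorizes training points); unbiased attributions
should score held-out rows.

## ANN

MLP with ReLU/Adam over layouts (50), (100), (50, 20), (100, 50),
(50, 30, 10) × iteration caps 1000/2000/3000.  Training is a manual
minibatch-epoch loop (batch 32, learning rate 0.01 — small-sample
defaults) with early stopping on the log-loss of a stratified 10%
validation split: patience 15 epochs, an improvement counts only if it
beats the best loss by 10% relative (1e-4 absolute floor), best-epoch
weights are restored, and training stops outright once validation loss
falls below 1e-3.  Loss-based stopping is deliberate: a validation
*score* saturates long before the probabilities do and truncates training
on small n.  When early stopping fires below an iteration cap, the larger
caps for the same layout would reproduce the identical trajectory and are
not retrained.  Candidate selection: smallest validation loss; ties to
the smaller network, then the smaller cap.  Metrics: the eight-metric
report with probability clipping at 1e-12 in the cross-entropy; AUC is
undefined (NaN) on single-class data.

ROI mapping was not specified by its source beyond the name; the
implementation jointly permutes sliding blocks of 11 contiguous columns
(~22 cm⁻¹), records the mean log-loss increase over seeded repeats at the
block centre, floors negatives at 0 and normalizes to max 1.  Block (not
single-column) permutation is essential on spectra: neighbouring columns
are nearly collinear, and permuting one at a time attributes importance
to none of them.

## Validation

Training (resubstitution), LOO (the entire model — stateful preprocessing
included — is refit n times), and the Venetian blind: excluded = 0-based
indices with i mod 3 == 2, i.e. 1-based positions 3, 6, 9 …, exactly a
third when 3 | n.  "Every 3rd entry" is ambiguous about the anchor, so the
offset is configurable.  Replicate averaging precedes splitting, matching
the definition of the modelling matrix.  Factories close over the
training partition, so held-out rows can never reach any fitted state;
a sentinel-poisoning test asserts this.

## The factorial experiment

11 preprocessing × 2 regions × 7 model families × 3 schemes on the
replicate-averaged, region-masked data.  Per cell: preprocess (fit on all
cell rows) → T²/Q screening → drop flagged rows → per-model evaluation
with fold-local preprocessing refits.  Costs are kept linear by three
choices documented as the package's own: PLSR LOO selection reuses one
NIPALS path per fold; SVR LOO runs at the selected hyperparameters; the
ANN is architecture-selected once per cell on the calibration rows and
the winning architecture is refit for the excluded-row scheme (LOO for
the ANN is not tabulated).  Per-cell seeds derive from the global seed by
CRC32 of `"{seed}:{region}:{preprocess}"`, masked to 31 bits, so any cell
reruns identically in isolation.  With the default synthetic dataset the
full factorial takes on the order of two minutes on one CPU and is
byte-identical across reruns with the same seed.

Problem sizes used by the test suite are scaled to the property under
test: model-behaviour checks run on 120–160 samples with 15–80 features
(or generator grids coarsened to 4 cm⁻¹), which is ample for the
contrasts asserted (8σ separation vs. null) while keeping the suite
fast; the factorial determinism check runs the full default conditions.

## Known limitations

* Two classes only throughout (SIMCA, LDA, PLS1).
* The empirical mean + 3 SD outlier rule has a nonzero false-flag rate by
  construction (a heavy-tailed statistic exceeds mean + 3 SD more than
  0.1% of the time); no distributional T²/Q limits are provided.
* Nested cross-validation is not implemented: hyperparameter selection and
  error estimation share data in the SVR/ANN workflows, so reported
  excluded-set numbers are mildly optimistic.
* JCAMP-DX support covers AFFN XYDATA/XYPOINTS only; compressed ordinate
  dialects raise an explicit unsupported-feature error.
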