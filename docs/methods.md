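# Methods

This note records the models, conventions, and numerical choices behind
`fmsc`, and what the synthetic validation does and does not establish.

## Networks

All three network types are Pearson-correlation matrices over a fixed,
ordered parcellation. Region order is canonical per study (taken from the
parcellation, never sorted), so an edge index refers to the same region pair
for every subject, fold, and report.

**Morphometric similarity (MSN).** Anatomical measures live on wildly
different scales (surface area in hundreds of mm², curvatures below 1), so
each measure is first z-scored across regions, Aᶻᵢ = (Aᵢ − μ_A)/σ_A. The MSN
edge is the Pearson correlation between two regions' z-scored measure
profiles. σ_A uses the sample (n−1) convention; `ddof=0` switches to the
population convention. A constant measure cannot be z-scored and raises an
error naming the measure. Profiles of length 2 correlate to ±1 identically;
this is allowed but warned about.

**Functional connectivity (FCN).** Pearson correlation between
parcel-averaged time series (at least 3 timepoints; a zero-variance parcel
is an error naming the region). Sparsification keeps an edge when its
*signed* correlation r ≥ t. Signed (rather than |r|) thresholding is the
default because the thresholds of interest (0.4–0.8) are positive and the
point of the operation is to remove weak edges; `use_abs=True` selects
absolute-value mode. Node degree (ND@t) counts edges of the binarized
network; node strength (NS) sums the signed off-diagonal weights of the
unthresholded FCN (a `positive_only` mode clips negatives). The diagonal
self-correlation is always excluded from both.

**Combined connectome (FMSC).** Node feature vectors concatenate the
anatomical measures with NS and one ND channel per threshold (14 channels at
the defaults). Channels are z-scored across regions and regions are
correlated by exactly the same routine the MSN uses, so an FMSC restricted
to anatomical channels equals the MSN on those metrics bit for bit. At high
thresholds ND can be constant (often all-zero); `build_fmsc` raises a named
error so the caller can drop the channel, and the model-search loop records
such specs as skipped rather than aborting.

## Statistics

The anatomical screen runs one pooled-variance two-sample t-test per
(region, metric) cell (Welch by flag; pooled is the default since the
targeted designs have near-equal groups) and corrects over the *full* family
of regions × metrics cells with the Holm–Šidák step-down: sort the m raw
p-values ascending, adjust the i-th smallest to 1 − (1 − p₍ᵢ₎)^(m−i+1),
enforce monotonicity with a running maximum, report in input order. A cell
is significant when its adjusted p < α (default 0.05).

Fold-internal feature selection is deliberately different: it keeps every
edge with raw two-sided p < α on the training fold, with *no* multiplicity
correction — selection here is a dimensionality-reduction heuristic inside
cross-validation, not an inference procedure, and the held-out fold provides
the error control.

## Classification protocol

Subjects are split by stratified k-fold (default k = 10, shuffled with a
fixed seed; per-fold class counts within one of proportional). k equal to
the number of subjects is special-cased as leave-one-out with singleton
folds. Per fold: t-test selection on training subjects only, then a linear
soft-margin SVM with C = 1 on the selected columns, then one prediction pass
over the held-out fold. Accuracy, precision, and F1 are computed per fold
from the confusion counts and averaged arithmetically; reports carry the
seed and resolved configuration. Conventions for degenerate folds: an empty
selection falls back to all features (keeping all k folds comparable; a
`skip` mode exists), and a fold with no positive predictions scores
precision 0 with a logged warning so fold averages stay total. A scaling
parameter γ is sometimes quoted alongside C for SVMs; it does not enter a
linear kernel and is not a parameter here.

Consensus connections are the edges selected in *all* k folds, ranked by
mean |t| across training folds (descending, ties toward the smaller flat
edge index). The strict upper triangle is vectorized row-major over (i, j)
with i < j; any fixed bijection would do, row-major is the convention.

**Majority-vote ensemble.** Models voted together must share the fold
structure (same k and seed), so every vote is an honest out-of-fold
prediction. Odd panels are decided by count alone. Even-panel ties resolve,
in order: larger summed calibrated confidence, where each model's |decision
margins| are standardized by that model's median |margin| (raw SVM decision
values are not comparable across feature spaces); then raw summed |margin|;
then the positive class. `positive` and `abstain` tie modes are available.

## Synthetic cohorts

The generator emulates the statistical shape of a small two-group
resting-state study: 23 + 24 subjects, 34 parcels, 200 usable volumes.

- *Morphometry*: region-specific baseline means drawn once from a fixed
  population template (SA ≈ 600 ± 150 mm², GMV ≈ 1800 ± 400 mm³,
  CT_avg ≈ 2.5 ± 0.25 mm, curvature indices of order 0.01–3) plus Gaussian
  subject noise (per-metric SD roughly 5–15% of the mean). The template is
  deliberately independent of the cohort seed: the seed varies subjects, not
  the population, which keeps effect propagation into similarity networks
  comparable across replicate cohorts. Group-1 effects are mean shifts
  expressed in subject-SD units.
- *Time series*: T i.i.d. draws from a zero-mean multivariate normal with a
  block-structured target correlation — homotopic pairs at 0.6, blocks of
  four consecutive regions at 0.45, background 0.1. The block level is
  chosen so node degree varies across regions at thresholds 0.4–0.5 while
  degenerating at ≥ 0.6, matching the qualitative behavior of thresholded
  connectomes. Group-1 effects add per-edge correlation deltas. The
  perturbed matrix is repaired to positive definite by eigenvalue clipping
  (floor 1e-6) and unit-diagonal renormalization, iterated to convergence.
  An AR(1) temporal mode (`ar1_phi`) is available; the default is temporally
  white, which is sufficient for correlation-based stages.

What the generator does *not* model: hemodynamics, scanner noise and motion,
spatial autocorrelation of anatomical measures, heavy-tailed or
subject-heterogeneous effects. Passing tests therefore establish the
correctness and calibration of the computational pipeline, not the effect
sizes to expect from real imaging cohorts.

## Validation problem sizes

The null calibration of the screen uses 500 effect-free cohorts; the power
check plants a 2-SD shift in one cell and uses 200 cohorts; null
classification pools out-of-fold predictions over 20 seeded cohorts and
compares against the exact binomial interval of chance; consensus recovery
plants three +0.4 edge deltas and uses 10 end-to-end runs. These sizes give
all stochastic checks comfortable margins. All simulation entry points are
deterministic given their configuration: identical config and seed reproduce
cohorts and reports byte for byte (manifest paths are stored relative to the
cohort directory for that reason).

## Numerical details

- Correlation matrices are symmetrized ((R + Rᵀ)/2), clipped to [−1, 1],
  and given an exact unit diagonal after `np.corrcoef`; connectome
  validation tolerates asymmetry only below 1e-10.
- Zero-variance guards are relative (SD ≤ 1e-12·(|mean| + 1)), so a row
  that is constant up to floating-point roundoff is treated as constant.
- Connectome TSVs are written at 17 significant digits and parsed with
  round-trip float precision, making write→read exact.
- Degenerate t-test columns (zero variance in both groups) score t = 0,
  p = 1 in vectorized feature scoring, i.e. they are simply never selected;
  the scalar `two_sample_t` raises instead, since there a degenerate input
  is a caller error.

## Known limitations

- The enumeration presets cover subsets of sizes 3–8 over the 8 anatomical
  metrics and size-3 subsets over the 14 combined channels; other ranges are
  available but the search cost grows binomially.
- The two-model vote inherits the usual fragility of even-sized panels: its
  quality depends on margin calibration, which the median standardization
  improves but does not guarantee.
- Holm–Šidák control is exact under independence and conservative under
  positive dependence; strongly negatively dependent cells could in
  principle exceed nominal FWE, a configuration the generator does not
  produce.
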