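# Methods

`momcrad` implements a multi-objective, multi-classifier, multi-modality
radiomics model for predicting local persistence/recurrence (P/R) of head
and neck squamous cell carcinoma after definitive radiotherapy, from
post-treatment PET/CT and clinical covariates.  Because no dataset of this
kind is publicly deposited, the package ships a synthetic-data module that
emulates the study conditions, and every empirical claim below is one the
test suite or `scripts/acceptance.py` computes at run time.

## Imaging preprocessing

Images are 3-D grids with anisotropic voxel spacing; CT in Hounsfield
units, PET as activity (Bq/mL) or standardized uptake value (SUV).
Preprocessing follows the usual post-treatment recipe:

* **Isotropic resampling** to 1.0 mm (configurable): tri-linear
  interpolation for intensities, nearest-neighbour for masks.  The output
  grid has `round(dim * spacing / target)` voxels per axis (minimum 1);
  voxel centres sit at `index * spacing` and edge samples clamp to
  constant extrapolation.  Tri-linear is the 3-D interpolation used here;
  sources sometimes label this step "bilinear", which is its 2-D analogue.
* **Soft-tissue windowing** of the tumour mask on CT: voxels with HU
  outside [-150, 180] (inclusive bounds) are removed.  The default order
  is resample-then-window, which keeps the mask and image aligned on one
  grid; windowing first is one flag away in the CLI/pipeline.
* **SUV conversion**: body-weight SUV, `activity [Bq/mL] * weight [g] /
  injected dose [Bq]`, assuming activity decay-corrected to injection.
  Lean-body-mass variants are out of scope.
* **SUV >= 2.5 region helper** (inclusive threshold), optionally restricted
  to 26-connected components touching a seed mask.

On-disk format is NIfTI with a diagonal RAS affine; acquisition metadata
travels in a JSON sidecar (`injected_dose_bq`, `body_weight_g`).

## Feature extraction (257 per imaging modality)

* **8 geometry features** from the binary region: volume, marching-cubes
  surface area, surface-to-volume ratio, sphericity
  `pi^(1/3) (6V)^(2/3) / A`, compactness `V / (sqrt(pi) A^(3/2))`, maximum
  3-D diameter, major-axis length and elongation (minor/major, from the
  eigenvalues of the voxel-coordinate covariance, `4 sqrt(lambda)` axis
  convention).  The padded mask is smoothed with a sigma = 0.7 voxel
  Gaussian before marching cubes: the staircase surface of a raw binary
  grid overestimates the area of a 10 mm digital sphere by ~8%, while the
  smoothed mesh lands within ~1% of `4 pi r^2`; regions too small to
  survive smoothing fall back to the raw mask.
* **9 intensity features** of in-region voxels: min, max, mean, median,
  population SD, skewness, Fisher kurtosis, energy `sum v^2`, and base-2
  entropy of a 64-bin histogram.  Constant regions define SD, skewness,
  kurtosis and entropy as 0 — feature tables are always finite.
* **240 GLCM texture features**: 10 Haralick-family statistics (energy,
  contrast, correlation, homogeneity/IDM, entropy, variance, sum average,
  dissimilarity, autocorrelation, cluster tendency) for every combination
  of 4 quantization settings (8, 16, 32, 64 gray levels) and 6 voxel
  distances (1–6).  Quantization is equal-width over the in-region range
  (the common radiomics-toolbox convention; constant regions map to a
  single bin).  Pairs are accumulated over the 13 unique 3-D directions at
  the given Chebyshev distance with both voxels in-region, symmetrized and
  normalized once ("merged" aggregation); a flag switches to per-direction
  statistic averaging.  Degenerate cases never produce NaN: correlation of
  a zero-variance matrix is 0, and a (levels, distance) setting with no
  valid pairs takes the single-bin constant-region values.  This
  10 x 4 x 6 decomposition is this package's documented reconstruction of
  a 240-feature GLCM family; the counts (8 + 9 + 240 = 257) are the
  binding contract.

Because quantization is range-relative, all GLCM features are invariant to
adding a constant to the image; direction merging makes them invariant to
90-degree rotations of image and mask together.  Both properties, and
equivalence with a brute-force pair-counting oracle, are tested.

## mRMR pre-selection

Radiomic tables are reduced to 50 features per imaging modality before
optimization.  Features are discretized to three levels around
mu +/- sigma (the classic mRMR convention; affine-invariant), mutual
information is computed in bits, and selection is greedy MID:
first the feature maximizing MI with the label, then repeatedly
`argmax MI(f; y) - mean_{s in S} MI(f; s)`, ties broken by column order.
MID (difference) rather than MIQ (quotient) is used because it is the
canonical default and stays stable as redundancy approaches zero.
Clinical features bypass mRMR.

## The multi-objective, multi-classifier core

A **solution** is `(f, beta, omega)`: a binary feature-selection vector
(at least one feature), hyperparameters for the three base classifiers,
and classifier-fusion weights on the 3-simplex.  Base classifiers are
fitted on z-scored selected columns (training-cohort statistics, reused at
prediction):

* logistic regression, L2, `C` in [1e-3, 1e3] (log-uniform search);
* linear discriminant analysis, lsqr solver with shrinkage in [0, 1];
* RBF SVM, `C` in [1e-2, 1e3], `gamma` in [1e-4, 10] (log-uniform), with a
  Platt-style sigmoid on decision values for probabilities.

All three are trained class-balanced (balanced sample weights / uniform
LDA priors): with 21% prevalence this keeps the fixed 0.5 risk threshold
meaningful for the sensitivity/specificity objectives.  Archived SVMs
additionally have their sigmoid refit on stratified out-of-fold decision
values, since a sigmoid fitted on resubstitution decisions is biased and
measurably depresses validation sensitivity.  Every classifier predicts
from plain coefficient arrays (for the SVM: support vectors, dual
coefficients, intercept, sigmoid), so a model round-trips through JSON to
bit-identical predictions.

The solution probability is `p = sum_c omega_c p_c(x)`.  Objectives, all
maximized on the training cohort at threshold 0.5, are sensitivity,
specificity and **feature sparsity** `1 / (number of selected features)`.
By default objectives are resubstitution estimates (the study's stated
behaviour); `IMIAConfig.objective_cv >= 2` switches to stratified
out-of-fold estimates.  The multi-seed simulation tests use
`objective_cv = 2` because on the synthetic Gaussian cohorts resubstitution
rewards memorizing solutions and the archive then generalizes poorly —
that behaviour, and the fix, are visible in the test suite itself.
Degenerate fits (one class, all-constant selected columns, singular
covariance) mark a solution infeasible with objectives (0, 0, 0).

### Immune optimization (IMIA)

Each generation: evaluate the population, take the non-dominated front
(dominance: component-wise >= with one strict >; with the sparsity
objective disabled, only sensitivity/specificity are compared), clone
front members proportionally to an NSGA-II crowding-distance affinity
(`clone_factor * population_size` clones), hypermutate the clones —
bit flips on `f` at rate `p_f = 2/|f|` (at least one bit stays set),
Gaussian sigma = 0.2 steps on log10-scale hyperparameters (DA shrinkage,
being bounded, takes a clipped linear sigma = 0.1 step), and omega blended
half-and-half with a fresh Dirichlet draw — then keep the front of the
merged population plus randomly drawn dominated members up to the
population size.  The archive accumulates every non-dominated solution
found (capped at `archive_max = 200`, pruned by crowding distance) and its
hypervolume against the origin is the convergence monitor: the loop stops
at `generations` (default 50) or after `patience` generations with less
than `hv_tol` hypervolume change.  Within a run, fits are cached per
`(f, beta)`; omega only re-mixes cached probability columns.  Everything
is driven by one `numpy` generator, so a seed fully reproduces a run.
Population size 50, clone factor 2 and the mutation laws are this
package's reconstruction of the immune-algorithm internals; all are
exposed in `IMIAConfig`.

### Evidential-reasoning fusion

Each archived solution gets weight
`w_i ∝ [(sens_i + spec_i)/2] * [1 - |sens_i - spec_i|]` (normalized;
uniform fallback when all raw weights are zero): accurate *and* balanced
solutions dominate the fusion.  Per-sample probabilities are combined by a
two-hypothesis evidential-reasoning rule: source i contributes masses
`m_i(+) = w_i p_i`, `m_i(-) = w_i (1 - p_i)` and residual `1 - w_i`;
sources combine pairwise conjunctively with conflict normalization
`K = 1 - m1(+)m2(-) - m1(-)m2(+)`, and the fused probability assigns the
residual proportionally to the combined singleton beliefs:
`p = m(+) + m(theta) m(+)/(m(+)+m(-))` (0.5 when no singleton evidence
survives).  This rule is exactly identity-preserving for a single source
and symmetric for contradicting equal-weight sources; for agreeing
sources it mildly *reinforces* the consensus away from 0.5 (two sources at
p = 0.6 with weights 0.5 fuse to 0.619), which is the expected behaviour
of conjunctive combination — tests assert containment up to that margin
rather than strict min/max containment.  The residual-redistribution rule
is this package's documented choice for the two-hypothesis frame.

### Modality fusion

Per-modality models (CT radiomics, PET radiomics, clinical) are fused by
the same ER rule with weights proportional to training AUC (balanced
accuracy is a config alternative; uniform fallback when nothing beats
chance).  A missing modality at prediction is an error — no silent
imputation.  Probability >= 0.5 (inclusive) classifies a patient high-risk.

## Evaluation

Sensitivity/specificity/accuracy at the threshold; Mann-Whitney AUC with
midrank ties; the DeLong test for correlated ROC curves via placement
values with a two-sided normal p-value (identical scores give z = 0,
p = 1); Kaplan-Meier product-limit curves and the two-group log-rank test
(through lifelines) for the predicted risk groups, with ties handled by
the standard simultaneous-risk-set convention and "no events" defined as
chi2 = 0, p = 1.

## Synthetic data

The phantom is a sphere with two lobes at 1 mm spacing: PET lesion at
SUV 6 over background 1 (so the SUV >= 2.5 rule recovers it), CT lesion
carrying a linear soft-tissue gradient over [0, 80] HU on a -120 HU
background, Gaussian noise on both (zero noise gives exactly
piecewise-constant/linear volumes).

The cohort generator emulates the study population: 328 patients at 21%
prevalence (69 positive), split 262/66 by label-stratified 4:1 sampling —
per-class rounding reproduces 55/14 positives in training/validation.
Radiomic tables have 50 columns by default (257 when mirroring the
extractor): nuisance features are block-correlated Gaussians (rho = 0.6
within blocks of 10) to give mRMR real redundancy to remove; 5 planted
informative features are independent standard normals shifted by d in
positives, so the per-modality Bayes-optimal AUC is
`Phi(sqrt(sum d_i^2)/sqrt(2))` exactly — the default targets 0.9.
`signal_overlap` sets the shared-latent fraction between CT and PET
signal (default 0: complementary).  Clinical covariates follow the
marginal frequencies of the study table (sex, site, smoking, T/N stage,
grade, HPV with an explicit Unknown level); ordinal covariates shift with
a latent effect (default 0.6) in positives and HPV-negativity is enriched
among them, yielding a deliberately weaker clinical signal.  Encoding is
ordinal integers for T/N/grade and one-hot indicators elsewhere.
Survival: positives draw exponential event times (median 12 months), with
a `censoring_rate` fraction cut short; negatives are censored at uniform
follow-up in [9, 113] months — so with zero censoring the event count
equals the positive count exactly.  The simple stratified split replaces
case-control matching, which is unnecessary for method testing.

What the generator does **not** emulate: scanner physics and
reconstruction artifacts, inter-feature distributions of real radiomics
(heavy tails, batch effects), correlated censoring, or site effects.
Passing tests therefore demonstrate that the machinery recovers known
planted structure under controlled conditions — not clinical performance.

## Problem sizes and numerical choices

The default `IMIAConfig` (population 50, 50 generations) reflects the
full-scale configuration.  The test suite and the acceptance script run
the optimizer at population 10–12 and 6–8 generations with
`objective_cv = 2`: on the 50-feature pre-selected tables this recovers
the planted signal reliably (10-seed mean validation AUC ≈ 0.95 for the
three-modality fusion) at a few seconds per modality, which is the
package's chosen benchmark size.  Other fixed choices: HU bounds and the
SUV threshold are inclusive; probability 0.5 classifies high-risk;
hypervolume reference point is the origin; archive deduplication is by
exact `(f, beta, omega)` identity, so objective-space duplicates with
different parameters are all kept.

## Known limitations

* The exact identities of the original 257 features and the internals of
  the immune optimizer and ER weighting live in sources that are not
  publicly available; counts, family structure and behaviour are
  preserved, identities are best-effort reconstructions.
* Resubstitution objectives (the default) overfit flexible solutions on
  small cohorts; use `objective_cv >= 2` when that matters.
* No wavelet/filtered features, GLRLM/GLSZM/NGTDM families, DICOM
  ingestion, Cox modelling or calibration analysis.
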