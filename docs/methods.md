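# Methods

`dualhub` implements, end to end, the analysis chain used to ask whether
distinct cortical hubs preferentially encode the semantic structure of
*event* concepts (e.g. *a wedding*) versus *object* concepts (e.g. *an
apple*): representational similarity analysis (RSA) with two-stage
permutation inference, univariate activation contrasts, and generalized
psychophysiological-interaction (gPPI) connectivity.  Because the pipeline
is validated entirely on synthetic data, the package also contains a
forward model that generates 4D BOLD runs with *known* representational
geometry planted in chosen regions, so every downstream stage can be
checked against ground truth.

## The emulated study design

The synthetic cohort mimics a single-run, event-related design:

* 60 concepts — 30 events, 30 objects — each presented once per block in
  4 randomized blocks (fresh permutation per block and subject);
* 2.5 s stimulus duration; inter-stimulus intervals drawn uniformly on
  [1, 4] s (mean 2.5 s).  Only the mean and range of the emulated design's
  jitter are known; the uniform shape is an assumption and is flagged in
  the concepts manifest;
* one catch question per concept (25% of trials), modelled as a 1 s event
  immediately after the flagged presentation.  Whether a catch response
  period should extend beyond the question is unknown; the fixed 1 s
  duration is an assumption;
* TR 1.7 s; a full run is ~858 volumes (~1459 s).

## Model RDMs

For each concept type separately, two 30 × 30 representational
dissimilarity matrices are built:

* **semantic**: d_ij = 1 − cos(v_i, v_j) over per-concept embedding
  vectors (word2vec-style);
* **visual**: d_ij = mean over the 4 × 4 cross-concept image pairs of
  1 − Pearson(f_a, f_b) over low-level image feature vectors (C1-layer
  style).  The diagonal is fixed at 0 rather than the within-concept image
  dissimilarity: diagonals never enter the pair vector, and a zero
  diagonal is what the RDM invariants require.  Only cross-concept pairs
  (16 per cell) are averaged — the within-concept pairs do not define a
  concept-*pair* quantity.

Neural RDMs are 1 − Pearson between activation patterns.  The canonical
pair vectorization everywhere is the row-major lower triangle excluding
the diagonal (length n(n−1)/2; 435 for n = 30).

## Forward model (synthetic BOLD)

Within each signal region, concept c's voxel pattern is the image of

    f_c = [ sqrt(w_sem(type(c))) · ŝ_c ,  sqrt(w_vis) · v̂_c ]

under one fixed, seeded linear map Q whose columns are orthonormal *and*
orthogonal to the constant voxel vector (ŝ_c: unit-norm semantic vector;
v̂_c: unit-norm feature-centered mean visual vector).  Orthonormality
preserves inner products and the zero-mean property turns the voxelwise
Pearson correlation into the feature cosine, so with zero exemplar jitter

    1 − corr(p_i, p_j) = (w_sem d_sem,ij + w_vis d_vis,ij) / (w_sem + w_vis),

i.e. the planted neural RDM is *exactly proportional* to the target
mixture — the sqrt on the weights is what makes the mixture come out in
the stated linear form.  A region must contain more voxels than semantic
plus visual dimensions plus one for the embedding to exist.

Each concept's time course is its HRF-convolved trial boxcar times the
pattern; catch questions add a spatially uniform response
(`catch_amplitude`, default 0.5).  Noise per voxel is AR(1) (coefficient
0.3, marginal SD `noise_sd`) plus white Gaussian (0.5 × `noise_sd`) plus
3 slow cosine drift terms (periods ≥ 2T/3, i.e. well below the 1/180 Hz
high-pass edge; per-term RMS `drift_amplitude`).  A per-subject
log-normal gain (σ = `subject_sd`) gives between-subject spread.
`amplitude` sets the per-voxel RMS of a unit-total-weight pattern.

**Matched-geometry control.**  `make_concept_space(mirror_types=True)`
makes the object-concept geometry an orthogonally rotated copy of the
event-concept geometry (the visual rotation additionally fixes the
all-ones direction so Pearson correlations survive the rotation).  The
two types then have bit-identical semantic and visual RDMs while
occupying different feature directions.  Event-vs-object difference
analyses compare the *detectability* of two geometries; without this
control a chance difference between two independently drawn stimulus
sets is a real signal, and an equal-weight region is correctly — but
uninformatively — flagged.  Recovery studies therefore use the mirrored
space; ordinary simulations default to independent geometries.

What the generator does **not** emulate: head motion, multi-echo decay,
physiological noise, spatial normalization artifacts, or any spatial
autocorrelation of the noise (noise is voxelwise independent; spatial
structure enters only through smoothing).  Passing tests therefore show
the *statistics* behave as designed, not that the pipeline is robust to
scanner artifacts.

## GLM stage

Design matrices contain HRF-convolved condition boxcars (double-gamma
HRF: response gamma shape 6/scale 1, undershoot shape 16/scale 1, ratio
1/6, 32 s support, unit peak; built on a 0.1 s grid and sampled at volume
onsets), a discrete-cosine high-pass basis with K = floor(2·T/cutoff)
columns (cutoff 180 s → K = 16 at 858 × 1.7 s), optional motion columns,
and a constant.  Estimation is per-voxel OLS without prewhitening — a
deliberate simplification (deterministic, hyperparameter-free); the
synthetic AR(1) component is mild and the calibration studies quantify
the consequence: type-I error stays inside the binomial band.

Per-concept patterns use **least squares separate (LSS)**: one GLM per
concept with that concept's 4 trials as one regressor of interest, all
other stimulus trials collapsed into a single nuisance regressor, catch
events in another, plus high-pass/motion/constant.  A structural property
worth knowing: at this design's 5 s mean SOA the LSS leakage matrix
(β̂ = Mβ with unit diagonal, off-diagonal RMS ≈ 0.04) bounds noiseless
recovery at a pooled Pearson of ~0.96 against the planted amplitudes;
the saturated all-concepts model (LSA) recovers the plant exactly, and
the unit suite asserts both facts.  Betas are expressed relative to the
implicit baseline; no percent-signal-change scaling.

Smoothing is separable Gaussian (σ = FWHM/(2√(2 ln 2)) per axis in voxel
units from the affine; axis-aligned affines only) with kernel
renormalization inside the brain mask: constants are preserved exactly
inside any mask, and on a full-grid mask the mean is preserved to
floating-point precision.  On partial masks renormalization trades exact
mean preservation for zero leakage across the mask edge.

## RSA stage

Searchlights are spheres of radius 4 voxels (center-to-center distance,
inclusive); ROI spheres are specified in millimetres (10 mm at the four
candidate-hub MNI centers).  The statistic is the partial Spearman
correlation between the sphere's neural RDM and the semantic RDM
controlling the visual RDM: rank-transform the three pair vectors
(average ranks on ties), residualize neural and semantic ranks on the
covariate ranks (with intercept), Pearson-correlate the residuals —
algebraically identical to the closed form
(r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) on rank correlations, which the
tests use as the independent oracle.  Fisher z = atanh(ρ clipped at
1−1e−12) keeps noiseless plants finite.  The statistic is assigned to the
sphere's center voxel; spheres with fewer than `min_voxels` (default 10)
usable voxels are missing (NaN), and missing values never enter group
averages (per-voxel valid-subject counts).  Whether ROI analyses should
use the 4 mm smoothed betas like the searchlight is not determined by the
emulated design; the pipeline uses the smoothed betas for both.

The searchlight engine ranks each sphere's neural pair vector once and
evaluates any number of (permuted) model RDM pairs as a single matrix
product — the permutation nulls cost one GEMM per subject.

## Inference stage

Two-stage Monte Carlo permutation scheme:

1. **Subject level** — recompute the statistic with the concept labels of
   the semantic *and* visual RDMs jointly reshuffled (one permutation
   applied to both, keeping the model RDMs aligned with each other while
   breaking their alignment to the brain; 100 permutations per subject at
   full scale).  Independent permutation of the covariate is available
   behind a flag (`joint=False`).  The neural RDM is never permuted.
2. **Group level** — each of n draws (10,000 at full scale) picks one
   null per subject uniformly (independently across draws) and averages.

Searchlight maps are corrected familywise with threshold-free cluster
enhancement (E = 0.5, H = 2, dh = max/100, 26-connectivity — the field's
standard values) and the max-statistic: p(v) = (1 + #{draws whose maximum
TFCE ≥ observed TFCE at v})/(1 + n).  ROI p-values are the rank of the
observed group mean among the draws, p = (1 + #{null ≥ obs})/(1 + n) —
never zero, ties counting against the observation.  Difference maps
(event z − object z per subject, with per-subject difference nulls from
independently permuted event and object statistics) are tested two-sided
via the max of |TFCE|.

A scope note on the difference test: label permutation builds the
*no-correspondence* null.  At voxels carrying strong signal of both
types, the sampling variance of the Fisher-z difference exceeds the
permutation spread (the atanh derivative grows as 1/(1−ρ²)), so the
difference test is well calibrated only in the realistic small-effect
regime (single-subject ρ up to ≈ 0.3–0.4).  The recovery study is
deliberately planted in that regime.

Univariate and PPI contrast maps have no label structure to permute;
their group test is whole-subject sign flipping of the one-sample t map
with the same max-statistic correction (exact enumeration when
2^N ≤ n_flips), replacing parametric random-field cluster correction with
a self-contained, assumption-light equivalent.

## PPI stage

Seed series are the first left singular vector of the ROI's mean-centered
time × voxel matrix, scaled by the singular value (per-√T convention) and
sign-aligned with the ROI mean.  The gPPI design holds (i) the seed,
(ii) one HRF-convolved psychological regressor per condition (event,
object, catch), (iii) one interaction per condition, (iv) motion
covariates, plus a constant.  The default interaction is the
`bold_product`: mean-centered seed × mean-centered condition indicator at
volume resolution — deterministic and hyperparameter-free.  A
`deconvolved` mode (ridge-regularized HRF deconvolution, product at
neural resolution, reconvolution; ridge 1e−2 trace-normalized) is
provided behind a flag, and the stage manifest records which mode
produced any output.  Centering both factors keeps main effects out of
the interaction columns.

## Problem sizes used by the test and acceptance studies

Monte Carlo studies run the identical algorithms at sizes chosen for a
single-CPU desk run, with permutation/draw counts large enough that the
binomial/Monte Carlo error is small relative to the asserted bands:

* ROI type-I calibration: 200 null cohorts × 8 subjects, 60-voxel ROI,
  30 concepts, 50 subject permutations, 1,000 group draws; α = 0.05 band
  [0.02, 0.09].
* Map FWE calibration: 100 null cohorts × 8 subjects, 12³ grid,
  radius-2 searchlight, 50 permutations, 500 draws, TFCE dh = max/50.
* Dual-hub recovery: 10 cohorts × 12 subjects, 16³ grid, two radius-3
  regions (event-preferring w_sem = 2.5 vs 0.25; control 0.6 vs 0.6;
  w_vis = 0.2 both), amplitude 0.085 with unit noise (single-subject
  region ρ ≈ 0.2–0.4), full forward simulation + LSS + 4 mm smoothing +
  searchlight + two-sided TFCE inference, 40 permutations, 600 draws.
* PPI recovery: 100 modulated-coupling replicates; 200 null cohorts of
  8 subjects with exhaustive-ish sign-flip inference (1,000 flips).

The demo pipeline configuration (4 subjects, 14³ grid, 8 + 8 concepts,
30 permutations, 500 draws) exists to exercise every stage quickly, not
to estimate anything precisely.

## Numerical choices and degenerate inputs

* Correlation-distance RDMs are clipped to [0, 2] and symmetrized against
  floating-point drift; diagonals are exactly 0.
* Degenerate searchlights (too few voxels, zero-variance patterns,
  zero-variance rank vectors) yield NaN, never 0; a zero-variance
  covariate degrades to plain Spearman; covariate ≡ target yields NaN
  (perfect confound), never a spurious value.
* TFCE integrates e(h)^E h^H dh at right-endpoint thresholds h_k = k·dh;
  at dh = max/100 the single-voxel value overshoots the analytic h³/3 by
  ≈ 1.5% (the Riemann-sum bias).  Negative lobes are processed on the
  negated map and returned negative.  Batched null processing normalizes
  each map by its own maximum, labels a 4D stack with no connectivity
  along the stack axis, and rescales by max^(H+1).
* Sign-flip tests use the t statistic (variance-standardized mean) and
  the (1+r)/(1+n) rule for random flips, exact counts for enumerated
  flips.
* All randomness flows through named integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  outputs, including NIfTI bytes (uncompressed .nii inside the pipeline).

## Known limitations

* OLS without prewhitening mildly misstates single-subject variances
  under AR(1) noise; group inference is permutation-based, so level is
  preserved (verified by the calibration studies).
* LSS leakage bounds noiseless recovery at ~0.96 pooled Pearson at this
  trial pacing (see above); analyses that need exact per-concept betas at
  slow pacing should use the LSA path.
* The difference-map permutation test is anti-conservative at
  implausibly strong effect sizes (see the inference scope note).
* The simulator's noise is spatially white; FWE calibration under
  realistic smoothness is exercised only via the explicit smoothing step.
* ROI spheres assume approximately isotropic voxel sizes when converting
  a millimetre radius to a voxel bounding box.
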