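# Methods

This note documents the models, defaults, and numerical choices behind
`refdecode`, and what its synthetic-data validation does and does not show.

## Experimental design model

A trial has four contiguous phases: fixation (1 TR), touch localization
delay (1–4 TR), movement planning delay (1–4 TR), and execution (1 TR),
with TR = 1.88 s. Runs hold 33 trials (17 in reduced test designs) between
rest periods of 11 TR (start) and 4 TR (end). Posture (uncrossed/crossed)
is constant within a run and changes only every three runs; for 12-run
designs the start posture alternates between the two halves of the
experiment.

**Counterbalancing.** The unit of run-wise first-order counterbalancing is
the foot × task condition (4 levels): with 33 trials a run has 32
transitions, and each of the 16 ordered condition pairs occurs exactly
twice. Eight-level balancing (including stimulation site) is impossible in
32 transitions, so the medial/lateral site is balanced marginally within
each foot only. Sequences are realized as Eulerian circuits of the complete
4-node transition multigraph with randomized edge order; the circuit's
start condition receives the run's single surplus (9th) occurrence and is
rotated across runs so per-condition experiment totals stay in a one-trial
band (49–50 for the default generator, inside the 48–51 band the
counterbalancing constraints allow).

**Delay selection.** `select_min_correlation_design` re-randomizes the
delays a configurable number of times (default 1000) and keeps the
candidate minimizing the maximum absolute Pearson correlation between task
predictors of the run-wise GLM design matrices (baseline and error columns
excluded; ties broken by candidate order). "Smallest correlations" admits
several summaries; the max-|r| criterion targets the worst pair, which is
what harms separability of betas.

## Synthetic BOLD model

The simulator provides ground truth the analysis must recover. Each planted
region carries, per trial phase, a zero-mean unit-RMS Gaussian weight
vector over its voxels; a trial's class along the region's coded dimension
(anatomical foot, external side, goal side, or task rule) multiplies the
weights by ± effect size. Signals are phase boxcars at 16 bins/TR convolved
with the canonical HRF, so the epoch GLM is correctly specified and betas
estimate the planted amplitudes directly. `effect_size` is therefore the
planted pattern amplitude in units of the voxel noise standard deviation
(default 1.0 — a strong but not unrealistic multivariate code given that
the searchlight pools ~10²–10² voxels).

Noise is white Gaussian (sd 1.0) with AR(1) autocorrelation (coefficient
0.3, innovation-scaled so the marginal variance is independent of the
coefficient), plus a slow sinusoidal drift (amplitude 0.5, period 192 s,
random phase per voxel) that the 128 s high-pass must remove. Six motion
nuisance series (random walks) are generated per run and can optionally be
coupled into the data and/or included as GLM columns. Not modeled:
physiological noise, spatial noise correlations, head-motion image
transforms, and inter-participant anatomical variability (the cohort shares
one grid, mirroring normalized group space; pattern weights are
participant-specific).

Phase-specific (independent) weights are the default regime and produce the
dynamic-coding signature: within-interval classifiers succeed where codes
are planted while cross-interval transfer fails. The `shared_patterns`
switch reuses localization weights during planning, the control regime in
which cross-interval decoding succeeds. Passing tests in both regimes shows
the pipeline *can* distinguish maintained from reorganized codes; it does
not show that real cortical codes behave either way.

## GLM

23 experiment-wide predictors: 2 posture baselines (fixation delays plus
run rest periods), 4 localization (posture × foot), 8 planning and 8
execution (posture × foot × task), 1 error predictor absorbing all phases
of excluded trials. A run contains 12 of these. The canonical HRF is the
standard double-gamma (delays 6/16 s, dispersions 1/1, undershoot ratio
1/6, 32 s support), unit-sum normalized; regressors are built at microtime
resolution (16 bins/TR) and sampled at the TR grid. The default `epoch`
variant models each phase for its true 1–4 TR duration; the `impulse`
variant uses fixed 1-TR boxcars (the two coincide when all delays are
1 TR).

Fitting projects the DCT high-pass basis (cutoff 128 s, constant included)
out of data and design, estimates a single AR(1) coefficient per run from
the pooled lag-1 autocorrelation of OLS residuals across in-mask voxels,
and refits after first-difference prewhitening (first row scaled by
√(1−ρ²)). Two numerical caveats are documented by tests: the pooled AR
estimate is attenuated because the high-pass filter absorbs low-frequency
autocorrelation (whitened *betas* remain calibrated to within ~15% in
variance, which is what the decoding consumes), and rank-deficient designs
fall back to the pseudo-inverse with a warning naming empty columns (e.g.
the error column of an error-free run).

## Decoding

Eight classifier analyses are fixed by `make_classifier_specs`; their label
maps derive from the same `external_side`/`goal_side` functions the design
generator uses, so labels and planted codes cannot drift apart. Samples are
run-wise betas of the phase's condition predictors (2 per run at
localization, 4 at planning); because both classes occur in every run,
every leave-one-run-out training fold is exactly class-balanced. The
classifier is LIBSVM's linear soft-margin SVM (scikit-learn `SVC`,
kernel="linear", C = 1) with no feature scaling; exact-zero decision values
are broken deterministically toward the first class. Cross-interval
analyses train once on all localization samples and test on all planning
samples (train/test disjoint by phase; run-wise folding for the cross
scheme is not retained, recorded here as the package's choice). The
searchlight visits every in-mask voxel, clips the radius-4 offset ball
(257 offsets) to the mask, and writes mean cross-validated accuracy at the
center; centers are independent and any execution order yields identical
maps.

## Group inference

Participant accuracy maps are smoothed with a mask-aware 6 mm FWHM
Gaussian (smoothed map divided by smoothed mask, so constants are preserved
at edges), then tested voxel-wise against 50% with a one-sided one-sample
*t*. FWE control uses sign-flip permutations of the (accuracy − chance)
maps: clusters form at the t quantile of one-sided p < 0.001 (df = n−1)
with 26-connectivity, the null is the distribution of the maximum cluster
*extent*, and observed clusters are significant at FWE p < 0.05. For
n ≤ 12 participants all 2^n sign patterns are enumerated (exact test);
otherwise 5000 random patterns including the identity. Cluster extent was
chosen over mass as the most common default; variance smoothing is not
applied (plain t, matching a one-sample t-test formulation). A voxel with
zero variance and positive mean (degenerate certainty) is treated as
suprathreshold inside the permutation test, while the standalone group
t-map reports t = 0 there.

## ROIs and overlap

Group ROIs are 6 mm spheres at each significant cluster's t-peak; within a
connected cluster, local maxima at least 20 mm apart (greedy, descending t)
each get an ROI. Individual ROIs re-center on the participant's
max-accuracy voxel inside the group ROI (ties to the lowest voxel index).
Overlapping ROIs merge when their per-participant accuracy means differ by
≤ 2 points and their variance ratio is ≤ 2 — "similar means and variances"
quantified, since no numeric rule exists; both tolerances are arguments.
Bootstrap CIs are percentile intervals of the mean over 1000 resamples of
the voxel-wise accuracies within the individual ROI (resampling
cross-validation folds instead would be a defensible alternative; the
choice is recorded in output metadata). Overlap reports count intersection
voxels and convert with the 27 mm³ voxel volume of 3 mm isotropic space.

## Validation scale and what it shows

The acceptance-level tests run the complete pipeline on 12³-voxel phantoms
with 6 participants × 6 runs × 17 trials, exhaustive 2^6 sign-flip
permutations, and two independently seeded repeats (plus one shared-weights
cohort); the type-I calibration uses 200 synthesized smooth null cohorts of
8 maps each, and the null-decoding check a 4-participant noise-only cohort.
These sizes keep the whole suite within minutes on one CPU while leaving
every threshold at its analysis value (p < 0.001, FWE 0.05, C = 1,
radius 4, 6 mm smoothing). The properties exercised — counterbalancing,
estimator correctness, fold balance, FWE control, recovery and
cross-interval dissociation — are scale-free, but absolute decoding
accuracies at this scale say nothing about real-data effect sizes.

## Known limitations

- The pooled AR(1)+high-pass noise model is an approximation; first-level
  t-statistics are mildly overdispersed (betas, which the decoding uses,
  are unbiased).
- No spatial noise correlation is simulated, so smoothing interacts with
  noise more benignly than in real data.
- The searchlight is serial; centers are independent, so parallelization
  is possible but not implemented.
- Individual-ROI bootstrap CIs resample voxels, not folds; with few voxels
  per sphere the intervals are optimistic about fold-to-fold variability.
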