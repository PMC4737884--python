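# Methods

`lhmap` implements the analysis stack of a whole-brain activity-mapping
study of the learned-helplessness (LH) paradigm: behavioral phenotyping of
shuttle-box sessions, a paired negative-binomial screen for differentially
activated brain regions, sphere-voxel density maps of detected cell
centroids, and a pooled-bootstrap test for stereotypy of brain-wide
activity profiles.  This note records the models, the defaults and why
they are what they are, what the synthetic data do and do not emulate, and
the numerical choices.

## Behavioral scoring and phenotyping

A testing session presents 35 trials of a 5 s cue light followed by a 10 s
escapable foot shock.  Trials are scored from the shuttle time `t`
(seconds from cue onset):

* `t < 5` — **avoidance** (the animal crossed during the cue; no shock, so
  no escape latency exists);
* `5 <= t < 15` — **escape**, with escape latency `t - 5` measured from
  shock onset;
* no crossing by 15 s — **failure**, censored at the 10 s shock duration.

The first five trials are discarded as association learning; the session
summary is computed over the next 30.  The mean escape latency averages
escapes and failures (failures contribute the censored 10 s); avoidance
trials are excluded because no shock was delivered — an all-avoidance
session gets latency 0.  Both conventions (latency reference at shock
onset, failures at 10 s) keep the latency index inside [0, 10] s.

Phenotypes are assigned by k-means (k = 2, fixed) on the raw
(latency-in-seconds, failure-count) plane — raw units, because the two
indices are the axes on which the two behavioral modes separate and
standardization would only rescale an already large gap.  k-means++ with
50 restarts under a fixed seed makes the partition deterministic; the
cluster with more failures is named helpless.  For classifying new animals
the package fits Fisher linear classification functions

    score_k(x) = x' S^-1 m_k - 0.5 m_k' S^-1 m_k + log pi_k

with pooled within-class covariance `S` (N - 2 denominator) and empirical
class priors; resilient wins when its score is larger, which is the
smaller-Mahalanobis-distance rule.  The classical published coefficient
set for this paradigm (R intercept -4.63, latency 5.67, failures -1.65;
LH intercept -23.24, latency 3.67, failures 0.53) ships as
`PAPER_DISCRIMINANT` so new sessions can be classified without refitting;
its implied boundary is the line `2.00*latency - 2.18*failures + 18.61 = 0`.

Rats in the lever-press variant are classified by printed thresholds:
>= 10 presses (within 20 s of shock onset, over 15 trials) resilient,
<= 5 helpless, 6-9 excluded.

Group comparisons of failures and latency use the two-tailed Mann-Whitney
test (midranks for ties; exact enumeration for small tie-free samples via
scipy).  Imaging cohorts are built by `select_extreme_pairs`: within each
batch of animals run in parallel, the helpless animal maximizing
(failures, latency) — lexicographically — is paired with the resilient
animal minimizing them, yielding the blocking structure the count screen
expects.

## Paired negative-binomial regional screen

For each region, cell counts `Y` over the `2 * n_pairs` animals follow an
NB2 GLM with log link (`Var = mu + alpha * mu^2`).  The linear predictor
is `B + G`: a categorical blocking variable `B` with one level per pair
(absorbing batch/day nuisance — any multiplicative pair-level factor is an
additive log-offset lying exactly in the span of the pair dummies, so it
cannot move the group test), and a binary `G` coded 1 for resilient, so a
positive coefficient means "R high".  The group effect is tested
sequentially: the reduced model `~ B` against the full model `~ B + G` by
the likelihood-ratio statistic of the added `G` term, the dispersion being
estimated once under the full model and shared by both fits.  Raw
P-values are BH-adjusted globally across regions; the significant set is
`{q <= alpha}` with direction from the sign of the `G` coefficient.

Two numerical choices matter at this design's size (22 observations, 13
full-model parameters):

* **Dispersion: Cox-Reid adjusted profile likelihood.**  Plain profile ML
  conditions on 12 fitted mean parameters and underestimates `alpha`
  severely (true 0.2 is recovered near 0.08 in simulation), which inflates
  the LR test to an empirical type-I error of ~0.20 at nominal 0.05 — the
  same inflation reproduces in an independent R `glm.nb` + sequential
  `anova` fit, so it is a property of the scheme, not of this
  implementation.  The default objective therefore subtracts
  `0.5 * logdet(X' W X)` (the Cox-Reid adjustment used by edgeR), which
  removes most of the bias.  `dispersion_method="ml"` restores plain ML.
* **Reference distribution: F(1, n - p).**  Even with Cox-Reid dispersion
  the chi2(1) reference leaves type-I near 0.073, because the statistic's
  null variance exceeds 2 when `alpha` must be estimated from 9 residual
  degrees of freedom.  Referring the statistic to F(1, n - p) — in the
  spirit of quasi-likelihood F-tests — brings the measured type-I to
  0.046 with no change to the statistic itself.  `test="chi2"` restores
  the asymptotic reference.

Power under these conditions is modest and irreducible: a log-fold effect
of 0.7 at baseline 100, dispersion 0.2 and 11 pairs has effect size
`z = 0.7 / sqrt(2*(0.2 + 1/100)/11) ~= 3.6`, while BH at q <= 0.05 with
~480 null regions demands `z ~= 3.2` at 80% recall — so even an exactly
calibrated oracle z-test tops out near 67% sensitivity, and any scheme
that reports more is paying for it with a false-discovery rate far above
nominal (plain-ML chi2 reaches 91% sensitivity at an empirical FDR of
0.7).  The package prefers the calibrated test; `scripts/acceptance.py`
reports the measured sensitivity/FDR pair.

The fitter is a batched IRLS over all regions simultaneously (stacked
weighted least squares; convergence on relative log-likelihood change
below 1e-11, 100 iteration cap), alternated with a vectorized
golden-section search for `alpha` on log scale in [1e-8, 1e3] (40
iterations; the lower boundary is evaluated as the exact Poisson limit).
Non-converged regions are flagged with `p = NA` rather than dropped;
regions constant across animals (including all-zero) are reported with
`p = 1` and undefined direction.  Single-region fits expose the usual
model/results surface (`PairedNegativeBinomial(...).fit().summary()`) and
are verified against statsmodels GLM log-likelihoods to 1e-11.

No library-size normalization is applied by default (regional counts from
a standardized whole-brain pipeline share one detection protocol);
`normalize="total"` adds a per-animal log-total-count offset.

## Sphere-voxel maps

Cell centroids (micrometers, atlas frame) are counted inside overlapping
analysis spheres — 100 um diameter, centers on a regular 50 um grid, so a
cell can contribute to several neighboring voxels; membership is
`distance <= radius` (boundary inclusive).  Atlas aggregation assigns each
cell the label of its containing atlas voxel by the floor convention over
half-open intervals `[i*s, (i+1)*s)`; background (label 0) and
out-of-volume cells are tallied separately so totals always equal the
cloud size.  `voxel_screen` reuses the paired NB test at every voxel of
per-animal density maps and BH-adjusts across voxels, producing a q-value
map aligned to the grid.  Spheres are 3-D; a single-section analysis is a
one-voxel-thick grid.  Volumes are written as NRRD with mandatory spacing
metadata (via SimpleITK).

## Stereotypy bootstrap

Each animal's brain-wide activity vector (regional c-FosGFP counts or
regional PET intensity, raw by default) enters a pairwise Pearson
correlation matrix; the stereotypy statistic of a group is the mean of the
off-diagonal upper triangle.  The test statistic is
`Correlation_LH - Correlation_R`.  The null is built by pooling all
animals and repeatedly (default 100,000 iterations) resampling n1 animals
with replacement into a pseudo-LH group and n2 into a pseudo-R group,
recording the difference of resampled means.  The two-sided P doubles the
smaller tail, with ties counted as extreme and a floor of `1/n_iter`
(an empirical tail cannot certify P = 0); `two_sided="abs"` offers the
|null| >= |observed| convention instead.

Resampled groups are multisets.  By default a duplicated animal
contributes r = 1 pairs (the literal reading of with-replacement
resampling); `include_duplicate_pairs=False` drops same-animal pairs and
redraws the rare iteration with no valid pair.  The two conventions give
nearly identical calibration on realistic data because regional activity
vectors are dominated by a shared region-size profile (pairwise r ~ 0.7-
0.95), so duplicate pairs are not outliers in the null; on artificial
uncorrelated vectors both variants turn conservative — a known property of
this pooled bootstrap, worth remembering when the statistic is applied to
decorrelated data.  Under the package's realistic synthetic nulls the
measured rejection rate at 0.05 is ~0.047.

## Synthetic data: what it emulates, what it does not

`simulate` provides the study conditions for every test:

* **Behavior** (`BehaviorSimParams`): 144 animals, 22% helpless, 35
  trials.  Per trial a latent escape latency is drawn normal per phenotype
  (resilient mean 1.0 s, SD 1.5; helpless mean 8.5 s, SD 2.0) and censored
  at the 10 s shock end; an additional per-trial outright-failure
  probability (0.02 resilient, 0.55 helpless) reproduces the
  high-failure helpless mode.  Negative latencies become avoidances.  The
  two phenotypes separate as in the study's latency-failure plane; the
  generator does not model within-session learning, trial-order effects,
  or the intermediate animals real cohorts contain, so perfect classifier
  agreement here bounds, rather than predicts, field performance.
* **Region counts** (`CountSimParams`): 11 pairs; NB2 counts with
  dispersion 0.2 around `log(region baseline) + pair offset (+/- group
  effect)`.  Region baselines are log-normal (SD 1.0) around 100 —
  regional counts in real brains span orders of magnitude, and that shared
  profile is what makes animals' brain-wide vectors strongly positively
  correlated, the regime the stereotypy bootstrap operates in (set
  `region_profile_sd=0` for exactly flat baselines).  The pair offset
  (log-normal, SD 0.3) is the nuisance the blocking variable absorbs.
  Signal regions carry `log_fold_change` 0.7 with per-region sign
  overrides covering both "R high" and the LC-like "LH high" direction;
  population group-mean ratios round-trip to exactly `exp(lfc)`.
* **Cell clouds** (`CloudSimParams`): a box-parcellated toy atlas with
  Poisson counts per region and uniform placement.  This is plumbing for
  the voxel pipeline, not a model of cytoarchitecture.

All generators are bit-reproducible under a fixed seed; the CLI splits one
root seed per pipeline stage via `numpy.random.SeedSequence`.

## Problem sizes

The test-suite simulations use the study's own design sizes (11 pairs, 500
regions for calibration and recovery; 500 outer replicates at 10,000
bootstrap iterations for the bootstrap calibration; 200 replicates for
screen recovery), which the batched fitter completes in a few minutes on
one CPU.  `scripts/acceptance.py` reports the same quantities at 10
recovery replicates and 200 bootstrap-calibration replicates, finishing in
under a minute.

## Known limitations

* The screen treats regions independently: no spatial smoothing, no
  shrinkage across the atlas ontology, no sharing of dispersion across
  regions (which would raise power considerably and is what count-based
  genomics tools do).
* The F(1, n - p) reference is a small-sample calibration device, not an
  exact distribution; at much larger designs it converges to the chi2
  reference.
* The stereotypy bootstrap is approximate by construction — resampling
  with replacement from the pooled set widens the null slightly relative
  to the sampling distribution of disjoint groups; on low-correlation
  vectors this turns markedly conservative.
* Escape-latency conventions (avoidances excluded; failures at 10 s) are
  configurable at scoring level but the printed discriminant coefficients
  assume them.
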