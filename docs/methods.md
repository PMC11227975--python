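# Methods

`tauspread` implements a connectivity-mediated tau-spreading analysis for
longitudinal tau-PET cohorts: regional accumulation rates are related to
each subject's position in a normative functional connectome, the local
effect of spreading on functional connectivity is quantified and its
amyloid mediation tested, and subjects are subtyped by the mismatch
between their tau spreading and their functional disconnection.  This
note documents the model, its assumptions, the tunable parameters, the
synthetic cohort that stands in for the access-restricted clinical data,
and the numerical choices.

## The analysis model

**Connectome template.** Subject-level region×region matrices of
Fisher-Z-transformed Pearson correlations (`fisher_z_matrix`; r clipped
to ±0.999 so Z stays finite) are averaged over a normative cohort and
thresholded at 30% edge density (`average_and_threshold`). Thresholding
ranks *signed* values — "strongest connections" read as largest positive
correlations — and keeps the ⌈density·P⌉ largest of the P = n(n−1)/2
pairs, retaining any ties at the cut so the result is order-independent.
Retained edges get length 1/weight and the distance between two regions
is the Dijkstra shortest-path length (`to_distance`): strongly connected
regions are close.  A one-hop variant (`multi_hop=False`) is available
because "path length" could also be read as the direct inverse weight;
multi-hop is the standard connectomics convention and the default.
Unreachable pairs are flagged missing (NaN) and logged, never silently
zeroed.

**Tau positivity and epicentres.** For each region, a two-component
Gaussian mixture is fitted to the cross-subject distribution of baseline
SUVR (`fit_region_gmm`).  The posterior probability of the high-mean
component is a threshold-free tau-positivity measure; multiplying it by
the raw SUVR gives the *cleaned* SUVR, and each subject's epicentres are
the 10 regions with the greatest cleaned value (`select_epicentres`,
ties at rank 10 to the lowest region index).  EM uses deterministic
initialization (components at the 25th/75th percentiles, equal weights,
tolerance 1e-6, cap 500 iterations), so results are seed-free.  A region
is *degenerate* — posteriors forced to 0 — when it has <20 values, the
high component's weight is <0.01, or the component means are closer than
2.0 pooled SDs.  The 2.0 constant separates two regimes: EM applied to a
single Gaussian splits it into overlapping halves about 1.2–1.6 pooled
SDs apart, whereas a genuine abnormal-tau component sits several SDs
above background.  Note the exact two-Gaussian posterior is guaranteed
monotone in SUVR only between the component means when the variances
differ; in practice the mixtures fitted here are near-equal-variance and
the posterior is monotone over the data range.

**Spreading statistic.** For every subject, the distance of each of the
190 non-epicentre regions to the epicentre set is the mean over the 10
epicentres (`distance_to_epicentres`; minimum available via `agg="min"`
— the mean reads "connectivity to the epicentres" as a graded quantity).
The spreading beta (`spreading_beta`) is the least-squares slope of
z-scored regional rate on z-scored distance; with no further covariate it
equals the Pearson correlation, matching the interchangeable use of
"correlation" and "standardized β" for this quantity.  Negative values
mean faster accumulation in regions functionally closer to the
epicentres.  Regions with missing distance are dropped and counted.  An
optional Euclidean-distance covariate supports the spatial-adjacency
control analysis.  A group-level variant averages rates and distances
across subjects before regressing (default) or pools all
subject×region pairs (`mode="pooled"`).

**Rates.** Regional accumulation rates (SUVR/year) come from region-wise
linear mixed models (`estimate_rates`, mode `"mixed"`: SUVR ~ time with
a random intercept and slope per subject; a subject's rate is the fixed
slope plus their empirical-Bayes random slope) or from independent
per-subject least-squares slopes (`"subject-slope"`).  The mixed
estimator shrinks noisy individual slopes toward the population trend
and has verifiably lower RMSE in simulation; singular or non-convergent
region fits fall back to subject slopes with a logged warning, and a
region where every subject's scans lie exactly on a line short-circuits
to the (exact) subject slopes since the mixed model's residual variance
is then unidentified.  At the 500-subject scale used for the headline
beta-recovery experiment the package uses the subject-slope estimator:
with 2–4 scans per subject the two estimators agree to well within the
reported tolerance and the cross-region correlation structure — the
quantity of interest — is unaffected by shrinkage.

**FC to epicentres and mediation.** `fc_to_epicentres` averages the
Fisher-Z connectivity of each non-epicentre region to the 10 epicentres,
globally and per network (a network whose regions are all epicentres
yields a logged missing value).  Associations with subject-level
variables use OLS on z-scored continuous variables with 0/1 indicators
(sex, APOE ε4) left unscaled (`association_model`).  `mediate` is
linear product-of-coefficients mediation: a from m ~ x (+ age, sex), b
and c′ from y ~ x + m (+ covariates), ACME = a·b, ADE = c′, total from
y ~ x (+ covariates).  In nested linear models ACME + ADE equals the
total exactly (an algebraic identity, asserted to 1e-8).  Confidence
intervals are percentile intervals over 1000 case-resampling bootstrap
replicates with a fixed seed; the bootstrap is vectorized (batched
normal-equation solves) so 1000 resamples cost milliseconds.  The
proportion mediated is the signed ratio ACME/total, flagged unstable
when |total| < 2·SE(total); a bias-corrected interval was evaluated
during development and did not improve the measured coverage (94.7% at
the synthetic study conditions, 1000 replicates), so the simpler
percentile interval is reported.

**Mismatch profiling and subtyping.** Per network, FC-to-epicentres is
robust-regressed on the spreading beta across subjects
(`robust_regress`: IRLS with Tukey bisquare weights, tuning constant
4.685, MAD scale, tolerance 1e-8, cap 100 iterations).  The residual —
how much more or less disconnection a subject shows than their spreading
predicts — is discretized at ±0.7 residual SDs (`discretize`;
"exceeds" is strict, so exact-boundary values map to 0).  The sign
convention follows the original description (positive residual → −1)
and is config-flippable; cluster *labels* are derived from raw residual
means, so they do not depend on this convention.  The residual SD is the
classical (ddof = 1) SD of the final residuals; a robust (MAD-based)
alternative would also be defensible, and the classical choice is
recorded here.  The 7-value profiles are clustered with Ward
agglomerative clustering on Euclidean distances (scipy's Ward.D2-style
criterion, subjects entering in index order for a deterministic
tie-break).  `choose_k` maximizes the mean silhouette over k = 2..8,
with an admissibility rule: a k counts only if the cut yields exactly k
clusters each holding ≥5% of subjects.  On discretized data this rule is
load-bearing — without it, splitting off near-duplicate "satellite"
patterns of a handful of subjects produces silhouette-1 singleton
clusters and the plain argmax drifts to the top of the range, which is a
clustering artifact, not a subtype.  The elbow (WSS) curve is reported
as a diagnostic; silhouette wins disagreements, logged.  Finally
`label_clusters` names the k = 4 solution from cluster-mean raw
residuals: *canonical* = smallest mean |residual| (disconnection
commensurate with spreading); *resilient* = most positive overall mean
among the rest; of the remaining two, the cluster whose DMN mean falls
more than 0.5 pooled residual SDs below its non-DMN mean is
*DMN-susceptible* and the other *susceptible*.  Unresolvable patterns or
k ≠ 4 keep generic labels with a warning.

**Group statistics.** `ancova_compare` fits outcome ~ cluster +
covariates (age, sex, education by default), reports the overall cluster
F-test and all pairwise contrasts tested against the full-model residual
variance (more stable than per-pair subsets).  Pairwise p-values are
adjusted by Benjamini–Hochberg (default, FDR 0.05) or Bonferroni — both
appear in the source material, so every report names the method used.
`chi_square_freq` is the Pearson χ² without continuity correction,
warning when an expected count is below 5.  `longitudinal_lme` models
repeated cognitive scores with a per-subject random intercept and fixed
effects for baseline score, time, cluster, cluster×time and covariates;
the interaction coefficients are cluster-specific extra decline in
outcome units per year (Wald tests).  A cohort without repeated
observations is an error; a degenerate random-effects fit falls back to
pooled OLS with a warning.

## The synthetic cohort

Real inputs for this analysis are access-restricted, so the package
ships a generator (`synthetic.py`) producing a cohort with the
statistical structure the analysis assumes.  All randomness derives from
one seed; the same configuration is byte-identical.  The planted truth
is emitted separately (`truth.json`) and no analysis stage reads it
(verified by a test that deletes it and reruns the pipeline from files).

Defaults are the study conditions: 211 subjects (94 Aβ-positive / 117
Aβ-negative), a 200-region parcellation with the seven canonical
cortical networks at their 200-parcel proportions (31/37/23/22/13/30/44),
a 69-subject normative template with 200 frames per run, 2–4 tau scans
per subject with total follow-up ~N(1.83, 1.23²) years truncated to
[0.5, 6] (the alternative per-group durations of 3.3±1.6 / 2.6±1.2 years
are a config choice), APOE ε4 carrier rates of 26%/59% by amyloid
status, and ages/education matching the reference demographics.

* **Template**: frames drawn i.i.d. from a block covariance
  (within-network correlation 0.5, between 0.1); a non-PD combination is
  a configuration error naming the offending parameters.  Finite frames
  supply natural per-subject sampling noise.
* **Tau**: each subject gets a seed region from a 3-candidate pool
  spread over limbic, default-mode and visual cortex (so each lifted
  region stays bimodal across subjects — with all seeds in one network
  every subject would lift the same regions and the cross-subject
  mixture would collapse to unimodal).  The planted epicentre set is the
  10 graph-nearest regions to the seed; baseline SUVR is
  N(1.1, 0.05²) background (truncated at 0.8) plus a lift of
  0.6·exp(−d/2.0) on the planted set, giving >4 pooled-SD separation for
  the mixture step.  Regional yearly rates over the 190 non-epicentre
  regions are drawn with population correlation ρᵢ against the
  distance-to-epicentre profile, ρᵢ ~ −0.3 ± 0.3 across subjects
  (clipped to a valid correlation); epicentre regions themselves
  accumulate fast.  Scans add N(0, 0.01²) measurement noise.
* **Amyloid**: regional maps with a +0.4 global shift for Aβ-positive
  subjects; the epicentre-region mean is set exactly to the planted
  mediator m = base + a·s + N(0, 0.4²), where s is the latent spread
  strength driving ρᵢ.
* **Subject FC**: the per-network FC-to-epicentre target is
  c₀ − c′·s − b·m + group offset + N(0, 0.035²), planting the mediation
  path (a, b, c′) = (0.4, 0.125, 0.15), i.e. a mediated proportion
  a·b/(a·b + c′) = 0.25.  The target is realized through a latent
  epicentre factor added to the block base covariance: epicentre regions
  load 1.2 on the factor and each non-epicentre region's loading is the
  closed-form quadratic root that makes its epicentre correlation equal
  the target (targets beyond the attainable bound are clamped and
  counted).  The covariance is positive definite by construction, so
  time-series can be sampled exactly — an earlier paint-the-block
  construction needed an eigenvalue-clipping projection that distorted
  the targets by up to ±0.35 Z and was discarded.  A config switch emits
  exact correlation matrices instead of time-series.
* **Groups**: four planted clusters with per-network FC offsets —
  canonical 0 everywhere; resilient +0.5 everywhere; susceptible −0.5 in
  the six non-DMN networks; DMN-susceptible −0.5 in the DMN only.  The
  offsets form a balanced multiset {0, 0, +0.5, −0.5} within every
  network so the robust regression line stays centred under random
  group-size imbalance; this keeps each group's residual about 4 noise
  SDs clear of the 0.7·SD discretization cut, which is what makes the
  clusters recoverable.  The magnitudes are deliberately larger than a
  realistic effect so recovery properties are sharp.
* **Cognition**: linear trajectories (3 annual visits) with
  cluster-specific slopes (−0.05/−0.02/−0.15/−0.10 per year), subject
  random intercepts (SD 0.4) and visit noise (SD 0.15), feeding the
  longitudinal mixed-model stage.

What the generator does **not** emulate: voxel-level images,
haemodynamics, tracer kinetics, spatial autocorrelation beyond the
network blocks, missing visits, scanner or site effects, and realistic
effect sizes for the group offsets.  Passing recovery tests therefore
demonstrates the estimators' correctness and calibration under the
assumed generative structure, not their power on clinical data.

## Problem sizes and seeds

The recovery experiments run at: spreading beta — 500 subjects × 200
regions, one cohort; mediation — 100 (script) / 200 (test) replicates of
n = 200 with 1000 bootstraps each; clustering — 50 replicates of 211
subjects at the subject level (the full imaging chain is exercised once
end-to-end in the pipeline suite — its per-replicate cost adds nothing
statistically since the subject-level sampler uses the identical planted
model); null ANOVA — 1000 cohorts of n = 120.  Unit tests use a
60-region parcellation with proportionally scaled networks.  All seeds
are fixed (tests) or derived from the acceptance script's `--seed`.

## Known limitations

* The estimated spreading beta is a noisy proxy of the latent spread
  strength; in mediation this attenuates path coefficients (the mediated
  *proportion* is invariant to attenuation in x, but not to measurement
  error in the mediator).
* Greedy agglomerative Ward is not guaranteed to reach the global
  minimum-variance partition on adversarial inputs; the oracle tests
  verify exact optimality on structured draws of ≤8 profiles, the regime
  the pipeline operates in.
* The mediation CIs are percentile bootstrap intervals; their measured
  coverage at the study conditions is ~95% nominal minus the usual
  small-sample ratio penalty (94.7% measured).
* With the 60-region toy parcellation, near-tied graph distances around
  a seed make epicentre recovery partial (~80% overlap); at the full 200
  regions recovery is ~95%.
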