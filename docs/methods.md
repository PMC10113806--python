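# Methods

`uvconf` re-implements, against fully synthetic data, the analysis chain of
a three-task perceptual confidence experiment: an orientation
discrimination task (clockwise vs anticlockwise), a yes/no detection task
(grating present vs absent) and a tilt-recognition task (vertical vs
tilted) in which one stimulus class has higher evidence variance than the
other, mimicking detection's asymmetry. This note records the models, the
conventions chosen where the design was genuinely open, and what the
synthetic data do and do not establish.

## Evidence model and behavioural metrics

Decisions are modelled with unequal-variance signal detection theory
(UV-SDT): a trial draws a scalar evidence sample from N(mu_low,
sigma_low^2) or N(mu_high, sigma_high^2), and 11 strictly increasing
criteria carve the axis into a folded 12-point rating scale — (respond
low-variance class, confidence 6..1) then (respond high-variance class,
confidence 1..6). The log-likelihood ratio of a sample is linear in the
sample when the variances are equal and quadratic otherwise; that
linear/quadratic distinction is the conceptual backbone of the whole
package.

Default criteria place the decision criterion at the ideal-observer
boundary (the increasing crossing of the LLR with the log prior odds) and
the five confidence criteria per side at mixture quantiles conditional on
that side. Two consequences match the empirical phenomenology of such
tasks: all 12 rating bins are populated in expectation, and with unequal
variances the observer gives the low-variance response on more than half
of the trials.

* **zROC slope.** Cumulative "high-side" proportions at the 11 criteria
  are z-transformed; a slope is estimated in both regression directions
  (z-hit on z-FA, and the reciprocal of the z-FA-on-z-hit slope) and their
  geometric mean returned. Group summaries exponentiate the mean of log
  slopes, i.e. a geometric mean across observers as well; group tests are
  t-tests on log slopes against 0. A log-linear correction (0.5 added to
  every cumulative cell, 1 to every total) keeps empty extreme bins
  usable. For Gaussian classes the estimator converges to
  sigma_low/sigma_high; at 1000 trials per class its small-sample bias is
  below ~0.01.
* **AUROC2.** Metacognitive sensitivity per response is the area under the
  response-conditional type-2 ROC (cumulative p(conf >= k | correct) vs
  p(conf >= k | error)), anchored at (0,0) and (1,1) and integrated by
  trapezoids; this equals the Mann-Whitney pair-counting statistic with
  ties counted half.
* **Ideal-observer response rate.** The probability of the low-variance
  response under the posterior rule is computed analytically from the
  quadratic LLR (the response region is one or two intervals) and
  integrated class-wise with Gaussian CDFs.

## Synthetic sessions

`synth.simulate_session` emulates the scanning protocol: 5–6 runs, each
with one 26-trial block per task in random order; uniform 0.5–4 s rest
jitter (the jitter law is our choice; only the range is specified by the
protocol), 0.5 s fixation, 0.5 s stimulus, 1 s decision window, 2.5 s
rating, 2 s instruction screens; balanced classes; independent Bernoulli
lapses (default 3%) with no response or confidence recorded. Stimulus
difficulty maps onto the evidence separation: a per-task gain multiplies
mu_high − mu_low, playing the role the visibility *v* (or the orientation
spread) plays at the stimulus level, and the between-block staircase
(easier at <= 52.5% accuracy, harder at >= 85%, factor 0.95) updates that
gain. The within-block (every-10-trials) rule used during practice
calibration applies the same 0.95 factor; the factor is only printed for
the between-block rule, so this is a package convention. Default
observers use separation 1.4 and sigma ratios 1.0 / 0.74 / 0.55
(discrimination / detection / tilt recognition), which lands accuracy in
the 70–80% band after calibration.

Stimulus clips themselves (10 frames of 142x142 uniform random luminance,
a 0/1-normalised sinusoidal grating at 24 pixels/period with random phase,
per-pixel replacement with probability p_i = v·exp(−|i−5|/2)) are
generated for completeness and tested, but the behavioural simulator works
at the SDT level rather than rendering pixels per trial.

## ROI time series and the two GLM routes

`synth.simulate_roi_timeseries` gives every usable responded trial a 4-s
boxcar with amplitude `a_r + g1·c + g2·c²`, where `c` is confidence
mean-centred within the response; first-of-block and excluded-block trials
contribute unmodulated unit boxcars, mirroring their nuisance treatment in
the design matrices. Boxcars are convolved with a canonical double-gamma
HRF (gamma shapes 6 and 16, undershoot ratio 1/6, 32 s support,
peak-normalised; it matches the SPM-style kernel to r > 0.99) on a 0.1 s
grid, sampled at the TR (default 2 s), and white noise is added. High-pass
filtering and autocorrelation modelling are deliberately absent because
the synthetic noise is white.

**QC-DM (quadratic-confidence design matrix).** Per response: a boxcar
regressor plus mean-centred linear and serially orthogonalized quadratic
confidence modulators (order main → linear → quadratic, a conventional
serial Gram–Schmidt; we do not reproduce any particular package's
orthogonalization bit-exactly) — 18 regressors of interest when all six
responses occur. Nuisance columns: missed trials, first trials, excluded
blocks, instruction screens, three button-press stick regressors, optional
motion/physiological matrices, and run constants that partition the scans
(no additional global intercept). Estimation is OLS; a rank-deficient
design raises an error naming the collinear columns.

The quadratic modulator's beta equals the generating `g2` directly. The
linear beta additionally absorbs what orthogonalization moved out of the
quadratic column; `glm.qc_gain_estimates` undoes that bookkeeping
(subtracting `g2·(alpha − 2·mean(conf))`, with `alpha` the slope of the
centred squared confidence on the centred confidence), recovering `g1`
exactly in the noise-free limit.

**Categorical route.** Per task, a single of-interest boxcar carries 12
dummy (0/1) modulators — response x confidence level — with the other two
tasks in the baseline plus an aggregate nuisance boxcar for their evoked
responses. Because every included trial activates exactly one dummy, the
base regressor equals the sum of the dummy columns and the design is
rank-deficient *by construction*; it is fitted with the minimum-norm OLS
solution (`allow_rank_deficient=True`). The indeterminacy shifts all 12
dummy betas by a common constant, which the second step absorbs into its
intercept, so the linear and quadratic contrasts of interest are
estimable. The second step regresses each response's six level betas on
{1, conf, conf²} without orthogonalization and with every level weighted
equally, making the estimates indifferent to the confidence frequency
distribution. A known limitation: confidence-modulation *fluctuations* of
the unmodelled other-task trials can leak into the estimates (up to ~10%
of a quadratic gain in our noise-free layout); the QC-DM route, which
models all tasks at once, has no such leakage.

Group inference applies per-subject contrasts (e.g. quadratic tilt −
quadratic discrimination) followed by one-sample t-tests with Cohen's
d = t/sqrt(n), one-way repeated-measures ANOVA (df (k−1, (k−1)(n−1))), and
JZS Bayes factors for t-contrasts: BF01 under a Cauchy(0, r) prior on the
standardized effect (default r = sqrt(2)/2 ≈ 0.707), computed by adaptive
quadrature over the effective inverse-gamma prior on g. Two-sided tests
throughout; no multiplicity correction for pre-specified ROI tests.
ANOVA-form Bayes factors are out of scope.

## RSA

The 12 conditions are task x response x confidence{low, high}, with
confidence split at the per-response median (ratings at or below the
median are "low"; a response-invariant overall-median cutoff is available
as a flag). Empirical RDMs use mean cross-run Euclidean distances — entry
(i, j) averages ||pattern(i, run r) − pattern(j, run s)|| over all ordered
pairs r ≠ s — so within-run noise correlations never contaminate the
entries and the diagonal holds informative cross-run self-distances.

Eight theory RDMs are provided (task; variance structure; detection
decision; UV decision; task-invariant confidence; confidence graded by
variance structure; detection-only confidence; UV-only confidence). Two
masking conventions needed fixing where theory left them open:

* Single-factor within-task models (C, D, G, H) are defined only inside
  their task block(s) and only for pairs differing in exactly one of
  (response, confidence); pairs differing in both carry no prediction.
  This makes G exactly the complement of C on their shared domain, so
  their off-diagonal Spearman correlation is −1 — the behaviour the
  original analyses report — and it is the convention our constructors
  enforce.
* Confidence models E and F predict within-cell (same task and response)
  contrasts and all cross-task pairs (confidence-aligned similar, crossed
  dissimilar), and are masked on within-task cross-response pairs. With
  this support, the 18 sub-RDMs below span E's unmasked entries exactly.
* F grades the confidence contrast by variance structure: weight 1.0 for
  UV-task conditions, 0.5 for discrimination, pair weight the mean of the
  two. The weights are configurable; nothing downstream depends on the
  exact grading because comparisons are rank-based.

Mask-free binary variants of all models are available
(`theoretical_rdms(masked=False)`).

Model fit is the Spearman correlation over off-diagonal entries where the
model makes a prediction. Reliability diagnostics: (i) the mean rank of
off-diagonal entries minus the mean rank of the diagonal, per subject,
t-tested at the group level (condition structure makes cross-run
self-distances the smallest entries); (ii) a leave-one-out noise-ceiling
lower bound — each subject's off-diagonal entries correlated with the
average ranked RDM of the remaining subjects.

A caveat the simulations exposed: when the shared group structure is
tie-heavy (e.g. patterns generated from a binary model RDM), the exact
tied model predictor can legitimately exceed this lower bound, because
rank transformation spreads arbitrarily small between-subject jitter over
the full within-class rank range. With continuous shared structure and
moderate noise — the realistic regime — the bound behaves as intended, and
that is the regime in which the bounding property is tested.

**Sub-RDM decomposition.** RDM E decomposes into 18 constituents: 6
within-cell sub-RDMs (one per task x response cell, contrasting its high
vs low confidence conditions) and 12 between-cell sub-RDMs (one per
across-task pair of cells; within-task cross-response pairs are excluded —
the only enumeration of this shape that yields 18). The empirical
off-diagonal entries on the union support are regressed on the 18
indicators plus an intercept. Two equal-weight beta combinations encode
the competing hypotheses: the response-specific detection–tilt combination
averages the betas pairing 'yes'↔'tilted' and 'no'↔'vertical' (the
variance-matched responses), and the response-invariant
tilt–discrimination combination averages all four response pairings; their
difference is a paired t-test.

**Pattern generator.** Condition prototypes are embedded from the
generating RDM by classical multidimensional scaling, treating entries as
squared distances (masked entries filled with the mean defined entry); if
the matrix is not Euclidean-embeddable a constant is added to all
off-diagonal entries — a rank-preserving shift — before re-embedding.
Prototypes are rotated into voxel space by a random orthonormal map and
independent Gaussian run noise is added. Since all downstream comparisons
are rank-based, any monotone embedding is adequate.

## Pipeline defaults (the simulated study conditions)

35 subjects; 6 runs; sigma ratios 1.0 / 0.74 / 0.55; lapse rate 3%;
exclusion rules: >20% missed trials per block (evaluated over all 26
trials), accuracy < 60%, the same response on > 80% of usable trials, the
same confidence on > 90% of trials for a response (only evaluated for
responses with at least 5 trials — a guard of ours); the first trial of
every block is dropped (25 usable), and subjects need three surviving
blocks per task. ROI gains: linear 0.15 in all tasks; quadratic 0.10
(discrimination), 0.10 (detection), 0.25 (tilt recognition) — the
"strongest in the asymmetric-discrimination condition" regime — with
between-subject gain spread 0.05 and unit scan noise. Patterns are
generated from model E scaled by 16 (squared-distance units) with unit
voxel noise across 60 voxels, i.e. task-invariant confidence geometry.
Every output table carries the seed and a config hash, and identical
config + seed reproduce every table byte-for-byte.

Problem sizes throughout the test-suite simulations (2–6 run sessions, 20
seeds for recovery checks, 200 noise simulations for the type-I-error
check, 12–16 subjects for RSA group checks) were chosen as the smallest
cohorts at which the checked quantities stabilise.

## What passing tests do and do not show

The generators share their trial-selection and confidence-coding
conventions with the estimators, so recovery tests validate the estimation
machinery, not robustness to convention mismatch. White scan noise means
the GLM results say nothing about drift, physiological spectra or
autocorrelation (an AR(1) flag exists for the curious, default off).
Evidence is Gaussian by construction, so zROC linearity is exact in
expectation rather than an empirical finding. Real fMRI pattern noise is
spatially correlated; our run noise is i.i.d. across voxels, which flatters
cross-run distance estimates. Finally, meta-d' fitting, response-time
modelling, whole-brain mass-univariate maps, cluster-level corrections and
searchlight/crossnobis RSA are all out of scope.
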