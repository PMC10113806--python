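# uvconf

Unequal-variance signal detection, confidence GLMs and representational
similarity analysis (RSA) for three-task perceptual confidence
experiments — with a synthetic-data generator that stands in for the
scanner.

The package is aimed at computational cognitive neuroscientists studying
metacognition: it models an experiment in which participants perform an
orientation **discrimination** task (clockwise vs anticlockwise), a yes/no
**detection** task (grating present vs absent) and a **tilt-recognition**
task (vertical vs tilted) engineered so that one stimulus class has higher
evidence variance — an "asymmetric discrimination" that shares detection's
distributional structure without requiring inference about stimulus
presence.

## The models

**Evidence and confidence.** A trial draws evidence x from N(mu_0,
sigma_0^2) (low-variance class) or N(mu_1, sigma_1^2); 11 ordered criteria
map x to a response and a 1–6 confidence rating. The log-likelihood ratio

    LLR(x) = log N(x; mu_1, sigma_1) − log N(x; mu_0, sigma_0)

is linear in x iff sigma_0 = sigma_1 and quadratic otherwise. Signatures
of unequal variance in behaviour: the type-1 zROC slope (geometric mean
over regression directions; → sigma_0/sigma_1 for Gaussian classes) falls
below 1, the response-conditional type-2 ROC area (AUROC2) is higher for
the high-variance response, and an ideal observer favours the low-variance
response.

**Confidence GLMs.** ROI time series are analysed with (a) a
quadratic-confidence design matrix — per response a 4-s boxcar plus
mean-centred linear and orthogonalized quadratic confidence modulators,
18 regressors of interest, convolved with a canonical double-gamma HRF —
and (b) a categorical route: 12 dummy modulators (response x confidence
level) whose betas feed an unorthogonalized second-step fit on
{1, c, c²}, weighting all confidence levels equally regardless of their
frequency. Group inference uses OLS contrasts, t-tests with d = t/√n,
repeated-measures ANOVA, and JZS Bayes factors (Cauchy prior on effect
size, default scale √2/2).

**RSA.** Empirical 12x12 RDMs (3 tasks x 2 responses x median-split
confidence) use mean cross-run Euclidean distances, compared by Spearman
correlation against 8 theory RDMs with no-prediction masks, alongside
on/off-diagonal reliability tests and a leave-one-out noise-ceiling lower
bound. The task-invariant confidence RDM decomposes into 18 sub-RDMs whose
regression betas combine into response-specific (detection↔tilt) and
response-invariant (tilt↔discrimination) similarity scores.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Simulate one observer cohort at the default study conditions (35 subjects,
6 runs of three 26-trial blocks, evidence sigma ratios 1.0 / 0.74 / 0.55)
and summarise behaviour:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_behavioral_metrics.py
```

which prints (seed 1):

```
accuracy by task: {'discrimination': 76.6, 'detection': 73.9, 'tilt_recognition': 73.3}
discrimination: geo-mean zROC slope 1.01 (t_34 = 0.26 on log slopes, p = 0.795, d = 0.04, BF01 = 5.34); low-response rate 0.51
detection: geo-mean zROC slope 0.80 (t_34 = -9.62 on log slopes, p = 3.08e-11, d = -1.63, BF01 = 3.22e-09); low-response rate 0.58
tilt_recognition: geo-mean zROC slope 0.64 (t_34 = -18.19 on log slopes, p = 4.3e-19, d = -3.07, BF01 = 9.31e-17); low-response rate 0.64
```

Discrimination behaves like an equal-variance task (slope ≈ 1, balanced
responses); detection and, more strongly, tilt recognition show the
unequal-variance signatures: slopes below 1, a bias toward the
low-variance response ('no', 'vertical'), and (also printed) higher
metacognitive sensitivity for 'yes'/'tilted' than for 'no'/'vertical'
responses.

`analysis/03_confidence_glm.py` fits both GLM routes to simulated ROI
series whose quadratic confidence gain is 0.10 in discrimination and
detection but 0.25 in tilt recognition:

```
route qc (quadratic confidence):
  tilt_minus_disc: t = 10.16, p = 7.82e-12, BF01 = 8.73e-10
  det_minus_disc:  t = -0.92, p = 0.362,    BF01 = 3.72
```

i.e. a clearly stronger quadratic effect in the asymmetric-discrimination
condition and moderate Bayesian evidence *against* a detection–
discrimination difference. `analysis/04_rsa.py` runs the RSA battery on
patterns generated from the task-invariant confidence model (E), which
wins the model comparison (mean Spearman 0.72), and finds no reliable
difference between the two beta combinations (t_34 = 0.40, p = 0.69) —
the task-invariant outcome.

The same stages are scriptable via the CLI (`uvconf simulate-behavior`,
`analyze-behavior`, `simulate-imaging`, `analyze-glm`, `analyze-rsa`,
`report`); `uvconf report --seed 1` runs everything and writes the full
TSV bundle, reproducibly to the byte.

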