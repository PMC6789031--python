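# Methods

## Overview

`soctouch` analyzes cortical single-unit spiking during naturalistic social
facial touch.  The pipeline has five stages: (1) a session data model with
behavioral summaries and PSTHs; (2) a Poisson point-process GLM with
spike-history terms and two shuffle-based significance tests that label
units *touch*, *sex-touch*, or *nonsignificant*; (3) an information-per-
spike statistic over partner-identity categories; (4) a mixed-effects
population model separating additive *bias* from multiplicative
*potentiation* in male- vs female-partner modulation; and (5) a layered
leaky-integrate-and-fire (LIF) microcircuit that simulates how an
oxytocin-like increase in inhibitory drive shapes touch responses.
Because no public dataset accompanies the design, a calibrated synthetic
generator produces sessions with the behavioral and spiking structure the
analysis assumes; all tests run on these.

## Point-process GLM

Spike trains are discretized in 1-ms bins (`dt`); bins more than 5 s from
any touch episode are dropped from the likelihood (their spikes still feed
the history regressors — the spikes existed; only likelihood rows are
removed).  The conditional intensity is `lambda_i = exp(P_i . beta)` with
columns: constant; five 1-ms spike-history lags and six 25-ms lag windows
covering the previous 155 ms; per-recording baseline indicators
(`n_rec - 1` columns); a touch indicator; and a partner-sex indicator.
A lag-`l` spike (1 <= l <= 5) maps to history column `h_l` ("previous
(l-1)–l ms"); window boundaries are half-open toward longer lags.

The sex column is raised only during touch episodes with a male partner.
A block-constant coding is not usable: with one partner per recording
block, a block-constant sex column is an exact linear combination of the
constant and the recording indicators, leaving the sex coefficient
unidentifiable.  Under the touch-gated coding the fold changes are exact:
female modulation `exp(b_touch)`, male modulation `exp(b_touch + b_sex)`
over the `exp(b_0)` baseline.

Fitting is Newton's method with step-halving (the Poisson log-link
likelihood is concave, so the optimum is global); convergence is declared
when the gradient infinity-norm falls below `1e-8 * sum(y)`.  The
log likelihood includes all constant terms so model variants fitted to the
same train are comparable on an absolute scale.  Shuffle-null refits share
a single design matrix in which only the permuted column is rewritten; the
Newton solve there uses a single-precision Hessian while the convergence
check stays in double precision on the exact gradient, which leaves the
optimum unchanged (verified against the reference fitter to 1e-13 nats)
and roughly halves the cost of the ~200 refits per unit.

### Shuffle tests

*Touch*: the touch column is circularly rotated along the concatenated
retained-bin axis (episode durations and spike autocorrelation are
preserved), with a minimum shift of 1 s; 100 rotations; the p value is the
plus-one upper-tail permutation estimate of the refitted log likelihoods
against the observed one.  *Sex*: partner labels are permuted at the
partner-animal level, preserving the male/female counts.  Labels follow
the convention female = 0, male = 1.

A structural fact constrains the sex test: flipping *all* labels maps the
sex column to `touch - sex`, which spans the same model space, so the
complement assignment always ties the observed likelihood exactly.  With
two partners per sex only ~3 distinct column spans exist and the test
cannot reach p < 0.05 (ties are counted, keeping the estimator
conservative and exact).  Calibration and power studies therefore use
eight-block sessions with four partners of each sex, within the
experimental design of four to eight partner blocks; with 4+4 partners the
achievable p floor is ~0.04 and the empirical type-I rate sits at the
nominal 5%.

Classification: *sex-touch* iff `p_sex < 0.05`; *touch* iff
`p_sex >= 0.05` and `p_touch < 0.05`; else *nonsignificant*.

## Synthetic sessions

Touch durations and inter-touch intervals are i.i.d. log-normal.  The
generator is calibrated from the printed behavioral statistics by solving
`mu = ln(median)` and `sigma = (ln q75 - ln q25) / (2 * 0.6745)`:
durations median 1.33 s (sigma 0.88), intervals median 4.68 s (sigma
2.19, spanning orders of magnitude).  A two-parameter log-normal matches
the median and the quartile *ratio*; the printed quartiles themselves are
slightly asymmetric around the median in log space and cannot all be
matched exactly by any two-parameter choice.  Episodes are tiled into
recording blocks (default four 600-s blocks, one partner per block,
alternating sexes); an episode that would cross a block end is dropped.
The latency from partner introduction to first touch is exponential with
5-s mean — the printed statistics constrain durations and between-bout
intervals, not this latency, and the heavy-tailed interval law would
otherwise leave short blocks episode-free.

Spike trains are simulated from the GLM itself, bin by bin, with the
count in each bin Poisson with mean `dt * exp(row . beta)`; the row is
built by the same predictor constructor used for inference, so encoder
and decoder cannot drift apart.  A warning is emitted if `lambda*dt`
exceeds 1 in more than 1% of bins.

The population-table generator draws per-unit female modulation (log2
scale, centered, spread 1.2) and produces male modulation from a linear
model with bias, slope, subject-sex main effect, interaction, per-subject
random intercept, and residual noise — the bias/potentiation geometries
the population model is meant to distinguish.

## Information per spike

`I = (1/lam) * sum_i lam_i log2(lam_i/lam) p_i` bits/spike with occupancy
probabilities `p_i` and category rates `lam_i` estimated as total spikes
over total occupancy time; `0 log 0 := 0`.  Significance uses a circular
rotation of the spike train relative to the episode timeline (equivalent
to shifting the episodes over the recording), 200 shifts, plus-one upper
tail.  The sex-information excess (real minus partner-label-shuffled
information over {baseline, male touch, female touch}) is tested with
`delta_i ~ 1 + (1 | unit)` fitted by maximum likelihood, because shuffles
within a unit are dependent; with a single shuffle per unit this
degenerates to a one-sample t test (checked numerically).

## Population model

Per-unit fold modulations come from the fitted coefficients; units beyond
a 32-fold increase or decrease on either axis are excluded.  The model

    male_mod ~ 1 + female_mod + subject_sex + female_mod:subject_sex
               + (1 | subject)

is fitted on the log2 fold-change scale (symmetric for increases and
decreases and matching the exclusion geometry; the ratio scale is
available via an option) with `statsmodels` MixedLM, REML by default,
Wald confidence intervals.  Potentiation is claimed when the slope CI
excludes 1, bias when the intercept CI excludes 0.  With a single subject
the random intercept is unidentifiable and an OLS fall-back is used with
a warning.  Area-wise label proportions are compared with a chi-square
test of independence plus standardized Pearson residuals
`(O - E)/sqrt(E(1 - p_row)(1 - p_col))`, flagged at |r| > 1.96; rank
association uses tie-adjusted Kendall's tau-b.

## LIF microcircuit

Eight cortical populations (L2/3e/i, L4e/i, L5e/i, L6e/i; 77,169 neurons
at full scale) plus 902 thalamic Poisson units.  For each population pair
the synapse count is `K = log(1 - p_conn)/log(1 - 1/(N_pre N_post))`;
synapses are assigned uniformly with replacement (multapses and autapses
allowed).  Membrane: `tau_m` 10 ms, `C_m` 250 pF, reset/rest −65 mV,
threshold −50 mV, refractory 2 ms; exponential synaptic currents with
`tau_syn` 0.5 ms; excitatory weights Normal(87.8, 8.8) pA truncated at
zero by redraw, inhibitory weights −4× an excitatory draw, the L4e→L2/3e
weight doubled; delays Normal(1.5, 0.75) ms excitatory / Normal(0.8, 0.4)
ms inhibitory, truncated below at one 0.1-ms step; background current
`b * 0.3512 pA` per population; initial V Normal(−58, 10) mV.  The
connection-probability cell L5e→L2/3i prints ambiguously (0.3075); the
value consistent with the upstream microcircuit model (0.0755) is the
default and the printed value is available by option — the full-scale
synapse total rounds to 0.3 billion either way.

Integration is the exact propagator of the linear membrane/synapse system
at 0.1-ms steps (matches the analytic subthreshold solution to 1e-9);
arrivals are applied at step boundaries.  Trials: 1000 ms baseline,
700 ms touch (thalamic rate 30 Hz), 300 ms post.  Neuromodulation, active
only during the touch window of modulated trials (interleaved with
non-modulated ones): inhibitory reset/rest potential depolarized by
{0, +0.5, +1.0} mV, and/or excitatory `tau_m` scaled by {1.0, 1.1, 1.2}
(an input-resistance increase, `tau_m = R_m C_m`).  Per-neuron responses
`beta = ln(r_touch/r_base)` use pooled 700-ms windows; neurons with fewer
than three spikes across trials or a zero-count window are excluded; a
random sample of 2000 neurons is analyzed.  Response-pattern selection
compares bias (`Y - X ~ 1`), potentiation (`Y ~ X`, no intercept) and
full (`Y ~ 1 + X`) OLS fits by `BIC = n ln(RSS/n) + k ln(n)`.

### Downscaling and its limits

Reduced-scale networks preserve the per-target in-degree (K scales with
the realized target population), keeping single-neuron input statistics
approximately invariant.  The default desk scale for the test suite is
0.05 (≈3,860 neurons, ≈15M synapses, 10+10 trials), chosen so the full
neuromodulation grid runs in a few minutes on one CPU.  Two caveats
follow, and they are limits of the downscaling, not of the full model:

1. Shared-input correlations grow roughly as 1/scale.  Under the
   excitability manipulation this synchronizes the L4i/L2/3i feedforward
   loop and produces a paradoxical suppression of L2/3e that masks the
   additive-bias regime; the population-mean response shift moves from
   −0.29 (scale 0.05) through −0.14 (0.1) to +0.03 (0.2, with deep layers
   strongly positive), i.e., the bias regime emerges only toward full
   scale.  The inhibitory-drive potentiation regime (slope < 1) and the
   null-modulation exchangeability are robust at desk scale.
2. Per-neuron `beta` estimates from twenty 0.7-s windows carry sampling
   noise comparable to the between-neuron spread, so any regression of
   modulated on non-modulated responses is attenuated below unit slope
   (classical errors-in-variables); model selection at desk scale is
   biased toward potentiation/full over bias.

Because neurons share trials, their response differences are strongly
correlated; per-neuron paired tests are invalid for the null check, and a
trial-label permutation test (population-mean difference statistic) is
provided instead.

## Spike-shape classification

Features: spike width at half maximum and post-positivity (waveform
integral 0.375–0.75 ms after the peak, normalized by peak voltage), both
computed on a cubic-spline interpolation at twice the sampling rate and
invariant to amplitude scaling.  Units are clustered in z-scored feature
space by a two-component Gaussian mixture (additive diagonal
regularization 0.1 on the z-scored features); the thin-spiked component
is labeled putative inhibitory.  Where the feature cloud is not bimodal a
single 2-d Gaussian is fitted and the cloud is cut through its mean along
the shortest principal axis (split by the sign of the projection on the
largest-variance eigenvector).  Classes are "putative" throughout: spike
shape is a weak proxy for cellular identity.

## Test-suite problem sizes

Parameter recovery uses twenty 600-s eight-block sessions; shuffle-test
calibration uses 200 null units on 64-s eight-block sessions with 100
shuffles per test (type-I rates checked against the central 95% binomial
band around 5%); information-test calibration uses 100 homogeneous units
at 200 shifts; population-regime recovery uses 150 units across six
subjects per seed, 20 seeds per regime.  The interval-median calibration
check uses the analytically derived 3-sigma Monte-Carlo band for the
10,000-draw sample median (the calibrated log-sd of 2.19 makes the sample
median itself 2.7% noisy at that n).

## Known limitations

- The generator draws episode durations and intervals i.i.d.; real touch
  is bursty beyond what a renewal process captures, and no whisking,
  vocalization or olfactory covariates exist.  Passing tests show the
  estimators are correct and calibrated under the assumed model, not that
  the model captures every structure of real sessions.
- The GLM assumes within-bin Poisson counts and log-linear covariate
  effects; strong bursting beyond the history terms is not modeled.
- Full-scale (77k-neuron) simulation is supported by the same code path
  but is not exercised in the test suite for memory/time reasons.
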