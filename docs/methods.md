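# Methods

This note records the modelling assumptions, parameter defaults, and
numerical choices behind `advicerl`, and what the synthetic-data experiments
do and do not demonstrate.

## Task model

A session is a sequence of trials (default 290) on which one of two colours
is correct. Two latent processes drive the feedback: the probability that
green is correct, and the probability that the partner's advice points to
the correct colour. Both are piecewise-constant block processes that reverse
several times per session and vary independently of one another; reward
magnitudes on the two options are uniform integers in [1, 100], independent
of both processes. The true block structure of the original task is not
publicly specified, so the default configuration is a documented choice, not
a reconstruction: five blocks per process, reward probability alternating
0.8/0.2 (block lengths 60/50/70/40/70), advice fidelity alternating
0.75/0.25 (45/65/55/75/50), with the reversal points of the two processes
deliberately misaligned. All of this is configurable per session.

Feedback is fully observable (the correct colour is revealed whatever the
player chose), so the binary outcome streams — "green was correct" and "the
advice was correct" — are functions of the schedule alone. Every belief
trajectory is therefore choice-independent, which is what makes dense grid
evaluation of the choice likelihood affordable: beliefs are computed once
per subject and shared across all parameter nodes.

## Volatility-adaptive tracker

Each outcome stream is tracked by a sequential grid filter over three
latents: the outcome probability `r`, its log-volatility `v` (how fast `r`
drifts), and a static log-volatility-of-volatility `k` (how fast `v`
drifts). Per trial the joint is propagated — `r` through a beta kernel with
mean `r` and total concentration `exp(−v)` (so dispersion grows with
`exp(v)` while the mean is preserved), `v` through a Gaussian random walk
with SD `exp(k)` — then multiplied by the Bernoulli likelihood of the
observed outcome and renormalised. The trial-`i` estimate is the predictive
mean of the `r` marginal taken after propagation but before that trial's
likelihood, so a choice never sees its own feedback. The prior is uniform
over the joint grid, making the first estimate exactly 0.5.

The exact kernel family matters little downstream (only the estimate
sequence is consumed), but it is fixed and documented: grid 30×30×30, `r` on
30 equispaced points in (0.01, 0.99), `v` ∈ [−11, −2], `k` ∈ [−8, 2] (log
scale). Transition kernels are evaluated as densities at grid nodes and
column-normalised; the joint is renormalised every trial and its mass is
guarded against underflow. Correctness is tested against an independently
coded filter that builds the explicit full-joint transition matrix from
textbook beta/normal densities and renormalises by explicit summation
(agreement to 1e−10 over 100-trial sequences).

The tracker's defining behaviour — an effective learning rate
`(e[i+1] − e[i]) / (o[i] − e[i])` that rises in reversal-rich stretches and
decays in stable ones — is exposed as a diagnostic (`adaptive_gain`) and
tested directly. The fixed-learning-rate alternative is the plain
Rescorla–Wagner delta rule with initial estimate 0.5 and spread reported as
zero.

## Choice model

Tracked probabilities are weighted by logistic transforms centred at 0.5
with per-subject gains γ_social and γ_reward history, fused by Bayes' rule
over the advised colour, converted to expected values with the trial's
magnitudes, and passed through a softmax with inverse temperature β (units:
1/points). Two numerical conventions:

* probabilities are clamped to [1e−9, 1 − 1e−9] before the odds-ratio
  fusion, so degenerate beliefs cannot divide by zero;
* every sigmoid is computed in a signed form that never exponentiates a
  large positive argument, so the policy is overflow-safe for any β.

The advice-blue branch of the fusion has two published variants; the default
is the Bayes-consistent mirror of the advice-green branch (numerator
`(1−p̂s)·p̂g`), which matches a four-world enumeration oracle to 1e−12. The
non-normalising variant is available behind `as_printed=True` purely for
audit.

## Fitting

The choice log-likelihood is evaluated on a log-spaced grid of 50 points per
parameter over [0.01, 10] (both the bounds and the log spacing are part of
the method's definition). The prior is uniform over the log-spaced grid,
i.e. log-uniform — the least informative choice consistent with log-space
integration. Within the likelihood, per-trial choice probabilities are
floored at 1e−9 to keep the sum finite.

Point estimates are marginal posterior means taken on the log scale and
exponentiated (median-like robustness for skewed marginals). Posterior
spread is reported on both scales, treating the grid posterior as a
histogram density — each node represents a log-width cell, whose uniform
within-cell variance (Δ²/12) is included. Without that term a likelihood
sharper than the node spacing reports a spuriously tiny SD; with it, the
±3-SD log-scale band covers the generating parameter in ≈99% of
study-scale recovery fits. Recovery checks use the log scale because the
grid is uniform there and the marginals are roughly symmetric there.

The Rescorla–Wagner model adds two learning rates and is fitted by
profiling: an equispaced 10×10 grid over (α_reward, α_social) ∈ [0.05,
0.95], with the inner 3-D (γ, γ, β) grid at 20 points per dimension refitted
for each pair. BIC (`k·ln n − 2·LL`) and AIC (`2k − 2·LL`) use each model's
best grid-node log-likelihood, k = 3 vs 5, and n = number of choice trials.
The coarser inner grid trades ≲1–2 LL units of refinement for tractability,
small against the BIC penalty difference 2·ln 290 ≈ 11.3.

Predictive accuracy is the fraction of trials on which the fitted policy's
preferred option (probability > 0.5) matches the observed choice; exact ties
count one half.

## Synthetic cohorts

`generate_cohort` is the ground-truth generator for every downstream
validation. Eight trait scores per subject emulate the PPI subscales
(Stress Immunity, Social Potency, Fearlessness, Machiavellian Egocentricity,
Blame Externalization, Carefree Non-planfulness, Impulsive Non-conformity,
Coldheartedness) as a multivariate normal with subscale means/SDs typical of
a community sample of young adults (e.g. Stress Immunity 28.9 ± 5.4) and
zero inter-trait correlation by default (a correlated preset stresses the
selection stage). Log-parameters are linear in the z-scored traits:
log γ_reward history loads negatively on Stress Immunity and Fearlessness,
log γ_social on Stress Immunity and Social Potency, each at coefficient
−0.35 × 0.5 with residual SD 0.5·√(1 − 2·0.35²), giving trait–parameter
correlations near −0.35 — the realistic low-signal regime for an n = 36
association study. Medians are γ_reward ≈ 1.1, γ_social ≈ 2.2, β ≈ 0.5
(log-normal, β trait-independent), resembling typical fitted magnitudes.
Traits reach behaviour only through this map, so conditional on an agent's
parameters its choices are independent of its traits.

What the generator does **not** emulate: item-level Likert structure of the
questionnaire, oversampled/non-normal trait distributions, lapses,
perseveration, side biases, or any departure of human choices from the
fitted policy family. Passing recovery tests therefore demonstrates that the
estimation and selection machinery works when the model is true at study
scale — not that the model is true of people. Consistent with that, mean
predictive accuracy on synthetic cohorts (≈95%) exceeds what is attainable
on human data.

## Trait association

All variables are optimally scaled at numeric level: z-scored and multiplied
by 10. The z-transform uses the population-SD (n) convention, configurable
to n−1; the choice is immaterial to selection because both conventions
rescale every column by the same factor. The lasso path is parameterised by
the standardised sum of coefficients — the L1 norm as a fraction of the
unconstrained least-squares solution's norm — on the 51-point grid 0.0 to
1.0 in steps of 0.02. Coefficients are exact: the lasso solution is
piecewise linear in its L1 norm, so the path is computed once by least-angle
regression and interpolated between knots (endpoint verified against the
closed-form OLS solution).

The optimal shrinkage level minimises the .632-bootstrap expected prediction
error with squared loss and 100 resamples: 0.368 × apparent error + 0.632 ×
out-of-bag error, the latter pooled over all out-of-bag predictions;
resamples with no out-of-bag subjects or a constant response are redrawn and
counted. Ties go to the smaller (more parsimonious) level. Pearson
correlations between selected traits and the parameter are tested by
percentile bootstrap (default 10,000 paired resamples, 95% interval);
a correlation is significant iff both CI bounds share a sign.

KS normality checks estimate the reference normal's mean and SD from the
sample. The default p-value uses the Lilliefors correction (the plug-in
asymptotic p is badly conservative in this situation — near 1.0 for true
normals and rarely below 0.01 even for uniform samples of n = 500);
`method='asymptotic'` and a parametric-bootstrap `method='bootstrap'` are
available.

## Problem sizes and reproducibility

The validation experiments run at deliberate scales: equation-fidelity
oracles at 1,000 random inputs; filter equivalence on 100-trial sequences
with an 8×7×6 grid (the explicit joint matrix is dense); parameter recovery
with 40 agents × 290 trials at the default grids; model comparison on a
36-agent cohort; association recovery over 20 trait-linked and 20 null
cohorts of 36 subjects each, using a 20×15×12 tracker grid and a 30-point
fit grid for the per-subject fits inside the replicate loop; bootstrap-CI
coverage over 200 runs of 2,000 resamples. Every stochastic stage takes an
explicit seed, the pipeline records a config hash and per-file checksums in
its manifest, and identical configs reproduce identical outputs.

## Known limitations

* The true session structure (block lengths, probability levels) of the
  original task is unknown; defaults are a plausible stand-in.
* The tracker's kernel family and grid bounds are fixed choices "after" the
  volatility-learning literature, not fitted; subjects' learning processes
  are assumed identical across people.
* The .632 estimator uses plain (not .632+) weighting, and the optimal
  scaling is the numeric-level z×10 transform, not a full
  alternating-least-squares quantification.
* Grid fitting bounds parameters to [0.01, 10]; agents generated outside
  that range are estimated at the boundary.
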