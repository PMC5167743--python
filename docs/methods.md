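# Methods

`dualcontrol` implements the computational machinery for cross-validating
two behavioral assays of the balance between goal-directed (model-based,
MB) and habitual (model-free, MF) instrumental control: a two-step Markov
decision task analyzed with a hybrid reinforcement-learning model, and the
three-phase slips-of-action paradigm summarized by a devaluation
sensitivity index (DSI). Because no subject-level data are available for
this design, the package centers on synthetic cohorts with known ground
truth: every statistic the pipeline produces can be checked against the
generative parameters that produced the data.

## Two-step task environment

One first-stage state offers two actions; action *a* leads to second-stage
state *a* with probability `p_common = 0.7` and to the other state with
probability 0.3. Each second-stage state offers two actions whose binary
reward probabilities follow independent Gaussian random walks (per-trial
increment sd 0.025, reflected once at [0.25, 0.75], initialized uniformly
within bounds). These walk parameters are the conventional ones for this
task family; the design source states only that the walks are slow and
Gaussian, so they are exposed in `TwoStepConfig` and default to the
convention. A session has 201 scored trials; 55 practice trials can be
generated by the same machinery (flagged, excluded from fitting, with
walks independent of the main task — the protocol does not say whether
the practice walks continue, and independent walks are the conservative
reading). Simulated sessions contain no invalid trials; the `valid` flag
exists so imported human data with response-window omissions can be
represented and skipped consistently.

## Hybrid MB/MF learner

MF values are learned by SARSA(λ). With stages i ∈ {1,2}, prediction
errors δ₁ = Q_MF(s₂,a₂) − Q_MF(s₁,a₁) (no first-stage reward) and
δ₂ = r − Q_MF(s₂,a₂) update the chosen values by α_i δ_i, and δ₂
additionally back-propagates to the chosen first-stage value with weight
λ (increment α₁λδ₂). δ₁ uses the pre-update second-stage value; within a
trial the three increments are then applied together. This order matches
the SARSA(λ) convention of the task's source literature; the update
equations alone do not pin it down. Values start at zero; unchosen values
are never touched (no forgetting).

MB first-stage values are recomputed each trial from the current
second-stage MF values and the *instructed* transition matrix:
Q_MB(a) = P(B|a)·max Q_MF(B,·) + P(C|a)·max Q_MF(C,·). No transition
learning is modeled — participants in this protocol are trained on the
structure beforehand.

First-stage decision values mix the systems, Q = ωQ_MB + (1−ω)Q_MF, and
choices follow a softmax with inverse temperature β₁ plus a perseveration
bonus ρ for repeating the previous first-stage choice. Perseveration
applies at stage 1 only; second-stage choices are a softmax with β₂ over
the raw second-stage MF values. The MB and MF contributions to choice
stochasticity are summarized as β_MB = ωβ₁ and β_MF = (1−ω)β₁. The
softmax uses max subtraction; large β × value products cannot overflow.

Seven free parameters: α₁, α₂, λ, ω ∈ (0,1); β₁, β₂ > 0; ρ unbounded.
For fitting they are mapped to an unconstrained scale — log-odds for the
unit-interval parameters, log for the temperatures, identity for ρ.

### Likelihood implementation

The MF/MB value trajectories depend only on (α₁, α₂, λ) and the observed
choices, never on the softmax parameters, so one sequential pass per
learning-rate setting serves every (ω, β₁, β₂, ρ) query. `Session`
caches these trajectories; finite-difference optimization and grid
searches hit the cache on roughly half their evaluations, and 2-parameter
grids on almost all. The vectorized likelihood is verified to 1e-10
against an independent scalar trace in the test suite.

## Hierarchical empirical-Bayes fitting

Subjects share a diagonal Gaussian prior on the transformed scale.
Fitting is MAP-EM:

- **Initialization** — the prior mean is the pooled maximum-likelihood
  estimate (all subjects concatenated as one likelihood, values reset per
  subject); the variance starts at a broad 6.25 per dimension (sd 2.5 on
  logit/log scales spans effectively the whole plausible range).
- **E-step** — per-subject MAP by L-BFGS-B on the penalized objective,
  with 5 starts (prior mean + seeded jitter) on cold fits and 2 (previous
  MAP + prior mean) on warm ones; box bounds at ±12 (logit, ρ) and ±6
  (log) only bite in likelihood-flat directions. Diagonal Laplace
  curvature at the optimum provides the posterior uncertainty;
  non-positive curvature (flat likelihood) is replaced by the prior
  precision.
- **M-step** — moment matching: the prior mean becomes the mean of the
  MAPs; the variance becomes mean(MAP² + Laplace variance) − mean², so a
  parameter estimated noisily in every subject keeps a wide prior.
  Variance updating can be disabled (`update_variance=False`) to hold the
  initial variance fixed.
- **Convergence** — max absolute change in the prior mean < 1e-3
  (configurable), cap 100 iterations. The recorded trajectory is the
  Laplace approximation to the group log marginal likelihood — the
  quantity this EM ascends — and is checked to be non-decreasing.

Reported per-subject −LL is the pure data likelihood at the MAP, without
the prior term, matching the usual reporting convention. `subject_map`
accepts a `free_mask` to pin parameters at the prior mean, which the test
suite uses to compare the optimizer against a dense grid on a 2-parameter
reduction.

At the default study conditions (28 subjects × 201 trials, group spread
of ω at its published anchor, sd 0.07), the group mean of ω is recovered
within ±0.02 typically and ±0.10 across seeds, and all-MF (ω=0) versus
all-MB (ω=1) cohorts separate cleanly (< 0.2 vs > 0.8). Per-subject ω
*ranking* is only moderately recoverable in this regime (rank
correlation with truth ≈ 0.55 on average, ranging 0.4–0.7 across
seeds): 201 trials cannot sharply discriminate individuals whose true ω
differ by a few hundredths. This is a property of the design, not
the fitter, and it is why cross-task correlations of fitted quantities
are attenuated relative to their generative counterparts.

## Slips-of-action paradigm

Six stimuli map deterministically onto six unique outcomes, three per
response side. Schedules reproduce the published design exactly: training
8 blocks × 12 (each stimulus twice per block, 16 total); outcome
devaluation 36 trials — all 9 left×right outcome pairs, 4 repeats,
devaluation side counterbalanced 2/2 (the source states only the pairing
rule and the total, so this balanced composition is the package's
choice); slips and baseline 9 blocks × 12 with two devalued items per
block (one per response side — side balance prevents a response-side
confound), each item devalued in exactly 3 blocks (36 devalued / 72
valued trials), and no stimulus ever repeated back-to-back (rejection
sampling, including across block boundaries).

The synthetic responder is deliberately minimal — no trial-level value
computation, since the paradigm's published analyses fit no generative
model. Training accuracy rises per stimulus as
p_k = (1−eps) − (0.5−eps)·exp(−a_learn·k); in the go/no-go tests the
agent responds on valued trials with probability `r_base` and slips on
devalued trials with probability `r_base·(1−g)` (slips phase) or
`r_base·(1−g_base)` (baseline). Defaults g = 0.8, r_base = 0.85,
a_learn = 0.3, eps = 0.02, g_base = 0.92 place the simulated summary
statistics in the healthy-adult regime reported for this task (≈85%
responding to valued, ≈15–20% slips, DSI in the mid-60s, near-ceiling
baseline inhibition, final-block training accuracy ≈98%). Expected DSI
is 100·r_base·g, which the simulation check reproduces.

DSI is computed per trial type — responses on valued trials over the 72
valued trials, minus responses on devalued trials over the 36 devalued
trials — matching the component percentages this literature reports. The
literal formula variant normalizing both counts by total responses is
available as `dsi_mode="total"`.

## Statistics

- **Stay probabilities**: trial t is classified by the previous valid
  trial's (reward, transition); the 2×2 repeated-measures ANOVA is
  computed through within-subject contrasts (F = t², df (1, n−1)), which
  is algebraically the textbook sums-of-squares analysis and is verified
  against an independent oracle and against `pingouin`.
- **Friedman** across training blocks uses midranks with the standard tie
  correction; the fully tied case returns χ² = 0 rather than erroring
  (scipy's implementation divides by zero there, hence the hand-computed
  statistic).
- **Wilcoxon signed-rank** reports a signed Z (direction of x − y) with
  tie-corrected normal approximation; zero differences are dropped.
- **Above-chance binomial**: the published test's construction is
  ambiguous between per-subject trial counts and a cohort count of
  above-chance subjects, so both are provided; the pipeline uses the
  cohort reading (count of subjects above 50% correct, exact upper-tail
  binomial at p₀ = 0.5).
- **Cross-task correlations**: midrank Spearman with one-tailed p from
  the t approximation, fixed positive direction for the three focal tests
  (β_MB, β_MF, ω vs DSI), Bonferroni m = 3. DSI outliers (|z| ≥ 2) are
  excluded first.
- **Mediation** (X = β_MB, M = VPA-like covariate, Y = DSI): OLS paths,
  indirect effect a·b, bias-corrected (non-accelerated) percentile
  bootstrap over case resamples (default 5000; the bootstrap uses
  closed-form bivariate OLS vectorized over resamples), Sobel
  Z = ab/√(b²SE_a² + a²SE_b²), and κ² — the indirect effect relative to
  its maximum, with each path bounded by positive semi-definiteness of
  the (X, M, Y) correlation matrix holding the other two observed
  correlations fixed. The BC interval attains ≈95% coverage at n = 200
  in the suite's 500-replication check.

## Synthetic cohorts

A single standard-normal latent trait G per subject drives the
transformed MB weight ω (loading 0.7), the slips goal-directedness g on
the log-odds scale (loading 0.7), and VPA/WMT/DSST-like covariates
(loadings 0.65/0.45/0.35, clipped to instrument ranges). Loadings are
fractions of each variable's marginal sd, so coupling strength and
marginal distributions are independent knobs; the defaults put the true
ω–g correlation near 0.45–0.5, the moderate-association regime.

G additionally loads on β₁ (0.5). This is a deliberate extension of the
minimal one-factor structure: the measured MB construct is β_MB = ωβ₁,
and with ω's marginal spread anchored to its published value (sd 0.07),
a trait expressed through the balance alone leaves β_MB essentially
uncorrelated with anything (≈0.07) because β₁'s independent variance
dominates the product. Letting the trait also modulate choice
decisiveness yields a true β_MB–DSI correlation near 0.3 and a fitted
one near 0.15–0.35 depending on n — the regime the paradigm comparison
operates in. Set `loading_beta1=0` to recover the strict one-factor
generator.

Group parameter marginals are anchored to the published estimates
(ω 0.68 ± 0.07, β₂ 4.18 ± 1.59, α₁ 0.50 ± 0.15, α₂ 0.52 ± 0.25,
λ 0.52 ± 0.24, ρ 0.13 ± 0.03; β₁ = β_MB + β_MF = 7.67 ± 2.0) and
converted to transformed-scale Gaussians by the delta method, which
preserves the natural-scale mean and sd to first order (verified by
simulation in the suite).

What the generator does *not* emulate: reaction times, within-session
non-stationarity of strategy, lapses or attention drifts in the two-step
task, learning during the slips test phases, and demographic covariates.
Passing tests therefore validate the estimators and the pipeline logic
under the stated generative assumptions, not robustness to the full
messiness of human data.

## Problem sizes and numerical choices

The validation suite runs the fitting oracle on 20 sessions against a
200×200 grid, cohort recovery and separability at 28 subjects × 201
trials with default EM settings, bootstrap coverage over 500 replications
at n = 200, and the end-to-end coupled-cohort check at n = 300 with the
large-cohort fit preset (2 starts, EM tolerance 1e-2, 5 iterations) —
with 300 subjects the group prior is constrained tightly enough that
extra EM refinement changes group-level conclusions only in the third
decimal. The acceptance script reproduces the full 28-subject study at
default settings.

Degenerate inputs are handled explicitly: empty sessions score zero
likelihood and are rejected by the fitter; constant vectors are rejected
by the correlation and outlier routines (zero variance → no outliers);
all-zero paired differences make the signed-rank test error rather than
fabricate a Z; collinear mediator/predictor designs are rejected. Ties
use midranks throughout.

## Known limitations

- Per-subject (as opposed to group-level) ω estimates are shrunk and
  noisy at 201 trials; individual-difference correlations built on them
  are attenuated by roughly half in the default regime.
- The diagonal prior ignores parameter correlations (e.g., ω with β₁);
  a full-covariance prior is out of scope.
- The slips responder has no trial-by-trial dynamics; it cannot express
  within-phase fatigue or learning-during-test effects.
- κ² inherits the known non-monotonicity criticisms of its published
  definition; it is reported for comparability, with the bootstrap CI as
  the primary inferential quantity.
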