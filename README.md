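# dualcontrol

Simulation, hierarchical model fitting, and cross-task statistics for the
balance between **goal-directed (model-based)** and **habitual
(model-free)** instrumental control.

Two laboratory assays dominate this literature: the **two-step Markov
decision task**, where a hybrid reinforcement-learning model decomposes
choice behavior into model-based (MB) and model-free (MF) contributions,
and the **slips-of-action paradigm**, where responding to stimuli whose
outcomes were just devalued ("slips") indexes habitual control and the
**devaluation sensitivity index** (DSI) summarizes the balance. Whether
the two tasks measure the same construct is an empirical question that
requires running both in one sample and correlating their parameters —
and validating that entire pipeline requires synthetic cohorts where the
ground truth is known. `dualcontrol` provides all of it:

- a two-step task simulator (70/30 transitions, bounded Gaussian
  random-walk rewards) and a hybrid SARSA(λ)/MB learner,
  Q = ωQ_MB + (1−ω)Q_MF, with softmax choice
  p(a) ∝ exp(β_i[Q(a) + ρ·rep(a)]) and the decomposition
  β_MB = ωβ₁, β_MF = (1−ω)β₁;
- hierarchical **empirical-Bayes fitting**: per-subject MAP estimates on
  a transformed (logit/log) scale under a group Gaussian prior, updated
  by Expectation–Maximization with Laplace uncertainties;
- the complete **slips-of-action paradigm**: discrimination training,
  outcome-devaluation test, slips test, baseline test — schedule
  generators reproducing every design constant, a minimal synthetic
  go/no-go responder with a goal-directedness trait g, and scoring
  including DSI = %responses(valued) − %responses(devalued);
- behavioral statistics (stay-probability 2×2 repeated-measures ANOVA,
  Friedman, signed-rank, exact binomial) and cross-task statistics
  (outlier screen, one-tailed Spearman with Bonferroni correction, and
  PROCESS-style simple mediation with bias-corrected bootstrap CI, Sobel
  test, and κ² effect size);
- a **synthetic-cohort generator** in which a single latent
  goal-directedness trait couples the MB weight, the slips trait g, and
  cognitive covariates, so the full pipeline
  (simulate → fit → score → correlate → mediate) runs end-to-end against
  known ground truth.

## Worked example

Run the whole study pipeline on a default 28-subject synthetic cohort:

```python
from dualcontrol import CohortSpec, run_study
from dualcontrol.emfit import FitOptions

out = run_study(CohortSpec(n_subjects=28, seed=42),
                fit_options=FitOptions(seed=42), n_boot=2000)
rep = out["report"]
print(f"recovered group-mean omega: {rep['em']['group_mean_natural']['omega']:.3f}")
print(f"stay reward x state interaction F: "
      f"{rep['stay_anova'][2]['F']:.1f}")
print(f"mean DSI: {rep['slips_summary']['mean_dsi']:.1f}")
print(f"beta_MB - DSI Spearman rho: "
      f"{rep['focal_correlations']['beta_mb_vs_dsi']['rho']:.3f}")
```

which prints:

```
recovered group-mean omega: 0.666
stay reward x state interaction F: 81.4
mean DSI: 64.4
beta_MB - DSI Spearman rho: 0.172
```

Reading these numbers: the cohort was generated with a group-mean MB
weight of 0.68 and EM recovers it to within 0.02; the large
stay-probability reward × state interaction at n = 28 is the signature
of strongly model-based choice; the mean DSI in the mid-60s with a
positive β_MB–DSI rank correlation reproduces the moderate cross-task
association that the generator's latent trait induces (attenuated, as
expected, relative to the true parameter-level coupling — see
`docs/methods.md`). The same pipeline is available from the shell:

```bash
dualcontrol run-study --seed 42 --n-subjects 28 --out report.json
dualcontrol simulate-twostep --seed 1 --n-subjects 28 --out trials.csv
dualcontrol fit-twostep --seed 1 --trials trials.csv --out fits.csv
dualcontrol simulate-slips --seed 2 --n-subjects 28 --out records.csv
dualcontrol score-slips --records records.csv --out scores.csv
```

Every command writes a `*.config.json` provenance sidecar so each output
is regenerable from its configuration and seed.

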