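"""Synthetic cohorts with a latent goal-directedness trait.

A single standard-normal latent factor G per subject drives

* the transformed MB weight ω of the two-step hybrid agent, and (more
  weakly) its first-stage choice decisiveness β₁ — the measured MB
  construct is β_MB = ω·β₁, and at the published marginal spread of ω a
  trait expressed through the balance alone barely registers in β_MB,
* the goal-directedness g of the slips-of-action responder (on the
  log-odds scale), and
* three cognitive covariates (VPA-, WMT-, DSST-like) with decreasing
  loadings,

so the generated data reproduce, with known ground truth, the qualitative
structure of interest: a positive cross-task association between
model-based control and devaluation sensitivity, partially mediated by a
shared cognitive factor. Loadings are expressed as correlation-scale
fractions of each variable's total sd; a loading of 0 decouples the
variable from G while leaving its marginal distribution unchanged.

Group parameter anchors are natural-scale means/sds converted to Gaussians
on the transformed (logit/log) fitting scale by the delta method
(μ_t = f(μ), σ_t = σ/|f⁻¹'(f(μ))|).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crossval, slips, stats
from .emfit import EMResult, FitOptions, em_fit, fits_to_frame
from .hybrid import PARAM_NAMES, AgentParams, from_transformed
from .slips import SlipsAgentParams, SROMap
from .twostep import Session, TwoStepConfig, trials_to_frame
from .hybrid import simulate_agent

__all__ = ["CohortSpec", "CohortTruth", "CovariateSpec", "generate_cohort", "run_study"]


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


#: natural-scale group anchors (mean, sd) for the hybrid-agent parameters;
#: beta1 is the sum of the MB and MF inverse-temperature anchors
GROUP_ANCHORS_NATURAL: dict[str, tuple[float, float]] = {
    "alpha1": (0.50, 0.15),
    "alpha2": (0.52, 0.25),
    "lam": (0.52, 0.24),
    "omega": (0.68, 0.07),
    "beta1": (7.67, 2.0),
    "beta2": (4.18, 1.59),
    "rho": (0.13, 0.03),
}


def natural_to_transformed_moments(name: str, mean: float, sd: float) -> tuple[float, float]:
    """Delta-method conversion of a natural (mean, sd) anchor to the
    transformed scale used for sampling and fitting."""
    if name in ("alpha1", "alpha2", "lam", "omega"):
        return _logit(mean), sd / (mean * (1 - mean))
    if name in ("beta1", "beta2"):
        return float(np.log(mean)), sd / mean
    return mean, sd  # rho: identity scale


@dataclass(frozen=True)
class CovariateSpec:
    """One cognitive covariate: instrument mean/sd, range clip, G loading."""

    mean: float
    sd: float
    low: float
    high: float
    loading: float  # fraction of sd carried by the latent factor, in [0, 1)


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a synthetic cohort.

    Latent loadings are fractions in [0, 1): ``loading_omega`` and
    ``loading_g`` default to 0.7 each, putting the latent correlation
    between transformed ω and the slips goal-directedness near 0.5 —
    the regime of a moderate cross-task association. ``loading_beta1``
    (default 0.5) lets the trait also express in first-stage choice
    decisiveness so that β_MB = ω·β₁ carries it at observable strength.
    Covariate anchors follow the VAT/WMT/DSST instruments (means 12.11,
    18.96, 87.05).
    """

    n_subjects: int = 28
    seed: int = 0
    task: TwoStepConfig = field(default_factory=TwoStepConfig)
    group_means: dict = field(default_factory=lambda: {
        k: v[0] for k, v in GROUP_ANCHORS_NATURAL.items()
    })
    group_sds: dict = field(default_factory=lambda: {
        k: v[1] for k, v in GROUP_ANCHORS_NATURAL.items()
    })
    loading_omega: float = 0.7
    loading_beta1: float = 0.5
    loading_g: float = 0.7
    slips_agent: SlipsAgentParams = field(default_factory=SlipsAgentParams)
    slips_g_sd: float = 0.8  # sd of g on the log-odds scale
    covariates: dict = field(default_factory=lambda: {
        "vpa": CovariateSpec(12.11, 3.89, 3, 18, 0.65),
        "wmt": CovariateSpec(18.96, 3.85, 0, 24, 0.45),
        "dsst": CovariateSpec(87.05, 10.74, 40, 135, 0.35),
    })

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("loading_omega", "loading_beta1", "loading_g"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")

    def transformed_moments(self) -> dict[str, tuple[float, float]]:
        return {
            n: natural_to_transformed_moments(n, self.group_means[n], self.group_sds[n])
            for n in PARAM_NAMES
        }


@dataclass
class CohortTruth:
    """Ground truth stored alongside generated data."""

    latent_g: np.ndarray
    agent_params: list[AgentParams]
    slips_params: list[SlipsAgentParams]
    covariates: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (ap, sp) in enumerate(zip(self.agent_params, self.slips_params)):
            row = {"subject_id": i, "latent_g": float(self.latent_g[i])}
            row.update({f"true_{k}": v for k, v in dataclasses.asdict(ap).items()})
            row["true_beta_mb"] = ap.beta_mb
            row["true_beta_mf"] = ap.beta_mf
            row.update({f"true_slips_{k}": v for k, v in dataclasses.asdict(sp).items()})
            rows.append(row)
        return pd.DataFrame(rows).merge(self.covariates, on="subject_id")


def _loaded_normal(mu: float, sd: float, loading: float, G: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """mu + loading·sd·G + residual noise, keeping total sd at ``sd``."""
    lam = loading * sd
    resid = float(np.sqrt(max(sd * sd - lam * lam, 0.0)))
    return mu + lam * G + rng.normal(0.0, resid, size=len(G))


def generate_cohort(spec: CohortSpec, with_data: bool = True):
    """Generate truth, two-step sessions, and all four slips phases.

    Returns ``(truth, twostep_frame, slips_frame)`` where the frames hold
    every subject's trial records in the tidy CSV schemas. Fully
    reproducible from ``spec.seed``. ``with_data=False`` returns
    ``(truth, None, None)`` — the latent draws only, cheap enough for
    Monte-Carlo studies of the coupling structure.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    G = rng.standard_normal(n)
    tm = spec.transformed_moments()

    draws = {}
    loadings = {"omega": spec.loading_omega, "beta1": spec.loading_beta1}
    for name in PARAM_NAMES:
        mu, sd = tm[name]
        draws[name] = _loaded_normal(mu, sd, loadings.get(name, 0.0), G, rng)

    agent_params = [
        from_transformed(np.array([draws[nme][i] for nme in PARAM_NAMES]))
        for i in range(n)
    ]

    base = spec.slips_agent
    g_latent = _loaded_normal(_logit(base.g), spec.slips_g_sd, spec.loading_g, G, rng)
    slips_params = [
        dataclasses.replace(base, g=float(1.0 / (1.0 + np.exp(-gl))))
        for gl in g_latent
    ]

    cov_rows = {"subject_id": np.arange(n)}
    for cname, cv in spec.covariates.items():
        vals = _loaded_normal(cv.mean, cv.sd, cv.loading, G, rng)
        cov_rows[cname] = np.clip(vals, cv.low, cv.high)
    covariates = pd.DataFrame(cov_rows)

    truth = CohortTruth(
        latent_g=G, agent_params=agent_params,
        slips_params=slips_params, covariates=covariates,
    )
    if not with_data:
        return truth, None, None

    ts_frames = []
    slips_frames = []
    for i in range(n):
        ts_seed = int(rng.integers(2**31))
        trials = simulate_agent(agent_params[i], spec.task, seed=ts_seed)
        ts_frames.append(trials_to_frame(trials, subject_id=i))

        sro = SROMap.default(seed=int(rng.integers(2**31)))
        records = []
        for phase in slips.PHASES:
            sched = slips.build_schedule(phase, sro, seed=int(rng.integers(2**31)))
            sim_seed = int(rng.integers(2**31))
            if phase == "training":
                df = slips.simulate_training(slips_params[i], sched, sro, sim_seed)
            elif phase == "outcome_devaluation":
                df = slips.simulate_devaluation_test(slips_params[i], sched, sro, sim_seed)
            else:
                df = slips.simulate_test_phase(slips_params[i], sched, sro, sim_seed)
            records.append(df)
        rec = pd.concat(records, ignore_index=True)
        rec.insert(0, "subject_id", i)
        slips_frames.append(rec)

    return truth, pd.concat(ts_frames, ignore_index=True), pd.concat(
        slips_frames, ignore_index=True
    )


def phase_scores_frame(slips_df: pd.DataFrame, dsi_mode: str) -> pd.DataFrame:
    rows = []
    for sid, sub in slips_df.groupby("subject_id"):
        row = {"subject_id": sid}
        for phase in slips.PHASES:
            sc = slips.score_phase(sub, phase, dsi_mode=dsi_mode)
            if phase == "training":
                row["training_pct_correct"] = sc.pct_correct
                for b, v in enumerate(sc.block_pct_correct):
                    row[f"training_block{b + 1}"] = v
            elif phase == "outcome_devaluation":
                row["devaluation_pct_correct"] = sc.pct_correct
            else:
                row[f"{phase}_pct_valued"] = sc.pct_responses_valued
                row[f"{phase}_pct_devalued"] = sc.pct_responses_devalued
                row[f"{phase}_dsi"] = sc.dsi
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    spec: CohortSpec,
    fit_options: FitOptions | None = None,
    n_boot: int = 2000,
    dsi_mode: str = "per_trial_type",
    outlier_z: float = 2.0,
) -> dict:
    """Run the full pipeline on a synthetic cohort.

    Generates the cohort, fits the hybrid model by empirical-Bayes EM,
    scores all slips phases, computes stay-probability ANOVA, Friedman and
    Wilcoxon tests, screens DSI outliers, runs the three focal one-tailed
    Spearman correlations (β_MB–DSI, β_MF–DSI, ω–DSI; Bonferroni m=3),
    covariate correlations, and the β_MB → VPA → DSI mediation. Returns a
    JSON-serializable report with ground truth attached.
    """
    truth, ts_df, slips_df = generate_cohort(spec)
    opts = fit_options or FitOptions(seed=spec.seed)

    sessions = [
        Session(
            a1=sub["a1"].to_numpy(), s2=(sub["state2"] == "C").to_numpy().astype(int),
            a2=sub["a2"].to_numpy(), r=sub["r"].to_numpy(),
            valid=sub["valid"].to_numpy().astype(bool),
        )
        for _, sub in ts_df.groupby("subject_id")
    ]
    em: EMResult = em_fit(sessions, spec.task, options=opts)
    fits = fits_to_frame(em.fits)

    scores = phase_scores_frame(slips_df, dsi_mode)
    merged = fits.merge(scores, on="subject_id").merge(
        truth.covariates, on="subject_id"
    )

    tables = [stats.stay_probability_table(s) for s in sessions]
    anova = stats.rm_anova_2x2(tables)

    block_cols = [f"training_block{b + 1}" for b in range(slips.TRAINING_BLOCKS)]
    chi2, fried_p = stats.friedman(scores[block_cols].to_numpy())
    k_above, binom_p = stats.cohort_above_chance(
        scores["devaluation_pct_correct"].to_numpy()
    )
    wz, wp = stats.wilcoxon_signed_rank(
        scores["slips_dsi"].to_numpy(), scores["baseline_dsi"].to_numpy()
    )

    mask = crossval.flag_outliers(merged["slips_dsi"].to_numpy(), threshold=outlier_z)
    kept = merged.loc[~mask]
    if len(kept) < 4:
        raise ValueError("too few subjects after outlier exclusion for correlations")

    focal = {}
    for var in ("beta_mb", "beta_mf", "omega"):
        res = crossval.spearman_one_tailed(
            kept[var].to_numpy(), kept["slips_dsi"].to_numpy(),
            direction="positive", m_tests=3,
        )
        focal[f"{var}_vs_dsi"] = dataclasses.asdict(res)

    covariate_corr = {}
    for var in ("omega", "beta_mb", "beta_mf", "slips_dsi"):
        for cov in spec.covariates:
            res = crossval.spearman_one_tailed(
                kept[var].to_numpy(), kept[cov].to_numpy(), direction="positive"
            )
            covariate_corr[f"{var}_vs_{cov}"] = dataclasses.asdict(res)

    med = crossval.mediate(
        kept["beta_mb"].to_numpy(), kept["vpa"].to_numpy(),
        kept["slips_dsi"].to_numpy(), n_boot=n_boot, seed=spec.seed,
    )

    report = {
        "spec": {
            "n_subjects": spec.n_subjects, "seed": spec.seed,
            "loading_omega": spec.loading_omega, "loading_beta1": spec.loading_beta1,
            "loading_g": spec.loading_g,
        },
        "em": {
            "n_iterations": em.n_iterations,
            "converged": em.converged,
            "prior_mean": dict(zip(PARAM_NAMES, map(float, em.prior.mean))),
            "prior_variance": dict(zip(PARAM_NAMES, map(float, em.prior.variance))),
            "group_mean_natural": {
                n: float(fits[n].mean()) for n in PARAM_NAMES
            },
            "group_mean_beta_mb": float(fits["beta_mb"].mean()),
            "group_mean_beta_mf": float(fits["beta_mf"].mean()),
            "mean_nll": float(fits["nll"].mean()),
        },
        "stay_anova": anova.to_dict(orient="records"),
        "training_friedman": {"chi2": chi2, "p": fried_p},
        "devaluation_above_chance": {"k": k_above, "n": spec.n_subjects, "p": binom_p},
        "baseline_vs_slips_wilcoxon": {"z": wz, "p": wp},
        "slips_summary": {
            "mean_dsi": float(scores["slips_dsi"].mean()),
            "mean_pct_valued": float(scores["slips_pct_valued"].mean()),
            "mean_pct_devalued": float(scores["slips_pct_devalued"].mean()),
            "mean_baseline_diff": float(scores["baseline_dsi"].mean()),
        },
        "outliers_excluded": int(mask.sum()),
        "focal_correlations": focal,
        "covariate_correlations": covariate_corr,
        "mediation_bmb_vpa_dsi": dataclasses.asdict(med),
        "truth_summary": {
            "mean_true_omega": float(np.mean([p.omega for p in truth.agent_params])),
            "mean_true_g": float(np.mean([p.g for p in truth.slips_params])),
            "true_omega_g_spearman": float(
                crossval.spearman_one_tailed(
                    [p.omega for p in truth.agent_params],
                    [p.g for p in truth.slips_params],
                ).rho
            ),
        },
    }
    return {
        "report": report,
        "truth": truth,
        "fits": merged,
        "scores": scores,
        "twostep": ts_df,
        "slips": slips_df,
        "em": em,
    }
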