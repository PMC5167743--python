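"""Hierarchical empirical-Bayes fitting of the hybrid model.

Subjects share a diagonal Gaussian prior over the transformed (logit/log)
parameters. Fitting alternates:

E-step
    per-subject maximum-a-posteriori (MAP) estimates of the transformed
    parameters under the current prior, with diagonal Laplace curvatures
    as local posterior uncertainties;
M-step
    moment-matching update of the prior — the mean becomes the mean of
    the MAP estimates; the variance becomes the mean of (MAP² + Laplace
    variance) minus the squared mean, so shrinkage reflects both spread
    and per-subject uncertainty.

The prior mean is initialized at the pooled maximum-likelihood estimate
(all subjects concatenated into one likelihood, values reset per subject)
with a broad default variance. Iterations stop when the largest change in
the prior mean drops below ``tol``.

The per-iteration ``trajectory`` records the Laplace approximation to the
group log marginal likelihood, the quantity EM ascends:
``Σ_subjects [ −NLL(MAP) + log N(MAP; prior) + ½ Σ_d log(2πe·var_d) ]``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .hybrid import PARAM_NAMES, AgentParams, from_transformed, session_nll, split_betas, to_transformed, transformed_nat
from .twostep import Session, TwoStepConfig

__all__ = [
    "GroupPrior",
    "FitOptions",
    "SubjectFit",
    "EMResult",
    "subject_map",
    "init_prior",
    "em_fit",
    "fits_to_frame",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: broad default prior variance per transformed dimension
DEFAULT_PRIOR_VARIANCE = 6.25

#: generic natural-scale starting point for pooled ML
_DEFAULT_START_NAT = AgentParams(
    alpha1=0.5, alpha2=0.5, lam=0.5, omega=0.5, beta1=3.0, beta2=3.0, rho=0.1
)

#: box bounds on the transformed scale; they only bite in likelihood-flat
#: directions (|logit| 12 is within 6e-6 of the unit-interval boundary)
_BOUNDS = [(-12.0, 12.0)] * 4 + [(-6.0, 6.0)] * 2 + [(-12.0, 12.0)]


@dataclass(frozen=True)
class GroupPrior:
    """Diagonal Gaussian prior over transformed parameters."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "variance", np.asarray(self.variance, dtype=float))
        if self.mean.shape != (len(PARAM_NAMES),) or self.variance.shape != self.mean.shape:
            raise ValueError("prior mean/variance must be 7-vectors")
        if not np.all(np.isfinite(self.variance)) or np.any(self.variance <= 0):
            raise ValueError("prior variances must be positive and finite")

    def logpdf(self, x: np.ndarray) -> float:
        z = (x - self.mean) ** 2 / self.variance
        return float(-0.5 * np.sum(z + np.log(self.variance) + _LOG2PI))

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": dict(zip(PARAM_NAMES, map(float, self.mean))),
                "variance": dict(zip(PARAM_NAMES, map(float, self.variance))),
                "scale": "transformed",
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "GroupPrior":
        d = json.loads(s)
        mean = np.array([d["mean"][n] for n in PARAM_NAMES])
        var = np.array([d["variance"][n] for n in PARAM_NAMES])
        return cls(mean, var)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer and EM controls.

    ``n_starts`` applies to cold E-steps (iteration 1 and :func:`subject_map`
    called directly); warm E-steps reuse the previous MAP plus the prior
    mean and ``n_starts_warm − 2`` jittered starts when positive.
    """

    n_starts: int = 5
    n_starts_warm: int = 2
    jitter_sd: float = 1.0
    maxiter: int = 400
    tol: float = 1e-3
    max_em_iter: int = 100
    update_variance: bool = True
    seed: int = 0


@dataclass(frozen=True)
class SubjectFit:
    """One subject's MAP fit.

    ``nll`` is the pure data negative log-likelihood at the MAP (the prior
    term is excluded, matching the usual −LL reporting convention);
    ``hessian_diag`` holds the diagonal curvature of the penalized
    objective at the optimum.
    """

    map_params: np.ndarray
    nat_params: AgentParams
    nll: float
    hessian_diag: np.ndarray
    converged: bool

    @property
    def laplace_variance(self) -> np.ndarray:
        return 1.0 / self.hessian_diag


@dataclass
class EMResult:
    prior: GroupPrior
    fits: list[SubjectFit]
    n_iterations: int
    trajectory: list[float]
    converged: bool = True


def _penalized(x: np.ndarray, session: Session, prior: GroupPrior,
               config: TwoStepConfig) -> float:
    """Negative log posterior (up to nothing — fully normalized)."""
    nat = transformed_nat(x)
    return session_nll(session, nat, config) - prior.logpdf(x)


def _curvature(fun, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central finite-difference diagonal Hessian."""
    f0 = fun(x)
    diag = np.empty_like(x)
    for i in range(len(x)):
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        diag[i] = (fun(xp) - 2.0 * f0 + fun(xm)) / (h * h)
    return diag


def subject_map(
    trials,
    prior: GroupPrior,
    config: TwoStepConfig,
    options: FitOptions | None = None,
    extra_starts: list[np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    free_mask: np.ndarray | None = None,
) -> SubjectFit:
    """MAP estimate of one subject's transformed parameters.

    Runs quasi-Newton (L-BFGS-B) optimization of the penalized objective
    from the prior mean plus seed-controlled jittered starts (and any
    ``extra_starts``, e.g. warm starts), keeping the best optimum. Laplace
    curvature is measured at the winner; non-positive curvature in a
    dimension is floored at the prior precision, which corresponds to a
    locally flat likelihood.

    ``free_mask`` selects a reduced model: parameters where it is False
    are clamped at the prior mean and only the remaining dimensions are
    optimized (their curvature entries report the prior precision).
    """
    opts = options or FitOptions()
    session = trials if isinstance(trials, Session) else Session.from_trials(trials)
    if session.n == 0:
        raise ValueError("cannot fit an empty session")
    if rng is None:
        rng = np.random.default_rng(opts.seed)
    if free_mask is None:
        free_mask = np.ones(len(PARAM_NAMES), dtype=bool)
    else:
        free_mask = np.asarray(free_mask, dtype=bool)

    starts = [prior.mean.copy()]
    if extra_starts:
        starts = list(extra_starts) + starts
        n_total = max(len(starts), opts.n_starts_warm)
    else:
        n_total = opts.n_starts
    sd = np.minimum(np.sqrt(prior.variance), opts.jitter_sd)
    while len(starts) < n_total:
        jit = prior.mean + rng.normal(0.0, sd, size=len(PARAM_NAMES))
        starts.append(jit)

    def embed(xfree: np.ndarray) -> np.ndarray:
        x = prior.mean.copy()
        x[free_mask] = xfree
        return x

    fun_full = lambda x: _penalized(x, session, prior, config)
    fun = lambda xfree: fun_full(embed(xfree))
    bounds = [b for b, f in zip(_BOUNDS, free_mask) if f]
    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            fun, np.clip(x0[free_mask], *zip(*bounds)), method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": 1e-10, "gtol": 1e-7},
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    x = embed(np.asarray(best.x, dtype=float))
    hess = np.full(len(PARAM_NAMES), np.nan)
    hess[free_mask] = _curvature(fun, x[free_mask])
    bad = ~np.isfinite(hess) | (hess <= 0)
    if np.any(bad):
        hess[bad] = 1.0 / prior.variance[bad]
    nat = from_transformed(x)
    return SubjectFit(
        map_params=x,
        nat_params=nat,
        nll=session_nll(session, nat, config),
        hessian_diag=hess,
        converged=any_ok,
    )


def init_prior(
    sessions: list,
    config: TwoStepConfig,
    options: FitOptions | None = None,
    variance: float = DEFAULT_PRIOR_VARIANCE,
) -> GroupPrior:
    """Pooled maximum-likelihood initialization of the group prior.

    All subjects' sessions are concatenated into one likelihood (values
    reset per subject) and maximized over a single transformed parameter
    vector; the prior variance is set to a broad default. If the optimizer
    fails everywhere, the generic starting point is used with the broad
    variance and a warning.
    """
    if not sessions:
        raise ValueError("init_prior requires at least one session")
    opts = options or FitOptions()
    sess = [s if isinstance(s, Session) else Session.from_trials(s) for s in sessions]
    rng = np.random.default_rng(opts.seed)

    x_default = to_transformed(_DEFAULT_START_NAT)

    def pooled(x: np.ndarray) -> float:
        nat = transformed_nat(x)
        return sum(session_nll(s, nat, config) for s in sess)

    starts = [x_default] + [
        x_default + rng.normal(0.0, 1.0, size=len(PARAM_NAMES))
        for _ in range(opts.n_starts - 1)
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            pooled, np.clip(x0, *zip(*_BOUNDS)), method="L-BFGS-B",
            bounds=_BOUNDS,
            options={"maxiter": opts.maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        logger.warning("pooled ML failed; falling back to broad default prior")
        mean = x_default
    else:
        mean = np.asarray(best.x, dtype=float)
    return GroupPrior(mean=mean, variance=np.full(len(PARAM_NAMES), variance))


def em_fit(
    sessions: list,
    config: TwoStepConfig,
    tol: float | None = None,
    max_iter: int | None = None,
    options: FitOptions | None = None,
    prior: GroupPrior | None = None,
) -> EMResult:
    """Fit a cohort by empirical-Bayes EM.

    Requires at least two subjects for a meaningful M-step. Returns the
    final prior, per-subject fits, and the per-iteration Laplace evidence
    trajectory. Non-convergence within ``max_iter`` is reported via the
    ``converged`` flag, never raised.
    """
    opts = options or FitOptions()
    tol = opts.tol if tol is None else tol
    max_iter = opts.max_em_iter if max_iter is None else max_iter
    if len(sessions) < 2:
        raise ValueError("em_fit requires at least 2 subjects")
    sess = [s if isinstance(s, Session) else Session.from_trials(s) for s in sessions]

    if prior is None:
        prior = init_prior(sess, config, options=opts)
    rng = np.random.default_rng(opts.seed)

    fits: list[SubjectFit] = []
    trajectory: list[float] = []
    converged = False
    it = 0
    warm: list[np.ndarray] | None = None
    for it in range(1, max_iter + 1):
        fits = []
        for j, s in enumerate(sess):
            extra = [warm[j]] if warm is not None else None
            fits.append(
                subject_map(s, prior, config, options=opts, extra_starts=extra, rng=rng)
            )
        ok = [f for f in fits if f.converged]
        if not ok:
            logger.warning("EM iteration %d: no subject fit converged", it)
            ok = fits

        evidence = sum(
            -f.nll + prior.logpdf(f.map_params)
            + 0.5 * float(np.sum(np.log(2.0 * np.pi * np.e * f.laplace_variance)))
            for f in fits
        )
        trajectory.append(float(evidence))

        maps = np.stack([f.map_params for f in ok])
        lvars = np.stack([f.laplace_variance for f in ok])
        new_mean = maps.mean(axis=0)
        if opts.update_variance:
            new_var = (maps**2 + lvars).mean(axis=0) - new_mean**2
            new_var = np.maximum(new_var, 1e-6)
        else:
            new_var = prior.variance
        delta = float(np.max(np.abs(new_mean - prior.mean)))
        logger.info(
            "EM iter %d: evidence %.3f, max prior-mean change %.2e", it, evidence, delta
        )
        prior = GroupPrior(mean=new_mean, variance=new_var)
        warm = [f.map_params for f in fits]
        if delta < tol:
            converged = True
            break

    return EMResult(
        prior=prior, fits=fits, n_iterations=it,
        trajectory=trajectory, converged=converged,
    )


def fits_to_frame(fits: list[SubjectFit], subject_ids=None) -> pd.DataFrame:
    """Per-subject parameter table: natural, transformed, β splits, −LL."""
    if subject_ids is None:
        subject_ids = list(range(len(fits)))
    rows = []
    for sid, f in zip(subject_ids, fits):
        row = {"subject_id": sid}
        row.update(dataclasses.asdict(f.nat_params))
        bmb, bmf = split_betas(f.nat_params.omega, f.nat_params.beta1)
        row["beta_mb"] = bmb
        row["beta_mf"] = bmf
        for n, v in zip(PARAM_NAMES, f.map_params):
            row[f"{n}_transformed"] = float(v)
        row["nll"] = f.nll
        row["converged"] = f.converged
        rows.append(row)
    return pd.DataFrame(rows)
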