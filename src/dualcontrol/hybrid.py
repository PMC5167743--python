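"""Hybrid model-based / model-free reinforcement-learning model.

The model combines a SARSA(λ) model-free (MF) learner with a model-based
(MB) planner that exploits the instructed 70/30 transition structure of the
two-step task.

Per trial, with stages i ∈ {1, 2}:

* MF values are updated by reward prediction errors,
  ``Q_MF ← Q_MF + α_i δ_i`` with ``δ_1 = Q_MF(stage-2 chosen) − Q_MF(stage-1
  chosen)`` (no reward after stage 1) and ``δ_2 = r − Q_MF(stage-2 chosen)``.
  The second-stage error additionally back-propagates to the chosen
  first-stage value with weight λ: ``Q_MF(stage 1) ← Q_MF(stage 1) + α_1 λ δ_2``.
* MB first-stage values are recomputed each trial as the
  transition-probability-weighted best second-stage MF value:
  ``Q_MB(a) = P(B|a)·max_a' Q_MF(B,a') + P(C|a)·max_a' Q_MF(C,a')``.
* The first-stage decision values mix the two systems with weight ω:
  ``Q = ω Q_MB + (1−ω) Q_MF``.
* Choices follow a softmax with inverse temperature β_i and, at stage 1
  only, a perseveration bonus ρ for repeating the previous first-stage
  action: ``p(a) ∝ exp(β_i [Q(a) + ρ·rep(a)])``.

The MB and MF contributions to first-stage choice stochasticity are
summarized by ``β_MB = ω β_1`` and ``β_MF = (1−ω) β_1``.

δ_1 is computed with the pre-update second-stage value; all three value
increments of a trial are then applied. Unchosen values are never updated
and there is no forgetting. Values start at zero each session.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

from .twostep import RewardWalks, Session, TwoStepConfig, TwoStepTrial, build_reward_walks

__all__ = [
    "AgentParams",
    "ValueState",
    "PARAM_NAMES",
    "split_betas",
    "to_transformed",
    "from_transformed",
    "mf_update",
    "mb_values",
    "hybrid_values",
    "choice_probs",
    "session_nll",
    "simulate_agent",
]

PARAM_NAMES = ("alpha1", "alpha2", "lam", "omega", "beta1", "beta2", "rho")

#: indices of log-odds-transformed (unit-interval) and log-transformed
#: (positive) parameters in the 7-vector; rho is fitted on the identity scale
_LOGIT_IDX = (0, 1, 2, 3)
_LOG_IDX = (4, 5)


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the hybrid learner, on the natural scale.

    alpha1, alpha2 : stage-wise learning rates in (0, 1)
    lam            : eligibility weight λ in (0, 1) coupling the stage-2
                     prediction error to stage-1 values
    omega          : MB weight ω in (0, 1); ω=1 is a pure planner, ω=0 a
                     pure MF learner
    beta1, beta2   : stage-wise softmax inverse temperatures, >= 0
    rho            : perseveration bonus for repeating the previous
                     first-stage choice (unbounded)
    """

    alpha1: float
    alpha2: float
    lam: float
    omega: float
    beta1: float
    beta2: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "omega"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be >= 0")

    @property
    def beta_mb(self) -> float:
        return self.omega * self.beta1

    @property
    def beta_mf(self) -> float:
        return (1.0 - self.omega) * self.beta1

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "AgentParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def to_json(self, scale: str = "natural") -> str:
        if scale == "natural":
            payload = dataclasses.asdict(self)
        elif scale == "transformed":
            payload = dict(zip(PARAM_NAMES, map(float, to_transformed(self))))
        else:
            raise ValueError(f"unknown scale {scale!r}")
        payload["scale"] = scale
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "AgentParams":
        d = json.loads(s)
        scale = d.pop("scale", "natural")
        x = np.array([d[n] for n in PARAM_NAMES], dtype=float)
        if scale == "transformed":
            return from_transformed(x)
        return cls.from_vector(x)


@dataclass
class ValueState:
    """Mutable value state carried across trials of one session."""

    q_mf_stage1: np.ndarray  # (2,)
    q_mf_stage2: np.ndarray  # (2 states, 2 actions)
    last_a1: int | None = None

    @classmethod
    def zeros(cls) -> "ValueState":
        return cls(q_mf_stage1=np.zeros(2), q_mf_stage2=np.zeros((2, 2)))


def split_betas(omega: float, beta1: float) -> tuple[float, float]:
    """Decompose the stage-1 inverse temperature into MB and MF shares.

    Returns ``(beta_mb, beta_mf) = (ω β₁, (1−ω) β₁)``; the two always sum
    to ``beta1`` exactly.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    if beta1 < 0:
        raise ValueError(f"beta1 must be >= 0, got {beta1}")
    beta_mb = omega * beta1
    return beta_mb, beta1 - beta_mb


def to_transformed(params: AgentParams) -> np.ndarray:
    """Map natural parameters to the unconstrained fitting scale.

    α, λ, ω are log-odds transformed, β₁ and β₂ log transformed, ρ is left
    on the identity scale. Raises on boundary values where the transform is
    undefined.
    """
    x = params.to_vector()
    y = x.copy()
    for i in _LOGIT_IDX:
        if not (0.0 < x[i] < 1.0):
            raise ValueError(
                f"{PARAM_NAMES[i]}={x[i]} is on the boundary; log-odds undefined"
            )
        y[i] = math.log(x[i] / (1.0 - x[i]))
    for i in _LOG_IDX:
        if x[i] <= 0.0:
            raise ValueError(f"{PARAM_NAMES[i]}={x[i]} must be > 0 for log transform")
        y[i] = math.log(x[i])
    return y


def from_transformed(y: np.ndarray) -> AgentParams:
    """Inverse of :func:`to_transformed`."""
    y = np.asarray(y, dtype=float)
    x = y.copy()
    for i in _LOGIT_IDX:
        x[i] = 1.0 / (1.0 + math.exp(-y[i]))
    for i in _LOG_IDX:
        x[i] = math.exp(y[i])
    return AgentParams.from_vector(x)


def transformed_nat(y: np.ndarray) -> np.ndarray:
    """Vector version of :func:`from_transformed` without bounds validation.

    Used inside optimization loops where β may underflow to 0 harmlessly.
    """
    y = np.asarray(y, dtype=float)
    x = y.copy()
    for i in _LOGIT_IDX:
        x[i] = 1.0 / (1.0 + math.exp(-y[i]))
    for i in _LOG_IDX:
        x[i] = math.exp(min(y[i], 700.0))
    return x


def mf_update(
    state: ValueState, trial: TwoStepTrial, params: AgentParams
) -> tuple[ValueState, float, float]:
    """Apply one trial's SARSA(λ) updates in place.

    Returns ``(state, delta1, delta2)``. Invalid trials leave the state
    untouched (deltas 0); ``last_a1`` is only advanced on valid trials so
    that perseveration refers to the last *observed* choice.
    """
    if not trial.valid:
        return state, 0.0, 0.0
    q1 = state.q_mf_stage1
    q2 = state.q_mf_stage2
    delta1 = q2[trial.state2, trial.a2] - q1[trial.a1]
    delta2 = trial.r - q2[trial.state2, trial.a2]
    q1[trial.a1] += params.alpha1 * delta1
    q2[trial.state2, trial.a2] += params.alpha2 * delta2
    q1[trial.a1] += params.alpha1 * params.lam * delta2
    state.last_a1 = trial.a1
    return state, float(delta1), float(delta2)


def mb_values(state: ValueState, config: TwoStepConfig) -> np.ndarray:
    """First-stage MB values from current second-stage MF values.

    Action ``a`` leads commonly (probability ``p_common``) to state ``a``;
    its MB value is the transition-weighted max over that state's MF values.
    """
    pc = config.p_common
    best = state.q_mf_stage2.max(axis=1)  # (2,) per second-stage state
    return np.array([pc * best[0] + (1 - pc) * best[1],
                     pc * best[1] + (1 - pc) * best[0]])


def hybrid_values(state: ValueState, params: AgentParams,
                  config: TwoStepConfig) -> np.ndarray:
    """Convex ω-combination of MB and MF first-stage values."""
    return params.omega * mb_values(state, config) + (
        1.0 - params.omega
    ) * state.q_mf_stage1


def choice_probs(
    values: np.ndarray,
    beta: float,
    rho: float = 0.0,
    last_action: int | None = None,
    stage: int = 1,
) -> np.ndarray:
    """Softmax choice probabilities over two actions.

    The perseveration bonus ρ is added to the action matching the previous
    trial's first-stage choice, at stage 1 only. Computed with max
    subtraction so large β·Q never overflows.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    v = np.asarray(values, dtype=float).copy()
    if stage == 1 and last_action is not None:
        v[last_action] += rho
    v *= beta
    if not np.all(np.isfinite(v)):
        raise FloatingPointError(f"non-finite decision values: {v}")
    v -= v.max()
    ev = np.exp(v)
    return ev / ev.sum()


# ---------------------------------------------------------------------------
# Fast likelihood path.
#
# The MF/MB value trajectories depend only on (alpha1, alpha2, lam) and the
# observed trial sequence, not on (omega, beta1, beta2, rho): choices enter
# the updates as data, never through the policy. One sequential pass per
# (alpha1, alpha2, lam) therefore serves every softmax-parameter setting,
# which the per-session trajectory cache exploits heavily during
# finite-difference optimization and grid search.
# ---------------------------------------------------------------------------


def _trajectories(session: Session, alpha1: float, alpha2: float, lam: float):
    """Pre-choice value trajectories for each trial of a session.

    Returns arrays ``qmf1`` (T,2) stage-1 MF values, ``qmax`` (T,2) max MF
    value per second-stage state, ``q2ch`` (T,2) MF values of the
    encountered second-stage pair, and ``rep`` (T,2) the 0/1 perseveration
    indicator — all evaluated before that trial's update.
    """
    key = (round(alpha1, 15), round(alpha2, 15), round(lam, 15))
    cached = session._traj_cache.get(key)
    if cached is not None:
        return cached

    a1s = session.a1.tolist()
    s2s = session.s2.tolist()
    a2s = session.a2.tolist()
    rs = session.r.tolist()
    valids = session.valid.tolist()
    T = session.n

    qmf1 = np.empty((T, 2))
    qmax = np.empty((T, 2))
    q2ch = np.empty((T, 2))
    rep = np.zeros((T, 2))

    q1 = [0.0, 0.0]
    q2 = [[0.0, 0.0], [0.0, 0.0]]
    last = -1
    al = alpha1 * lam
    for t in range(T):
        qmf1[t, 0] = q1[0]
        qmf1[t, 1] = q1[1]
        qmax[t, 0] = q2[0][0] if q2[0][0] >= q2[0][1] else q2[0][1]
        qmax[t, 1] = q2[1][0] if q2[1][0] >= q2[1][1] else q2[1][1]
        s2 = s2s[t]
        q2ch[t, 0] = q2[s2][0]
        q2ch[t, 1] = q2[s2][1]
        if last >= 0:
            rep[t, last] = 1.0
        if not valids[t]:
            continue
        a1 = a1s[t]
        a2 = a2s[t]
        q2sa = q2[s2][a2]
        delta1 = q2sa - q1[a1]
        delta2 = rs[t] - q2sa
        q1[a1] += alpha1 * delta1
        q2[s2][a2] += alpha2 * delta2
        q1[a1] += al * delta2
        last = a1

    out = (qmf1, qmax, q2ch, rep)
    if len(session._traj_cache) >= Session._CACHE_MAX:
        session._traj_cache.pop(next(iter(session._traj_cache)))
    session._traj_cache[key] = out
    return out


def session_nll(
    session: Session | list[TwoStepTrial],
    params: AgentParams | np.ndarray,
    config: TwoStepConfig,
) -> float:
    """Negative log-likelihood of a session under the hybrid model.

    Sums ``−log p(a1) − log p(a2)`` over valid trials, with values updated
    sequentially; invalid trials contribute nothing and do not update
    values. An empty session scores 0.
    """
    if not isinstance(session, Session):
        session = Session.from_trials(session)
    if isinstance(params, AgentParams):
        x = params.to_vector()
    else:
        x = np.asarray(params, dtype=float)
    alpha1, alpha2, lam, omega, beta1, beta2, rho = x
    if session.n == 0:
        return 0.0

    qmf1, qmax, q2ch, rep = _trajectories(session, alpha1, alpha2, lam)
    pc = config.p_common
    qmb = np.empty_like(qmax)
    qmb[:, 0] = pc * qmax[:, 0] + (1 - pc) * qmax[:, 1]
    qmb[:, 1] = pc * qmax[:, 1] + (1 - pc) * qmax[:, 0]

    v1 = beta1 * (omega * qmb + (1.0 - omega) * qmf1 + rho * rep)
    v2 = beta2 * q2ch

    idx = np.arange(session.n)
    m1 = v1.max(axis=1)
    lse1 = m1 + np.log(np.exp(v1[:, 0] - m1) + np.exp(v1[:, 1] - m1))
    lp1 = v1[idx, session.a1] - lse1
    m2 = v2.max(axis=1)
    lse2 = m2 + np.log(np.exp(v2[:, 0] - m2) + np.exp(v2[:, 1] - m2))
    lp2 = v2[idx, session.a2] - lse2

    mask = session.valid
    return float(-(lp1[mask].sum() + lp2[mask].sum()))


def simulate_agent(
    params: AgentParams,
    config: TwoStepConfig,
    seed: int,
    walks: RewardWalks | None = None,
) -> list[TwoStepTrial]:
    """Generate one session of hybrid-agent behavior.

    Environment (walks, transitions, rewards) and choices are reproducible
    from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if walks is None:
        walks = build_reward_walks(config, seed=int(rng.integers(2**31)))
    state = ValueState.zeros()
    trials: list[TwoStepTrial] = []
    for t in range(config.n_trials):
        qh = hybrid_values(state, params, config)
        p1 = choice_probs(qh, params.beta1, params.rho, state.last_a1, stage=1)
        a1 = int(rng.random() < p1[1])
        common = rng.random() < config.p_common
        state2 = a1 if common else 1 - a1
        p2 = choice_probs(state.q_mf_stage2[state2], params.beta2, stage=2)
        a2 = int(rng.random() < p2[1])
        r = int(rng.random() < walks.prob(state2, a2, t))
        trial = TwoStepTrial(
            t=t, a1=a1, state2=state2,
            transition="common" if common else "rare", a2=a2, r=r,
        )
        mf_update(state, trial, params)
        trials.append(trial)
    return trials
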