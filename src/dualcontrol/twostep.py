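"""Two-step Markov decision task environment.

The task has a single first-stage state with two actions. Each first-stage
action leads predominantly (probability ``p_common``, 70% by default) to one
of two second-stage states, B or C, and rarely (30%) to the other. Each
second-stage state offers two actions whose binary reward probabilities
drift across trials as bounded Gaussian random walks, which keeps subjects
(or simulated agents) learning throughout the session.

Conventions used across the package:

* actions are coded 0/1 at both stages;
* second-stage states are coded 0 (``B``) and 1 (``C``);
* first-stage action ``a`` leads commonly to state ``a`` — i.e. action 0 is
  predominantly linked to B and action 1 to C;
* the four reward walks are ordered (B,action0), (B,action1), (C,action0),
  (C,action1) and named A..D in CSV output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoStepConfig",
    "RewardWalks",
    "TwoStepTrial",
    "Session",
    "build_reward_walks",
    "sample_transition",
    "run_session",
    "trials_to_frame",
    "frame_to_trials",
    "STATE_LABELS",
]

STATE_LABELS = ("B", "C")

WALK_COLUMNS = ("p_rewA", "p_rewB", "p_rewC", "p_rewD")


class ConfigurationError(ValueError):
    """Raised when a task configuration violates its invariants."""


@dataclass(frozen=True)
class TwoStepConfig:
    """Design parameters of the two-step task.

    Defaults follow the canonical instantiation: 201 scored two-stage
    trials preceded by 55 practice trials, a 70/30 transition structure,
    and reward walks with per-trial Gaussian increments of sd 0.025
    reflected at [0.25, 0.75].
    """

    n_trials: int = 201
    n_practice: int = 55
    p_common: float = 0.7
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    reward_magnitude: float = 0.20  # euros; cosmetic only
    seed: int | None = None

    def __post_init__(self) -> None:
        low, high = self.walk_bounds
        if not (0.5 < self.p_common <= 1.0):
            raise ConfigurationError(
                f"p_common must lie in (0.5, 1], got {self.p_common}"
            )
        if self.walk_sd < 0:
            raise ConfigurationError(f"walk_sd must be >= 0, got {self.walk_sd}")
        if not (0.0 <= low < high <= 1.0):
            raise ConfigurationError(
                f"walk_bounds must satisfy 0 <= low < high <= 1, got {self.walk_bounds}"
            )
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.n_practice < 0:
            raise ConfigurationError(f"n_practice must be >= 0, got {self.n_practice}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["walk_bounds"] = list(self.walk_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStepConfig":
        d = dict(d)
        if "walk_bounds" in d:
            d["walk_bounds"] = tuple(d["walk_bounds"])
        return cls(**d)


@dataclass(frozen=True)
class RewardWalks:
    """Reward probabilities for the four second-stage actions.

    ``p_reward`` has shape (4, n_trials); row order is (state B, action 0),
    (B, 1), (C, 0), (C, 1).
    """

    p_reward: np.ndarray

    def prob(self, state2: int, a2: int, t: int) -> float:
        return float(self.p_reward[2 * state2 + a2, t])


@dataclass(frozen=True)
class TwoStepTrial:
    """One two-stage trial."""

    t: int
    a1: int
    state2: int  # 0 = B, 1 = C
    transition: str  # "common" | "rare"
    a2: int
    r: int
    valid: bool = True
    practice: bool = False

    def __post_init__(self) -> None:
        expected = "common" if self.state2 == self.a1 else "rare"
        if self.transition != expected:
            raise ValueError(
                f"transition label {self.transition!r} inconsistent with "
                f"a1={self.a1}, state2={self.state2}"
            )
        if self.r not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.r}")


def build_reward_walks(config: TwoStepConfig, seed: int) -> RewardWalks:
    """Generate the four bounded Gaussian-random-walk reward series.

    Each series starts at an independent uniform draw within
    ``walk_bounds`` and adds a zero-mean Gaussian increment of sd
    ``walk_sd`` per trial, reflected once at the boundaries.
    """
    rng = np.random.default_rng(seed)
    low, high = config.walk_bounds
    n = config.n_trials
    p = np.empty((4, n))
    p[:, 0] = rng.uniform(low, high, size=4)
    steps = rng.normal(0.0, config.walk_sd, size=(4, max(n - 1, 0)))
    for t in range(1, n):
        nxt = p[:, t - 1] + steps[:, t - 1]
        # single reflection at each bound
        nxt = np.where(nxt > high, 2 * high - nxt, nxt)
        nxt = np.where(nxt < low, 2 * low - nxt, nxt)
        p[:, t] = np.clip(nxt, low, high)
    return RewardWalks(p_reward=p)


def sample_transition(
    a1: int, config: TwoStepConfig, rng: np.random.Generator
) -> tuple[int, str]:
    """Sample the second-stage state reached from first-stage action ``a1``.

    Returns ``(state2, label)`` where label is "common" when the
    predominantly linked state was reached.
    """
    if a1 not in (0, 1):
        raise ValueError(f"a1 must be 0 or 1, got {a1}")
    common = rng.random() < config.p_common
    state2 = a1 if common else 1 - a1
    return state2, ("common" if common else "rare")


def run_session(
    policy: Callable[[list[TwoStepTrial], int | None], int],
    config: TwoStepConfig,
    seed: int,
    walks: RewardWalks | None = None,
    practice: bool = False,
) -> list[TwoStepTrial]:
    """Run one session of the task under a caller-supplied policy.

    The policy is a function ``policy(history, state2) -> action`` invoked
    twice per trial: first with ``state2=None`` for the first-stage action,
    then with the sampled second-stage state for the second-stage action.
    ``history`` is the list of completed trials.

    Rewards are Bernoulli draws from the walk value of the chosen
    second-stage action at trial ``t``. The result is a pure function of
    ``(config, policy, seed)``.
    """
    rng = np.random.default_rng(seed)
    if walks is None:
        walks = build_reward_walks(config, seed=int(rng.integers(2**31)))
    trials: list[TwoStepTrial] = []
    for t in range(config.n_trials):
        a1 = int(policy(trials, None))
        if a1 not in (0, 1):
            raise ValueError(f"policy returned invalid first-stage action {a1}")
        state2, label = sample_transition(a1, config, rng)
        a2 = int(policy(trials, state2))
        if a2 not in (0, 1):
            raise ValueError(f"policy returned invalid second-stage action {a2}")
        r = int(rng.random() < walks.prob(state2, a2, t))
        trials.append(
            TwoStepTrial(
                t=t, a1=a1, state2=state2, transition=label, a2=a2, r=r,
                valid=True, practice=practice,
            )
        )
    return trials


class Session:
    """Array view of one subject's session, used by the likelihood code.

    Holds column arrays of the trial sequence plus a small cache of
    model-free value trajectories keyed by the learning parameters that
    determine them (see :mod:`dualcontrol.hybrid`).
    """

    __slots__ = ("a1", "s2", "a2", "r", "valid", "n", "_traj_cache")

    _CACHE_MAX = 8

    def __init__(
        self,
        a1: Sequence[int],
        s2: Sequence[int],
        a2: Sequence[int],
        r: Sequence[int],
        valid: Sequence[bool] | None = None,
    ) -> None:
        self.a1 = np.asarray(a1, dtype=np.int64)
        self.s2 = np.asarray(s2, dtype=np.int64)
        self.a2 = np.asarray(a2, dtype=np.int64)
        self.r = np.asarray(r, dtype=np.float64)
        self.n = len(self.a1)
        if valid is None:
            self.valid = np.ones(self.n, dtype=bool)
        else:
            self.valid = np.asarray(valid, dtype=bool)
        for arr in (self.s2, self.a2, self.r, self.valid):
            if len(arr) != self.n:
                raise ValueError("session columns must have equal length")
        self._traj_cache: dict = {}

    @classmethod
    def from_trials(cls, trials: Sequence[TwoStepTrial]) -> "Session":
        scored = [tr for tr in trials if not tr.practice]
        return cls(
            a1=[tr.a1 for tr in scored],
            s2=[tr.state2 for tr in scored],
            a2=[tr.a2 for tr in scored],
            r=[tr.r for tr in scored],
            valid=[tr.valid for tr in scored],
        )

    def n_valid(self) -> int:
        return int(self.valid.sum())


def trials_to_frame(
    trials: Sequence[TwoStepTrial],
    subject_id: str | int = 0,
    walks: RewardWalks | None = None,
) -> pd.DataFrame:
    """Serialize trials to the tidy trial-table schema."""
    rows = []
    for tr in trials:
        row = {
            "subject_id": subject_id,
            "t": tr.t,
            "a1": tr.a1,
            "state2": STATE_LABELS[tr.state2],
            "transition": tr.transition,
            "a2": tr.a2,
            "r": tr.r,
            "valid": int(tr.valid),
            "practice": int(tr.practice),
        }
        if walks is not None:
            for k, col in enumerate(WALK_COLUMNS):
                row[col] = walks.p_reward[k, tr.t]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> list[TwoStepTrial]:
    """Parse a trial-table DataFrame (one subject) back into trials."""
    required = {"t", "a1", "state2", "transition", "a2", "r"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials = []
    for row in df.itertuples(index=False):
        state2 = STATE_LABELS.index(str(row.state2))
        trials.append(
            TwoStepTrial(
                t=int(row.t),
                a1=int(row.a1),
                state2=state2,
                transition=str(row.transition),
                a2=int(row.a2),
                r=int(row.r),
                valid=bool(getattr(row, "valid", True)),
                practice=bool(getattr(row, "practice", False)),
            )
        )
    return trials
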