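"""Three-phase instrumental learning ("slips-of-action") paradigm.

Six stimuli map deterministically onto six unique outcomes; three stimuli
require a left and three a right button press. The paradigm has four parts:

training
    8 blocks × 12 trials (96 total; each stimulus 16 times, twice per
    block); subjects learn the stimulus–response–outcome map by
    trial and error.
outcome_devaluation
    36 trials pairing one left-associated and one right-associated
    outcome, one of which is devalued; the correct response is the one
    that earned the still-valuable outcome.
slips
    9 blocks × 12 trials (108 total). Per block two outcomes — one from
    each response side — are devalued; subjects respond (go) to stimuli
    whose outcomes are still valuable and withhold (no-go) for devalued
    ones. Each outcome is devalued in exactly 3 of the 9 blocks, giving
    36 devalued and 72 valued trials. Stimuli never repeat back-to-back.
baseline
    identical structure, but devaluation applies to stimuli directly, so
    inhibition needs no outcome knowledge.

The devaluation sensitivity index (DSI) for the slips (and baseline) test
is the percentage of valued trials with a response minus the percentage of
devalued trials with a response; 100 is perfectly goal-directed, 0 is
outcome-insensitive responding. A literal variant normalizing both counts
by the total response count is available via ``dsi_mode="total"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SROMap",
    "SlipsSchedule",
    "SlipsAgentParams",
    "SlipsPhaseScores",
    "PHASES",
    "build_schedule",
    "simulate_training",
    "simulate_devaluation_test",
    "simulate_test_phase",
    "score_phase",
]

PHASES = ("training", "outcome_devaluation", "slips", "baseline")

N_STIMULI = 6
TRAINING_BLOCKS = 8
TEST_BLOCKS = 9
REPS_PER_BLOCK = 2  # each stimulus, in training and slips/baseline blocks


@dataclass(frozen=True)
class SROMap:
    """Stimulus → (response, outcome) contingencies.

    ``correct_response[s]`` is 0 (left) or 1 (right); ``outcome[s]`` is the
    unique outcome index delivered by the correct response ("100%
    contingency"). Exactly three stimuli per response side.
    """

    correct_response: tuple[int, ...]
    outcome: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.correct_response) != N_STIMULI or len(self.outcome) != N_STIMULI:
            raise ValueError("SROMap needs exactly 6 stimuli")
        if sorted(self.correct_response) != [0, 0, 0, 1, 1, 1]:
            raise ValueError("exactly 3 left- and 3 right-response stimuli required")
        if len(set(self.outcome)) != N_STIMULI:
            raise ValueError("outcomes must be unique")

    @classmethod
    def default(cls, seed: int | None = None) -> "SROMap":
        """Random assignment of sides and outcomes to stimuli."""
        rng = np.random.default_rng(seed)
        sides = rng.permutation([0, 0, 0, 1, 1, 1])
        outcomes = rng.permutation(N_STIMULI)
        return cls(tuple(int(s) for s in sides), tuple(int(o) for o in outcomes))

    def stimuli_for_side(self, side: int) -> list[int]:
        return [s for s in range(N_STIMULI) if self.correct_response[s] == side]

    def outcome_to_stimulus(self) -> dict[int, int]:
        return {o: s for s, o in enumerate(self.outcome)}


@dataclass(frozen=True)
class SlipsSchedule:
    """Trial schedule for one phase.

    ``blocks`` lists stimulus indices per block, except for the
    outcome-devaluation phase where entries are ``(left_outcome,
    right_outcome, devalued_outcome)`` triples. ``devalued`` holds the
    per-block devalued set: outcomes for the slips phase, stimuli for
    baseline, empty for training.
    """

    phase: str
    blocks: list[list]
    devalued: list[frozenset] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass(frozen=True)
class SlipsAgentParams:
    """Synthetic responder for the paradigm.

    g       : goal-directedness in [0, 1]; the probability-scale degree to
              which devalued outcomes suppress responding
    r_base  : response probability on valued go trials
    a_learn : exponential learning rate per stimulus encounter in training
    eps     : asymptotic lapse rate
    g_base  : stimulus-level inhibition for the baseline test; near 1
              because withholding to a marked stimulus requires no outcome
              retrieval
    """

    g: float = 0.8
    r_base: float = 0.85
    a_learn: float = 0.3
    eps: float = 0.02
    g_base: float = 0.92

    def __post_init__(self) -> None:
        for name in ("g", "r_base", "a_learn", "eps", "g_base"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SlipsPhaseScores:
    """Per-subject scores for one phase; percentages in [0, 100]."""

    phase: str
    pct_correct: float | None = None
    block_pct_correct: tuple[float, ...] | None = None
    pct_responses_valued: float | None = None
    pct_responses_devalued: float | None = None
    dsi: float | None = None


def _no_repeat_order(items: list[int], rng: np.random.Generator,
                     forbidden_first: int | None) -> list[int]:
    """Shuffle ``items`` so no two equal entries are adjacent and the first
    differs from ``forbidden_first``; rejection sampling (cheap at n=12)."""
    items = list(items)
    for _ in range(10_000):
        rng.shuffle(items)
        if forbidden_first is not None and items[0] == forbidden_first:
            continue
        if all(items[i] != items[i + 1] for i in range(len(items) - 1)):
            return items
    raise RuntimeError("could not satisfy no-immediate-repeat constraint")


def _balanced_devaluation(sides: tuple[list[int], list[int]],
                          rng: np.random.Generator) -> list[tuple[int, int]]:
    """Per-block (left, right) devalued items: each of the 3 items per side
    is used in exactly 3 of the 9 blocks, order shuffled."""
    left = [sides[0][i % 3] for i in range(TEST_BLOCKS)]
    right = [sides[1][i % 3] for i in range(TEST_BLOCKS)]
    rng.shuffle(left)
    rng.shuffle(right)
    return list(zip(left, right))


def build_schedule(phase: str, sro: SROMap, seed: int) -> SlipsSchedule:
    """Build a randomized schedule for one phase (see module docstring for
    the per-phase design constants)."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(seed)

    if phase == "training":
        blocks = []
        prev_last: int | None = None
        for _ in range(TRAINING_BLOCKS):
            block = _no_repeat_order(
                list(range(N_STIMULI)) * REPS_PER_BLOCK, rng, prev_last
            )
            blocks.append(block)
            prev_last = block[-1]
        return SlipsSchedule(phase=phase, blocks=blocks)

    if phase == "outcome_devaluation":
        left_out = [sro.outcome[s] for s in sro.stimuli_for_side(0)]
        right_out = [sro.outcome[s] for s in sro.stimuli_for_side(1)]
        trials = []
        # all 9 left×right outcome pairs, 4 repeats each, devaluation side
        # counterbalanced 2/2 within pair
        for lo in left_out:
            for ro in right_out:
                for devalued in (lo, lo, ro, ro):
                    trials.append((lo, ro, devalued))
        order = rng.permutation(len(trials))
        return SlipsSchedule(phase=phase, blocks=[[trials[i] for i in order]])

    # slips / baseline
    if phase == "slips":
        left = [sro.outcome[s] for s in sro.stimuli_for_side(0)]
        right = [sro.outcome[s] for s in sro.stimuli_for_side(1)]
    else:
        left = sro.stimuli_for_side(0)
        right = sro.stimuli_for_side(1)
    pairs = _balanced_devaluation((left, right), rng)
    blocks = []
    devalued = []
    prev_last: int | None = None
    for b in range(TEST_BLOCKS):
        block = _no_repeat_order(
            list(range(N_STIMULI)) * REPS_PER_BLOCK, rng, prev_last
        )
        blocks.append(block)
        prev_last = block[-1]
        devalued.append(frozenset(pairs[b]))
    return SlipsSchedule(phase=phase, blocks=blocks, devalued=devalued)


def _trial_devalued(phase: str, stimulus: int, devalued: frozenset,
                    sro: SROMap) -> bool:
    if phase == "slips":
        return sro.outcome[stimulus] in devalued
    return stimulus in devalued


def simulate_training(
    agent: SlipsAgentParams, schedule: SlipsSchedule, sro: SROMap, seed: int
) -> pd.DataFrame:
    """Simulate the discrimination training phase.

    Correct-response probability for a stimulus rises from chance toward
    ``1 − eps`` as ``p_k = (1−eps) − (0.5−eps)·exp(−a_learn·k)`` at the
    k-th encounter (k = 0, 1, ...).
    """
    if schedule.phase != "training":
        raise ValueError("simulate_training requires a training schedule")
    rng = np.random.default_rng(seed)
    seen = np.zeros(N_STIMULI, dtype=int)
    rows = []
    for b, block in enumerate(schedule.blocks):
        for i, s in enumerate(block):
            p = (1 - agent.eps) - (0.5 - agent.eps) * np.exp(-agent.a_learn * seen[s])
            correct = bool(rng.random() < p)
            seen[s] += 1
            resp = sro.correct_response[s] if correct else 1 - sro.correct_response[s]
            rows.append(
                {
                    "phase": "training", "block": b, "trial": i, "stimulus": s,
                    "devalued_flag": 0,
                    "response": "left" if resp == 0 else "right",
                    "correct_flag": int(correct),
                }
            )
    return pd.DataFrame(rows)


def simulate_devaluation_test(
    agent: SlipsAgentParams, schedule: SlipsSchedule, sro: SROMap, seed: int
) -> pd.DataFrame:
    """Simulate the outcome-devaluation test.

    Choosing the still-valuable side requires outcome knowledge; the agent
    is correct with probability ``0.5 + (0.5 − eps)·g``, i.e. chance for a
    pure stimulus–response agent and near-perfect for a goal-directed one.
    """
    if schedule.phase != "outcome_devaluation":
        raise ValueError("requires an outcome_devaluation schedule")
    rng = np.random.default_rng(seed)
    p_correct = 0.5 + (0.5 - agent.eps) * agent.g
    rows = []
    for i, (lo, ro, devalued) in enumerate(schedule.blocks[0]):
        valued = ro if devalued == lo else lo
        correct_side = 0 if valued == lo else 1
        correct = bool(rng.random() < p_correct)
        resp = correct_side if correct else 1 - correct_side
        rows.append(
            {
                "phase": "outcome_devaluation", "block": 0, "trial": i,
                "stimulus": sro.outcome_to_stimulus()[valued],
                "devalued_flag": 0,
                "response": "left" if resp == 0 else "right",
                "correct_flag": int(correct),
            }
        )
    return pd.DataFrame(rows)


def simulate_test_phase(
    agent: SlipsAgentParams, schedule: SlipsSchedule, sro: SROMap, seed: int
) -> pd.DataFrame:
    """Simulate go/no-go responding in the slips or baseline test.

    The agent responds on valued trials with probability ``r_base``. On
    devalued trials the response ("slip") probability is ``r_base·(1−g)``
    in the slips phase and ``r_base·(1−g_base)`` in the baseline phase.
    """
    if schedule.phase not in ("slips", "baseline"):
        raise ValueError("requires a slips or baseline schedule")
    rng = np.random.default_rng(seed)
    inhibition = agent.g if schedule.phase == "slips" else agent.g_base
    rows = []
    for b, block in enumerate(schedule.blocks):
        dev = schedule.devalued[b]
        for i, s in enumerate(block):
            is_dev = _trial_devalued(schedule.phase, s, dev, sro)
            p_resp = agent.r_base * (1 - inhibition) if is_dev else agent.r_base
            responded = bool(rng.random() < p_resp)
            if responded:
                resp = "left" if sro.correct_response[s] == 0 else "right"
            else:
                resp = "none"
            rows.append(
                {
                    "phase": schedule.phase, "block": b, "trial": i, "stimulus": s,
                    "devalued_flag": int(is_dev),
                    "response": resp,
                    # correct = respond on valued, withhold on devalued
                    "correct_flag": int(responded != is_dev),
                }
            )
    return pd.DataFrame(rows)


def score_phase(records: pd.DataFrame, phase: str,
                dsi_mode: str = "per_trial_type") -> SlipsPhaseScores:
    """Score one subject's records for one phase.

    For the slips and baseline tests, response percentages are computed per
    trial type (default): responses on valued trials over the number of
    valued trials, likewise for devalued, and DSI is their difference.
    ``dsi_mode="total"`` instead normalizes both counts by the total number
    of responses.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    sub = records[records["phase"] == phase]
    if sub.empty:
        raise ValueError(f"no records for phase {phase!r}")
    expected = {"training": 96, "outcome_devaluation": 36,
                "slips": 108, "baseline": 108}[phase]
    if len(sub) < expected:
        import logging
        logging.getLogger(__name__).warning(
            "phase %s has %d of %d trials; scoring available trials",
            phase, len(sub), expected,
        )

    if phase == "training":
        blocks = tuple(
            float(100.0 * g["correct_flag"].mean())
            for _, g in sub.groupby("block", sort=True)
        )
        return SlipsPhaseScores(
            phase=phase,
            pct_correct=float(100.0 * sub["correct_flag"].mean()),
            block_pct_correct=blocks,
        )
    if phase == "outcome_devaluation":
        return SlipsPhaseScores(
            phase=phase, pct_correct=float(100.0 * sub["correct_flag"].mean())
        )

    valued = sub[sub["devalued_flag"] == 0]
    devalued = sub[sub["devalued_flag"] == 1]
    n_val_resp = int((valued["response"] != "none").sum())
    n_dev_resp = int((devalued["response"] != "none").sum())
    if dsi_mode == "per_trial_type":
        pct_val = 100.0 * n_val_resp / len(valued) if len(valued) else float("nan")
        pct_dev = 100.0 * n_dev_resp / len(devalued) if len(devalued) else float("nan")
    elif dsi_mode == "total":
        total = n_val_resp + n_dev_resp
        pct_val = 100.0 * n_val_resp / total if total else 0.0
        pct_dev = 100.0 * n_dev_resp / total if total else 0.0
    else:
        raise ValueError(f"unknown dsi_mode {dsi_mode!r}")
    return SlipsPhaseScores(
        phase=phase,
        pct_correct=float(100.0 * sub["correct_flag"].mean()),
        pct_responses_valued=float(pct_val),
        pct_responses_devalued=float(pct_dev),
        dsi=float(pct_val - pct_dev),
    )
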