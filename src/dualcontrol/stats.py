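"""Descriptive and nonparametric statistics for the two tasks.

Stay probabilities condition the repetition of the first-stage choice on
the previous trial's reward (reward / no reward) and transition (common /
rare); a model-free learner shows a reward main effect, a model-based
learner a reward × transition crossover. The 2×2 repeated-measures ANOVA
is computed through within-subject contrasts (each effect is a one-sample
t on the per-subject contrast, F = t² with df (1, n−1)), which equals the
textbook sums-of-squares formulation.

Friedman, Wilcoxon signed-rank and exact binomial tests wrap scipy with
the conventions used for these tasks (midrank ties, asymptotic p-values,
zero differences dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .twostep import Session

__all__ = [
    "StayTable",
    "stay_probability_table",
    "rm_anova_2x2",
    "friedman",
    "wilcoxon_signed_rank",
    "binomial_above_chance",
    "cohort_above_chance",
]

STAY_CELLS = (
    ("rewarded", "common"),
    ("rewarded", "rare"),
    ("unrewarded", "common"),
    ("unrewarded", "rare"),
)


@dataclass(frozen=True)
class StayTable:
    """One subject's stay probabilities by previous-trial (reward, transition).

    ``p_stay`` and ``counts`` are keyed by the cells in ``STAY_CELLS``;
    cells with no eligible trials hold NaN probabilities.
    """

    p_stay: dict
    counts: dict

    def as_array(self) -> np.ndarray:
        """2×2 array, rows = (rewarded, unrewarded), cols = (common, rare)."""
        return np.array(
            [
                [self.p_stay[("rewarded", "common")], self.p_stay[("rewarded", "rare")]],
                [self.p_stay[("unrewarded", "common")], self.p_stay[("unrewarded", "rare")]],
            ]
        )

    @property
    def complete(self) -> bool:
        return not np.isnan(self.as_array()).any()


def stay_probability_table(trials) -> StayTable:
    """Tabulate stay behavior for one session.

    Trial t (t ≥ 2 in 1-based terms) counts as a "stay" when its
    first-stage action repeats the previous valid trial's; it is
    classified by that previous trial's reward and transition type. The
    first trial contributes nothing.
    """
    if isinstance(trials, Session):
        session = trials
    else:
        session = Session.from_trials(trials)
    if session.n_valid() < 2:
        raise ValueError("need at least 2 valid trials for stay probabilities")
    idx = np.flatnonzero(session.valid)
    stays = {c: 0 for c in STAY_CELLS}
    counts = {c: 0 for c in STAY_CELLS}
    for prev, cur in zip(idx[:-1], idx[1:]):
        rew = "rewarded" if session.r[prev] > 0 else "unrewarded"
        trans = "common" if session.a1[prev] == session.s2[prev] else "rare"
        cell = (rew, trans)
        counts[cell] += 1
        if session.a1[cur] == session.a1[prev]:
            stays[cell] += 1
    p = {
        c: (stays[c] / counts[c]) if counts[c] else float("nan")
        for c in STAY_CELLS
    }
    return StayTable(p_stay=p, counts=counts)


def rm_anova_2x2(tables: list[StayTable]) -> pd.DataFrame:
    """2×2 repeated-measures ANOVA on a cohort of stay tables.

    Subjects with empty cells are dropped (with a warning). Returns a tidy
    frame with one row per effect (reward, state, reward_x_state) holding
    F, df1, df2, p and n.
    """
    complete = [t for t in tables if t.complete]
    dropped = len(tables) - len(complete)
    if dropped:
        import logging
        logging.getLogger(__name__).warning(
            "rm_anova_2x2: dropping %d subject(s) with empty cells", dropped
        )
    n = len(complete)
    if n < 3:
        raise ValueError("rm_anova_2x2 requires >= 3 subjects with complete cells")
    data = np.stack([t.as_array() for t in complete])  # (n, reward, state)
    contrasts = {
        "reward": data[:, 0, :].mean(axis=1) - data[:, 1, :].mean(axis=1),
        "state": data[:, :, 0].mean(axis=1) - data[:, :, 1].mean(axis=1),
        "reward_x_state": (data[:, 0, 0] - data[:, 0, 1]) - (data[:, 1, 0] - data[:, 1, 1]),
    }
    rows = []
    for effect, c in contrasts.items():
        se = c.std(ddof=1) / np.sqrt(n)
        if se == 0:
            t = 0.0
        else:
            t = c.mean() / se
        F = t * t
        p = float(sps.f.sf(F, 1, n - 1)) if F > 0 else 1.0
        rows.append({"effect": effect, "F": float(F), "df1": 1, "df2": n - 1,
                     "p": p, "n": n})
    return pd.DataFrame(rows)


def friedman(block_scores: np.ndarray) -> tuple[float, float]:
    """Friedman test across repeated conditions (e.g. training blocks).

    ``block_scores`` is (subjects × conditions); midrank ties, chi-square
    approximation with k−1 df.
    """
    block_scores = np.asarray(block_scores, dtype=float)
    if block_scores.ndim != 2 or block_scores.shape[1] < 2:
        raise ValueError("need a 2-D (subjects x >=2 conditions) array")
    if block_scores.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n, k = block_scores.shape
    # rank within subject with midranks; scipy's friedmanchisquare ties
    # handling matches, but it rejects the all-tied case we allow
    ranks = np.apply_along_axis(sps.rankdata, 1, block_scores)
    rbar = ranks.mean(axis=0)
    ssq = n * np.sum((rbar - (k + 1) / 2.0) ** 2)
    # tie correction
    denom = 0.0
    for row in block_scores:
        _, counts = np.unique(row, return_counts=True)
        denom += np.sum(counts**3 - counts)
    correction = 1.0 - denom / (n * k * (k * k - 1))
    if correction <= 0:  # every row fully tied
        return 0.0, 1.0
    chi2 = 12.0 * ssq / (k * (k + 1)) / correction
    return float(chi2), float(sps.chi2.sf(chi2, k - 1))


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test with normal approximation.

    Zero differences are dropped; Z carries the sign of the median
    difference direction (negative when x tends below y). Errors when all
    differences are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; test undefined")
    # alternative="greater" makes scipy report the signed z of W+ (the
    # two-sided call uses min(W+, W-) and loses direction)
    res = sps.wilcoxon(x, y, zero_method="wilcox", method="approx",
                       correction=False, alternative="greater")
    z = float(res.zstatistic)
    return z, float(2.0 * sps.norm.sf(abs(z)))


def binomial_above_chance(k: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= k | n, p0)."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(sps.binom.sf(k - 1, n, p0))


def cohort_above_chance(pct_correct: np.ndarray, chance: float = 50.0,
                        p0: float = 0.5) -> tuple[int, float]:
    """Cohort-level above-chance test.

    Counts subjects whose accuracy exceeds ``chance`` percent and returns
    that count with the exact binomial upper-tail probability of seeing at
    least as many under per-subject success probability ``p0``. This is
    the cohort reading of the "above chance" binomial test; the per-subject
    reading is :func:`binomial_above_chance` on trial counts.
    """
    pct_correct = np.asarray(pct_correct, dtype=float)
    k = int((pct_correct > chance).sum())
    return k, binomial_above_chance(k, len(pct_correct), p0)
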