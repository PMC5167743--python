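"""Cross-task statistics: outlier screening, one-tailed Spearman
correlations with Bonferroni correction, and simple mediation.

The mediation model is the standard three-variable setup: independent X,
mediator M, outcome Y with OLS paths

    M = i₁ + a·X,      Y = i₂ + c′·X + b·M,      Y = i₃ + c·X,

indirect effect a·b (= c − c′ for complete data), a bias-corrected
percentile bootstrap interval over case resamples, the Sobel
normal-approximation test Z = a·b / √(b²·SE_a² + a²·SE_b²), and the κ²
effect size of Preacher & Kelley — the indirect effect relative to the
largest same-sign indirect effect attainable while holding the observed
variances and the X–Y covariance fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "MediationResult",
    "flag_outliers",
    "spearman_one_tailed",
    "mediate",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    r_squared: float
    p_one_tailed: float
    p_bonferroni: float
    n: int
    bonferroni_m: int
    direction: str


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    boot_ci: tuple[float, float]
    sobel_z: float
    sobel_p: float
    kappa_sq: float
    n: int
    n_boot: int
    seed: int


def flag_outliers(values, threshold: float = 2.0) -> np.ndarray:
    """Boolean mask of values whose |z| meets ``threshold``.

    z-scores use the sample mean and sd (ddof=1) of the full vector; a
    zero-variance vector yields an empty mask.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values for an outlier screen")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(len(values), dtype=bool)
    z = np.abs(values - values.mean()) / sd
    return z >= threshold


def spearman_one_tailed(
    x, y, direction: str = "positive", m_tests: int = 1
) -> CorrelationResult:
    """One-tailed Spearman correlation with Bonferroni adjustment.

    Midrank rho with the t approximation for the tail probability in the
    hypothesized direction; the adjusted p is min(1, m·p).
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be positive|negative, got {direction!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a Spearman correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho = float(sps.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        p = 0.0 if (rho > 0) == (direction == "positive") else 1.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p_upper = float(sps.t.sf(t, n - 2))
        p = p_upper if direction == "positive" else 1.0 - p_upper
    return CorrelationResult(
        rho=rho,
        r_squared=rho * rho,
        p_one_tailed=p,
        p_bonferroni=min(1.0, m_tests * p),
        n=n,
        bonferroni_m=m_tests,
        direction=direction,
    )


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS with intercept; returns (coef_without_intercept, se)."""
    Xd = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, Xd).fit()
    return fit.params[1:], fit.bse[1:]


def _boot_indirect(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                   n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized a·b over case-resampled datasets (closed-form OLS)."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    a = sxm / sxx
    det = sxx * smm - sxm * sxm
    b = (sxx * smy - sxm * sxy) / det
    return a * b


def _bc_interval(boot: np.ndarray, estimate: float, level: float) -> tuple[float, float]:
    """Bias-corrected (non-accelerated) percentile interval."""
    prop = np.mean(boot < estimate)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1.0 - 1.0 / (len(boot) + 1))
    z0 = sps.norm.ppf(prop)
    alpha = (1.0 - level) / 2.0
    zlo, zhi = sps.norm.ppf(alpha), sps.norm.ppf(1.0 - alpha)
    plo = sps.norm.cdf(2 * z0 + zlo)
    phi = sps.norm.cdf(2 * z0 + zhi)
    lo, hi = np.quantile(boot, [plo, phi])
    return float(lo), float(hi)


def _kappa_squared(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                   a: float, b: float) -> float:
    """Preacher–Kelley κ²: the indirect effect relative to its maximum.

    Each path is bounded separately by positive semi-definiteness of the
    (X, M, Y) correlation matrix with the other two observed correlations
    held fixed: r_XM may range over r_XY·r_MY ± √((1−r_XY²)(1−r_MY²)),
    which bounds a = r_XM·s_M/s_X, and the partial coefficient b attains
    |b|_max = √((1−r_XY²)/(1−r_XM²))·s_Y/s_M at the corresponding r_MY
    limit. κ² = |ab| / (|a|_max·|b|_max) ∈ [0, 1].
    """
    sx, sm_, sy = (np.std(v, ddof=1) for v in (x, m, y))
    r_xm = float(np.corrcoef(x, m)[0, 1])
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_my = float(np.corrcoef(m, y)[0, 1])
    ab = a * b
    if ab == 0:
        return 0.0
    root = np.sqrt(max((1 - r_xy**2) * (1 - r_my**2), 0.0))
    lo, hi = r_xy * r_my - root, r_xy * r_my + root
    r_xm_max = hi if a > 0 else lo  # same-sign extreme of the a path
    a_max = abs(r_xm_max) * sm_ / sx
    b_max = np.sqrt(max(1 - r_xy**2, 0.0) / max(1 - r_xm**2, 1e-12)) * sy / sm_
    denom = a_max * b_max
    if denom == 0:
        return float("nan")
    return float(min(abs(ab) / denom, 1.0))


def mediate(x, m, y, n_boot: int = 5000, seed: int = 0,
            level: float = 0.95) -> MediationResult:
    """Simple mediation of the X → Y effect through M (see module docstring)."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal length")
    n = len(x)
    if n < 10:
        raise ValueError("mediation requires n >= 10")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(m)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values are not allowed")
    if np.var(x) == 0 or np.var(m) == 0:
        raise ValueError("singular design: constant predictor or mediator")
    if abs(np.corrcoef(x, m)[0, 1]) > 1 - 1e-12:
        raise ValueError("singular design: mediator collinear with predictor")

    (a,), (se_a,) = _ols(m, x[:, None])
    coefs, ses = _ols(y, np.column_stack([x, m]))
    c_prime, b = float(coefs[0]), float(coefs[1])
    se_b = float(ses[1])
    (c,), _ = _ols(y, x[:, None])
    a, c = float(a), float(c)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boot = _boot_indirect(x, m, y, n_boot, rng)
    ci = _bc_interval(boot, indirect, level)

    sobel_se = np.sqrt(b * b * se_a**2 + a * a * se_b**2)
    sobel_z = indirect / sobel_se if sobel_se > 0 else float("nan")
    sobel_p = 2.0 * float(sps.norm.sf(abs(sobel_z))) if np.isfinite(sobel_z) else float("nan")

    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=float(indirect),
        boot_ci=ci, sobel_z=float(sobel_z), sobel_p=sobel_p,
        kappa_sq=_kappa_squared(x, m, y, a, b),
        n=n, n_boot=n_boot, seed=seed,
    )
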