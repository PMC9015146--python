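"""Tie-aware Spearman correlation and the equality-of-correlations test.

Spearman's rho is the Pearson correlation of midranks.  For the small group
sizes typical of per-timepoint graft comparisons (n <= 10) the two-sided
p-value is computed by full enumeration of the permutation null; for larger
samples the usual t approximation on n - 2 degrees of freedom is used.
Confidence intervals come from the Fisher z transform with standard error
1 / sqrt(n - 3).

The heterogeneity test asks whether k independent correlation coefficients
(e.g. the per-timepoint rho between HV index and pressure gradient) could
share a common population value: each rho is mapped to z = atanh(rho),
weighted by n - 3, and the weighted sum of squared deviations from the
pooled z is referred to a chi-squared distribution on k - 1 degrees of
freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "HeterogeneityResult",
    "spearman",
    "fisher_ci",
    "correlation_heterogeneity",
]

#: Largest n for which the exact permutation p-value is used by default.
EXACT_P_MAX_N = 10


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with confidence interval for one variable pair."""

    rho: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    label: str = ""


@dataclass(frozen=True)
class HeterogeneityResult:
    """Chi-squared test of equality of k independent correlations."""

    chi2: float
    df: int
    p: float
    pooled_z: float
    per_group: tuple = field(default_factory=tuple)  # (rho, n, z, weight)

    @property
    def pooled_rho(self) -> float:
        return math.tanh(self.pooled_z)


# ---------------------------------------------------------------------------
# exact permutation null for small n

_PERM_CACHE: dict[int, np.ndarray] = {}


def _permutation_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n), built iteratively (int8, n <= 10)."""
    if n in _PERM_CACHE:
        return _PERM_CACHE[n]
    perms = np.zeros((1, 1), dtype=np.int8)
    for m in range(2, n + 1):
        k = perms.shape[0]
        out = np.empty((k * m, m), dtype=np.int8)
        for pos in range(m):
            block = out[pos * k:(pos + 1) * k]
            block[:, :pos] = perms[:, :pos]
            block[:, pos] = m - 1
            block[:, pos + 1:] = perms[:, pos:]
        perms = out
    _PERM_CACHE[n] = perms
    return perms


def _exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: share of permutations with |rho*| >= |rho_obs|."""
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    perms = _permutation_matrix(n)
    total = perms.shape[0]
    count = 0
    threshold = abs(rho_obs) * denom - 1e-9 * denom
    chunk = 200_000
    for start in range(0, total, chunk):
        block = perms[start:start + chunk]
        stats_ = yc[block] @ xc
        count += int(np.count_nonzero(np.abs(stats_) >= threshold))
    return count / total


# ---------------------------------------------------------------------------


def spearman(x, y, method: str = "auto", label: str = "",
             ci_level: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation with p-value and Fisher-z CI.

    Parameters
    ----------
    x, y : array-like
        Paired observations, equal length n >= 4, finite.
    method : {"auto", "exact", "approx"}
        "exact" enumerates all n! rank permutations (n <= 10); "approx" uses
        the t approximation on n - 2 df; "auto" picks "exact" for n <= 10.
    label : str
        Free-text tag (variable pair / group) carried into the result.

    Notes
    -----
    Ties receive average ranks.  Zero rank variance in either variable makes
    the correlation undefined and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")

    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("correlation undefined: zero variance in ranks")

    rho = float(np.corrcoef(xr, yr)[0, 1])
    rho = max(-1.0, min(1.0, rho))

    if method == "auto":
        method = "exact" if n <= EXACT_P_MAX_N else "approx"
    if method == "exact":
        if n > 12:
            raise ValueError("exact permutation p is limited to n <= 12")
        p = _exact_p(xr, yr, rho)
    elif method == "approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    ci_low, ci_high = fisher_ci(rho, n, level=ci_level)
    return CorrelationResult(rho=rho, n=n, ci_low=ci_low, ci_high=ci_high,
                             p=p, label=label)


def fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    ``tanh(atanh(rho) +/- z_level / sqrt(n - 3))``.  At |rho| = 1 the
    interval degenerates to (rho, rho) with a warning.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 for a Fisher-z interval, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if abs(rho) >= 1.0:
        warnings.warn("|rho| = 1: degenerate confidence interval",
                      stacklevel=2)
        return (float(rho), float(rho))
    z = math.atanh(rho)
    half = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def correlation_heterogeneity(rhos, ns) -> HeterogeneityResult:
    """Test equality of k independent correlation coefficients.

    Parameters
    ----------
    rhos : array-like
        Correlation coefficients, each strictly inside (-1, 1).
    ns : array-like
        Per-group sample sizes, each >= 4 (Fisher weights are n - 3).

    Returns
    -------
    HeterogeneityResult
        chi2 = sum w_i (z_i - z_bar)^2 with w_i = n_i - 3 and
        z_bar = sum w_i z_i / sum w_i, referred to chi-squared on k - 1 df.
    """
    rhos = np.asarray(rhos, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if rhos.shape != ns.shape or rhos.ndim != 1:
        raise ValueError("rhos and ns must be equal-length 1-d arrays")
    k = len(rhos)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns <= 3):
        raise ValueError("every group needs n >= 4 (weights are n - 3)")
    if np.any(np.abs(rhos) >= 1.0):
        raise ValueError("|rho| must be < 1 for the Fisher z transform")

    z = np.arctanh(rhos)
    w = ns - 3.0
    z_bar = float(np.sum(w * z) / np.sum(w))
    chi2 = float(np.sum(w * (z - z_bar) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    per_group = tuple(
        (float(r), int(n), float(zi), float(wi))
        for r, n, zi, wi in zip(rhos, ns, z, w)
    )
    return HeterogeneityResult(chi2=chi2, df=df, p=p, pooled_z=z_bar,
                               per_group=per_group)
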