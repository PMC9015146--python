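"""Nonparametric group comparisons: Kruskal-Wallis, Steel-Dwass, Wilcoxon.

The per-timepoint graft comparisons are rank-based throughout: a
tie-corrected Kruskal-Wallis test across all timepoints, the Steel-Dwass
all-pairs posthoc (familywise control through the studentized-range
distribution with infinite degrees of freedom), and the two-sample Wilcoxon
rank-sum test for the two-group assay tables.  A normality screen (moment
coefficients of skewness/kurtosis plus Shapiro-Wilk) documents why the
rank-based track is taken.

Steel-Dwass details: each pair of groups is ranked jointly (midranks), the
rank sum of the first group is standardized by its permutation mean and
tie-corrected variance, and sqrt(2)|t| is referred to the studentized range
q_{k,inf} for k groups.  A permutation mode replaces that reference with a
max-T resampling null: pooled group labels are permuted, every pairwise
statistic is recomputed, and the null distribution of the *maximum*
sqrt(2)|t*| over pairs calibrates each observed pair, which reproduces the
familywise character of the asymptotic reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "KWResult",
    "PosthocPair",
    "NormalityScreen",
    "kruskal_wallis",
    "steel_dwass",
    "wilcoxon_rank_sum",
    "normality_screen",
    "studentized_range_sf",
    "significance_stars",
]


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal-Wallis statistic with chi-squared p-value."""

    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class PosthocPair:
    """One Steel-Dwass pairwise comparison."""

    group_a: str
    group_b: str
    t_stat: float
    p: float
    method: str


@dataclass(frozen=True)
class NormalityScreen:
    """Moment coefficients and Shapiro-Wilk screen for one sample."""

    skewness: float
    excess_kurtosis: float
    shapiro_w: float | None
    shapiro_p: float | None
    n: int


def _clean_groups(groups, min_size: int) -> list[np.ndarray]:
    out = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.ndim != 1 or len(a) < min_size:
            raise ValueError(f"group {i} needs at least {min_size} values")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {i} contains non-finite values")
        out.append(a)
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def kruskal_wallis(groups) -> KWResult:
    """Kruskal-Wallis H test with tie correction.

    ``groups`` is a sequence of 1-d samples (k >= 2, total N >= 3).  All
    pooled values identical makes the tie-correction denominator zero and
    raises ``ValueError``.
    """
    gs = _clean_groups(groups, min_size=1)
    if sum(len(g) for g in gs) < 3:
        raise ValueError("need a total of at least 3 observations")
    if np.ptp(np.concatenate(gs)) == 0:
        raise ValueError(
            "degenerate data for Kruskal-Wallis: all pooled values identical "
            "(tie-correction denominator is zero)")
    H, p = stats.kruskal(*gs)
    return KWResult(H=float(H), df=len(gs) - 1, p=float(p),
                    group_sizes=tuple(len(g) for g in gs))


# ---------------------------------------------------------------------------
# studentized range with infinite degrees of freedom


def studentized_range_sf(q: float, k: int) -> float:
    """Upper tail of the studentized range q_{k,inf}.

    ``P(q_{k,inf} >= q)`` for the range of k iid standard normals, computed
    by numerical integration of
    ``cdf(q) = k * int phi(z) * (Phi(z) - Phi(z - q))**(k-1) dz``.
    For k = 2 this reduces to the two-sided normal tail of q / sqrt(2).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if q <= 0:
        return 1.0
    if k == 2:
        return 2.0 * float(stats.norm.sf(q / math.sqrt(2.0)))

    def integrand(z):
        return stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - q)) ** (k - 1)

    cdf, _ = integrate.quad(integrand, -9.0, 9.0, limit=200)
    cdf *= k
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def _pair_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized joint-midrank statistic for one group pair.

    The tie-corrected null variance of the rank sum equals the variance of
    sampling n_a midranks without replacement from the pooled midranks:
    ``n_a * n_b / (N - 1) * mean((r - r_bar)^2)``, which reduces to
    ``n_a n_b (N+1)/12 * (1 - sum(t^3 - t)/(N^3 - N))`` for tie groups t.
    """
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = float(ranks[:na].sum())
    N = na + nb
    expect = na * (N + 1) / 2.0
    var = na * nb / (N - 1) * float(np.mean((ranks - (N + 1) / 2.0) ** 2))
    if var <= 0:
        raise ValueError("degenerate pair: all pooled values identical")
    return (ra - expect) / math.sqrt(var)


def _pair_stats_resampled(values: np.ndarray, na: int, nb: int,
                          perm_cols: np.ndarray) -> np.ndarray:
    """Vectorized pair statistics for many resampled label assignments.

    ``perm_cols`` is an (R, na + nb) integer array of indices into ``values``
    selecting, per resample, the observations assigned to this pair.
    """
    sub = values[perm_cols]                      # (R, na+nb)
    ranks = stats.rankdata(sub, axis=1)
    ra = ranks[:, :na].sum(axis=1)
    N = na + nb
    expect = na * (N + 1) / 2.0
    var = na * nb / (N - 1) * np.mean((ranks - (N + 1) / 2.0) ** 2, axis=1)
    var = np.where(var > 0, var, np.nan)
    return (ra - expect) / np.sqrt(var)


def steel_dwass(groups, labels=None, method: str = "asymptotic",
                n_resamples: int = 100_000, seed: int | None = None
                ) -> list[PosthocPair]:
    """Steel-Dwass all-pairs nonparametric comparison.

    Parameters
    ----------
    groups : sequence of 1-d samples
        k >= 2 groups, each of size >= 2.
    labels : sequence of str, optional
        Group names; defaults to ``g0, g1, ...``.
    method : {"asymptotic", "permutation"}
        "asymptotic" refers sqrt(2)|t| to the studentized range q_{k,inf};
        "permutation" calibrates against the resampled null of the maximum
        pairwise statistic (max-T), preserving familywise control.
    n_resamples, seed
        Permutation-mode Monte Carlo size and RNG seed.
    """
    gs = _clean_groups(groups, min_size=2)
    k = len(gs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    labels = [str(l) for l in labels]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")

    pairs = list(itertools.combinations(range(k), 2))
    t_obs = {(i, j): _pair_stat(gs[i], gs[j]) for i, j in pairs}

    if method == "asymptotic":
        return [
            PosthocPair(labels[i], labels[j], t_obs[(i, j)],
                        studentized_range_sf(math.sqrt(2.0) * abs(t_obs[(i, j)]), k),
                        "asymptotic")
            for i, j in pairs
        ]
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(gs)
    N = len(pooled)
    offsets = np.cumsum([0] + [len(g) for g in gs])
    # R random permutations of observation indices
    perm = np.argsort(rng.random((n_resamples, N)), axis=1)
    max_stat = np.zeros(n_resamples)
    for i, j in pairs:
        cols = np.concatenate([
            np.arange(offsets[i], offsets[i + 1]),
            np.arange(offsets[j], offsets[j + 1]),
        ])
        t_null = _pair_stats_resampled(pooled, len(gs[i]), len(gs[j]),
                                       perm[:, cols])
        np.fmax(max_stat, math.sqrt(2.0) * np.abs(t_null), out=max_stat)

    out = []
    for i, j in pairs:
        q_obs = math.sqrt(2.0) * abs(t_obs[(i, j)])
        p = float(np.mean(max_stat >= q_obs - 1e-12))
        out.append(PosthocPair(labels[i], labels[j], t_obs[(i, j)], p,
                               "permutation"))
    return out


# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p).

    Exact enumeration of all C(N, n_x) rank assignments is used when
    n_x + n_y <= 12 (ties handled through midranks); otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be nonempty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    nx, ny = len(x), len(y)
    N = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:nx].sum())
    expect = nx * (N + 1) / 2.0

    if method == "auto":
        method = "exact" if N <= 12 else "approx"

    if method == "exact":
        dev_obs = abs(W - expect)
        count = 0
        total = 0
        for combo in itertools.combinations(range(N), nx):
            w = ranks[list(combo)].sum()
            if abs(w - expect) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return W, count / total
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")

    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts ** 3 - counts))
    var = nx * ny * (N + 1) / 12.0 * (1.0 - tie / (N ** 3 - N))
    if var <= 0:
        raise ValueError("degenerate data: all pooled values identical")
    dev = abs(W - expect) - 0.5  # continuity correction
    z = max(dev, 0.0) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(z))
    return W, min(1.0, p)


def normality_screen(x) -> NormalityScreen:
    """Skewness, excess kurtosis and Shapiro-Wilk for one sample.

    Moment coefficients need n >= 3; Shapiro-Wilk is reported for n >= 8
    (``None`` below that).  A constant sample has undefined moments and
    raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d sample with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: moments undefined")
    g1 = float(stats.skew(x, bias=True))
    g2 = float(stats.kurtosis(x, fisher=True, bias=True))
    if len(x) >= 8:
        w, p = stats.shapiro(x)
        return NormalityScreen(g1, g2, float(w), float(p), len(x))
    return NormalityScreen(g1, g2, None, None, len(x))


def significance_stars(p: float) -> str:
    """Annotation stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
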