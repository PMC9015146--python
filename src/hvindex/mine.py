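"""MINE-family statistics: characteristic matrix, MIC, MAS, MCN, MIC-R2, TIC.

The maximal-information framework scores a bivariate sample against every
k x l grid with k * l below a sample-size-dependent bound B(n) = n^alpha.
For each grid shape the mutual information of the induced cell counts is
maximized over cut placements and normalized by log2(min(k, l)), giving the
characteristic matrix M.  Summaries:

* MIC     — max of M over admissible shapes (strength of association);
* MAS     — max |M[k,l] - M[l,k]| (deviation from monotonicity);
* MCN     — log2(k*l) of the coarsest grid attaining the maximum
            (complexity of the relationship);
* MIC-R2  — MIC minus the squared Pearson correlation (nonlinearity);
* TIC     — sum of M over all admissible shapes (total information).

Two search modes are provided.  The exhaustive mode enumerates every cut
placement on both axes and is exact; it is the default for n <= 12 where it
is cheap.  The heuristic mode is the standard equipartition-plus-dynamic-
programming search: one axis is equipartitioned, the other axis' cuts are
optimized by dynamic programming over at most c*k "superclumps", and both
orientations are taken.  B(n) is floored at 4 so the 2 x 2 grid is always
admissible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "MineParams",
    "MineResult",
    "grid_bound",
    "admissible_shapes",
    "characteristic_matrix",
    "mine_stats",
]

#: Largest n at which method="auto" uses the exhaustive (exact) search.
EXHAUSTIVE_MAX_N = 12


@dataclass(frozen=True)
class MineParams:
    """Search parameters for the characteristic-matrix computation.

    alpha : grid-size exponent, B(n) = max(n**alpha, 4); 0 < alpha <= 1.
    c     : clump factor; the optimized axis is pre-partitioned into at most
            c * k superclumps before dynamic programming.
    eps_mcn : tolerance for MCN; cells with M >= (1 - eps_mcn) * MIC count
            as attaining the maximum.
    """

    alpha: float = 0.6
    c: float = 15.0
    eps_mcn: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.c < 1.0:
            raise ValueError("clump factor c must be >= 1")
        if not 0.0 <= self.eps_mcn < 1.0:
            raise ValueError("eps_mcn must lie in [0, 1)")


@dataclass(frozen=True)
class MineResult:
    """MINE summaries plus the characteristic matrix they derive from."""

    mic: float
    mas: float
    mcn: float
    mic_r2: float
    tic: float
    char_matrix: dict = field(default_factory=dict)  # {(k, l): M}
    n: int = 0
    params: MineParams = field(default_factory=MineParams)


def grid_bound(n: int, alpha: float = 0.6) -> float:
    """Admissible grid bound B(n) = max(n**alpha, 4)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return max(float(n) ** alpha, 4.0)


def admissible_shapes(n: int, alpha: float = 0.6) -> list[tuple[int, int]]:
    """All (k, l) with k, l >= 2 and k * l <= B(n), in row-major order."""
    B = grid_bound(n, alpha)
    out = []
    for k in range(2, int(B // 2) + 1):
        for l in range(2, int(B // k) + 1):
            if k * l <= B:
                out.append((k, l))
    return out


# ---------------------------------------------------------------------------
# shared helpers


def _mutual_information_bits(counts: np.ndarray) -> float:
    """Mutual information (bits) of a 2-d contingency table."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _cut_positions(values: np.ndarray) -> np.ndarray:
    """Candidate cut points: midpoints between consecutive distinct values."""
    distinct = np.unique(values)
    return (distinct[:-1] + distinct[1:]) / 2.0


def _best_mi_exhaustive(x: np.ndarray, y: np.ndarray, k: int, l: int) -> float:
    """Exact max mutual information (bits) over all k x l grids."""
    xcuts = _cut_positions(x)
    ycuts = _cut_positions(y)
    if len(xcuts) < k - 1 or len(ycuts) < l - 1:
        # fewer distinct values than bins: fall back to the finest partition
        xcombos = [tuple(xcuts)] if len(xcuts) else [()]
        ycombos = [tuple(ycuts)] if len(ycuts) else [()]
    else:
        xcombos = itertools.combinations(xcuts, k - 1)
        ycombos = list(itertools.combinations(ycuts, l - 1))
    best = 0.0
    for xc in xcombos:
        xbin = np.searchsorted(np.asarray(xc), x)
        for yc in ycombos:
            ybin = np.searchsorted(np.asarray(yc), y)
            counts = np.zeros((k, l))
            np.add.at(counts, (xbin, ybin), 1.0)
            mi = _mutual_information_bits(counts)
            if mi > best:
                best = mi
    return best


# ---------------------------------------------------------------------------
# heuristic search (equipartition + dynamic programming)


def _equipartition_labels(sorted_vals: np.ndarray, l: int) -> np.ndarray:
    """Greedy balanced assignment of sorted values into at most l bins.

    Tied values always share a bin.  Returns an integer label per position
    of the sorted array.
    """
    n = len(sorted_vals)
    labels = np.empty(n, dtype=np.int64)
    desired = n / l
    row = 0
    in_row = 0
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        size = j - i
        if (in_row != 0 and row < l - 1
                and abs(in_row + size - desired) >= abs(in_row - desired)):
            row += 1
            in_row = 0
            desired = (n - i) / (l - row)
        labels[i:j] = row
        in_row += size
        i = j
    return labels


def _superclump_boundaries(sorted_vals: np.ndarray, m_max: int) -> np.ndarray:
    """Cumulative point counts at superclump edges (tied values together)."""
    n = len(sorted_vals)
    change = np.flatnonzero(sorted_vals[1:] != sorted_vals[:-1]) + 1
    edges = np.concatenate([[0], change, [n]])  # tie-block boundaries
    if len(edges) - 1 <= m_max:
        return edges
    labels = _equipartition_labels(
        np.repeat(np.arange(len(edges) - 1), np.diff(edges)), m_max)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    return np.concatenate([[0], change, [n]])


def _optimize_axis(rows: np.ndarray, n_rows: int, boundaries: np.ndarray,
                   kmax: int) -> np.ndarray:
    """Max mutual information (bits) for 2..kmax bins on the free axis.

    ``rows`` are fixed-axis bin labels per point, in sorted order of the
    free axis; ``boundaries`` are superclump edges (cumulative counts).
    Returns an array I[k] (index 0 -> k=2) maximized over <= k bins.
    """
    n = len(rows)
    m = len(boundaries) - 1
    # cumulative row counts at each boundary
    C = np.zeros((m + 1, n_rows))
    np.add.at(C, (np.searchsorted(boundaries, np.arange(n), side="right"),
                  rows), 1.0)
    C = np.cumsum(C, axis=0)
    cum_n = C.sum(axis=1)

    # cost[s, t]: n * H(rows | points in clumps s..t) contribution, nats
    NT = cum_n[None, :] - cum_n[:, None]
    S = np.zeros_like(NT)
    for q in range(n_rows):
        D = C[None, :, q] - C[:, None, q]
        S += xlogy(D, D)
    cost = xlogy(NT, NT) - S
    cost[np.tril_indices(m + 1)] = np.inf  # only s < t is a valid bin

    row_tot = C[-1]
    h_rows = float(xlogy(cum_n[-1], cum_n[-1]) - np.sum(xlogy(row_tot, row_tot))) / n

    kmax = min(kmax, m)
    out = np.zeros(max(kmax - 1, 0))
    if kmax < 2:
        return out
    f = cost[0].copy()  # one bin over clumps (0, t]
    best = np.inf
    for x in range(2, kmax + 1):
        f = np.min(f[:, None] + cost, axis=0)
        best = min(best, f[m])
        i_nats = h_rows - best / n
        out[x - 2] = max(0.0, i_nats / math.log(2.0))
    return out


def _heuristic_matrix(x: np.ndarray, y: np.ndarray,
                      params: MineParams) -> dict:
    n = len(x)
    B = grid_bound(n, params.alpha)
    shapes = admissible_shapes(n, params.alpha)
    M = {shape: 0.0 for shape in shapes}

    for free, fixed, transpose in ((x, y, False), (y, x, True)):
        # fixed axis equipartitioned into l bins; free-axis cuts optimized
        order = np.argsort(free, kind="stable")
        free_sorted = free[order]
        fixed_sorted = fixed[order]
        for l in range(2, int(B // 2) + 1):
            kmax = int(B // l)
            if kmax < 2:
                continue
            fixed_order = np.argsort(fixed_sorted, kind="stable")
            labels_sorted = _equipartition_labels(fixed_sorted[fixed_order], l)
            rows = np.empty(n, dtype=np.int64)
            rows[fixed_order] = labels_sorted
            n_rows = int(rows.max()) + 1
            if n_rows < 2:
                continue
            boundaries = _superclump_boundaries(
                free_sorted, max(2, int(params.c * kmax)))
            info = _optimize_axis(rows, n_rows, boundaries, kmax)
            for idx, k in enumerate(range(2, 2 + len(info))):
                if k * l > B:
                    break
                shape = (l, k) if transpose else (k, l)
                val = info[idx] / math.log2(min(k, l))
                if val > M[shape]:
                    M[shape] = min(1.0, val)
    return M


def _exhaustive_matrix(x: np.ndarray, y: np.ndarray,
                       params: MineParams) -> dict:
    M = {}
    for k, l in admissible_shapes(len(x), params.alpha):
        mi = _best_mi_exhaustive(x, y, k, l)
        M[(k, l)] = min(1.0, mi / math.log2(min(k, l)))
    return M


# ---------------------------------------------------------------------------


def characteristic_matrix(x, y, params: MineParams | None = None,
                          method: str = "auto") -> dict:
    """Normalized maximal-mutual-information matrix {(k, l): M} .

    Parameters
    ----------
    x, y : array-like
        Paired observations, equal length n >= 8, finite.
    params : MineParams
        Grid bound and search parameters.
    method : {"auto", "exhaustive", "heuristic"}
        "exhaustive" enumerates every cut placement (exact, small n);
        "heuristic" is the equipartition + dynamic-programming search run in
        both orientations; "auto" is exhaustive for n <= 12.

    A constant x or y has no information to resolve: the matrix is all
    zeros and a warning is emitted.
    """
    params = params or MineParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 8:
        raise ValueError(f"need n >= 8 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: characteristic matrix is all zeros",
                      stacklevel=2)
        return {shape: 0.0 for shape in admissible_shapes(n, params.alpha)}

    if method == "auto":
        method = "exhaustive" if n <= EXHAUSTIVE_MAX_N else "heuristic"
    if method == "exhaustive":
        return _exhaustive_matrix(x, y, params)
    if method == "heuristic":
        return _heuristic_matrix(x, y, params)
    raise ValueError(f"unknown method {method!r}")


def mine_stats(x, y, params: MineParams | None = None,
               method: str = "auto") -> MineResult:
    """All five MINE summaries for one variable pair."""
    params = params or MineParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    M = characteristic_matrix(x, y, params=params, method=method)

    mic = max(M.values())
    mas = max(abs(M[(k, l)] - M[(l, k)]) for (k, l) in M)
    if mic > 0:
        qualifying = [k * l for (k, l), v in M.items()
                      if v >= (1.0 - params.eps_mcn) * mic - 1e-12]
        mcn = math.log2(min(qualifying))
    else:
        mcn = math.log2(4.0)
    tic = float(sum(M.values()))

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    mic_r2 = mic - r * r

    return MineResult(mic=float(mic), mas=float(mas), mcn=float(mcn),
                      mic_r2=float(mic_r2), tic=tic, char_matrix=M,
                      n=len(x), params=params)
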