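"""Spearman correlation, Fisher-z intervals, equality-of-correlations test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hvindex import correlation_heterogeneity, fisher_ci, spearman


def _midranks(v):
    """Oracle midranks: sort-based, independent of scipy.stats.rankdata."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and v[order[j]] == v[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based positions
        i = j
    return ranks


def _pearson(a, b):
    a = a - np.mean(a)
    b = b - np.mean(b)
    return float(np.sum(a * b) / math.sqrt(np.sum(a * a) * np.sum(b * b)))


def rank_then_pearson(x, y):
    """Brute-force Spearman oracle: rank by sorting, then Pearson formula."""
    return _pearson(_midranks(x), _midranks(y))


def test_perfect_monotone_and_antitone():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)


def test_rho_matches_rank_then_pearson_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(4, 21))
        x = rng.random(n)
        y = rng.random(n)
        if rng.random() < 0.4:  # inject ties
            x = np.round(x, 1)
            y = np.round(y, 1)
        if np.ptp(_midranks(x)) == 0 or np.ptp(_midranks(y)) == 0:
            continue
        res = spearman(x, y, method="approx")
        assert res.rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)


def test_spearman_example_from_rank_oracle():
    x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
    res = spearman(x, y)
    assert res.rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)
    assert res.rho == pytest.approx(0.8)


def test_exact_p_matches_direct_enumeration(rng):
    for n, with_ties in ((6, False), (7, True)):
        x = rng.random(n)
        y = np.round(rng.random(n), 1) if with_ties else rng.random(n)
        if np.ptp(_midranks(y)) == 0:
            continue
        res = spearman(x, y, method="exact")
        xr, yr = _midranks(x), _midranks(y)
        rho_obs = abs(_pearson(xr, yr))
        count = total = 0
        for perm in itertools.permutations(range(n)):
            if abs(_pearson(xr, yr[list(perm)])) >= rho_obs - 1e-9:
                count += 1
            total += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)


def test_large_n_p_matches_t_approximation(rng):
    x, y = rng.random(25), rng.random(25)
    res = spearman(x, y)  # auto -> approx for n > 10
    rho_sp, p_sp = stats.spearmanr(x, y)
    assert res.rho == pytest.approx(rho_sp, abs=1e-12)
    assert res.p == pytest.approx(p_sp, abs=1e-10)


def test_monotone_transform_invariance(rng):
    x, y = rng.random(12), rng.random(12)
    base = spearman(x, y)
    trans = spearman(np.exp(3 * x), y ** 3 + 5 * y)
    assert trans.rho == pytest.approx(base.rho, abs=1e-12)
    assert trans.p == pytest.approx(base.p, abs=1e-12)


@pytest.mark.parametrize("x, y, exc", [
    ([1, 2, 3], [1, 2, 4], "n >= 4"),
    ([1, 1, 1, 1], [1, 2, 3, 4], "zero variance"),
    ([1, 2, 3, np.inf], [1, 2, 3, 4], "finite"),
])
def test_spearman_input_errors(x, y, exc):
    with pytest.raises(ValueError, match=exc):
        spearman(x, y)


# ---------------------------------------------------------------------------
# Fisher-z confidence intervals


def test_fisher_ci_symmetric_at_zero():
    lo, hi = fisher_ci(0.0, 52)
    assert lo == -hi
    assert hi == pytest.approx(math.tanh(1.959964 / 7.0), abs=1e-6)
    assert hi == pytest.approx(0.2735, abs=1e-3)  # tanh(0.28) to rounded z


def test_fisher_ci_pooled_study_scale():
    lo, hi = fisher_ci(0.718, 58)
    assert (lo, hi) == (pytest.approx(0.5644, abs=1e-4),
                        pytest.approx(0.8236, abs=1e-4))


def test_fisher_ci_width_decreases_with_n():
    widths = [np.diff(fisher_ci(0.5, n))[0] for n in (8, 16, 32, 64, 128)]
    assert np.all(np.diff(widths) < 0)


def test_fisher_ci_limits():
    # as the confidence level approaches 1 the interval approaches (-1, 1)
    lo, hi = fisher_ci(0.3, 4, level=1 - 1e-15)
    assert lo < -0.99 and hi > 0.99
    with pytest.warns(UserWarning):
        assert fisher_ci(1.0, 20) == (1.0, 1.0)


# ---------------------------------------------------------------------------
# equality of independent correlations

STUDY_NS = [10, 10, 10, 10, 10, 8]


def test_heterogeneity_reproduces_study_statistics():
    # per-timepoint correlations against pressure gradient, six groups
    h_hv = correlation_heterogeneity(
        [0.370, 0.709, 0.540, 0.794, 0.600, 0.786], STUDY_NS)
    assert h_hv.chi2 == pytest.approx(2.452, abs=0.01)
    assert h_hv.df == 5
    h_area = correlation_heterogeneity(
        [0.188, -0.636, -0.261, -0.503, -0.770, -0.905], STUDY_NS)
    assert h_area.chi2 == pytest.approx(10.59, abs=0.05)
    h_angle = correlation_heterogeneity(
        [0.285, 0.503, 0.903, 0.770, 0.455, 0.571], STUDY_NS)
    assert h_angle.chi2 == pytest.approx(6.580, abs=0.05)
    for h in (h_hv, h_area, h_angle):
        assert h.df == 5
        assert 0.0 < h.p < 1.0


def test_heterogeneity_zero_iff_equal_z(rng):
    assert correlation_heterogeneity([0.4, 0.4, 0.4], [10, 20, 8]).chi2 == 0.0
    for _ in range(10):
        rhos = np.round(rng.uniform(-0.9, 0.9, 4), 3)
        if len(set(rhos)) == 1:
            continue
        assert correlation_heterogeneity(rhos, [10] * 4).chi2 > 0.0


def test_heterogeneity_group_order_invariance(rng):
    rhos = [0.1, 0.5, -0.3, 0.7]
    ns = [8, 12, 20, 9]
    a = correlation_heterogeneity(rhos, ns)
    order = rng.permutation(4)
    b = correlation_heterogeneity(np.asarray(rhos)[order],
                                  np.asarray(ns)[order])
    assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
    assert a.pooled_z == pytest.approx(b.pooled_z, rel=1e-12)


def test_heterogeneity_pooled_z_is_weighted_mean():
    h = correlation_heterogeneity([0.2, 0.6], [13, 7])
    expected = (10 * math.atanh(0.2) + 4 * math.atanh(0.6)) / 14
    assert h.pooled_z == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("rhos, ns", [
    ([0.5], [10]),
    ([0.5, 0.4], [10, 3]),
    ([1.0, 0.4], [10, 10]),
])
def test_heterogeneity_input_errors(rhos, ns):
    with pytest.raises(ValueError):
        correlation_heterogeneity(rhos, ns)
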