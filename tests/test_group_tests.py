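"""Rank-based group comparisons and the normality screen."""

import numpy as np
import pytest
from scipy import stats

from hvindex import (kruskal_wallis, normality_screen, significance_stars,
                     steel_dwass, studentized_range_sf, wilcoxon_rank_sum)
from hvindex.group_tests import _pair_stat


def kruskal_oracle(groups):
    """Brute-force H: explicit midranks and the tie-corrected formula."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    i = 0
    while i < N:
        j = i
        while j < N and pooled[order[j]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    return h / (1.0 - tie / (N ** 3 - N))


def test_kruskal_hand_example():
    assert kruskal_wallis([[1, 2], [3, 4]]).H == pytest.approx(2.4)


def test_kruskal_identical_groups():
    res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert res.H == pytest.approx(0.0, abs=1e-12)
    assert res.df == 1


def test_kruskal_matches_rank_formula_oracle(rng):
    for _ in range(10):
        groups = [rng.integers(0, 8, 5).astype(float) for _ in range(3)]
        if np.ptp(np.concatenate(groups)) == 0:
            continue
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(kruskal_oracle(groups), abs=1e-10)
        assert res.p == pytest.approx(stats.chi2.sf(res.H, 2), abs=1e-12)


def test_kruskal_degenerate_data():
    with pytest.raises(ValueError, match="degenerate"):
        kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])


def test_kruskal_two_groups_equals_squared_wilcoxon(rng):
    # with k = 2 and no ties, H is the squared standardized rank-sum statistic
    x, y = rng.random(7), rng.random(9)
    t = _pair_stat(x, y)
    assert kruskal_wallis([x, y]).H == pytest.approx(t * t, abs=1e-9)


# ---------------------------------------------------------------------------
# Steel-Dwass


def test_studentized_range_tail_matches_scipy():
    for k in (2, 3, 6):
        for q in (1.0, 2.5, 3.5):
            assert studentized_range_sf(q, k) == pytest.approx(
                stats.studentized_range.sf(q, k, 1e7), rel=1e-4)
    assert studentized_range_sf(0.0, 3) == 1.0


def test_steel_dwass_identical_groups():
    pair = steel_dwass([[1, 2, 3, 4], [1, 2, 3, 4]])[0]
    assert pair.t_stat == pytest.approx(0.0)
    assert pair.p == pytest.approx(1.0)


def test_steel_dwass_two_groups_reduces_to_normal_tail(rng):
    x, y = rng.random(6), rng.random(7) + 0.4
    pair = steel_dwass([x, y])[0]
    assert pair.p == pytest.approx(2 * stats.norm.sf(abs(pair.t_stat)),
                                   rel=1e-10)


def test_steel_dwass_relabeling_symmetry(rng):
    groups = [rng.random(5), rng.random(5) + 0.2, rng.random(5) + 0.5]
    fwd = {(p.group_a, p.group_b): p.p
           for p in steel_dwass(groups, labels=["a", "b", "c"])}
    rev = {(p.group_a, p.group_b): p.p
           for p in steel_dwass(groups[::-1], labels=["c", "b", "a"])}
    for (a, b), p in fwd.items():
        assert rev[(b, a)] == pytest.approx(p, rel=1e-10)
        assert 0.0 <= p <= 1.0


def test_steel_dwass_permutation_converges_to_asymptotic(rng):
    # moderate n: the max-T permutation null approaches q_{k,inf}
    groups = [rng.normal(0, 1, 15), rng.normal(0.4, 1, 15),
              rng.normal(0.8, 1, 15)]
    asym = steel_dwass(groups, method="asymptotic")
    perm = steel_dwass(groups, method="permutation", n_resamples=40_000,
                       seed=5)
    for pa, pp in zip(asym, perm):
        assert pp.p == pytest.approx(pa.p, abs=0.04)


def test_steel_dwass_rejects_tiny_groups():
    with pytest.raises(ValueError):
        steel_dwass([[1.0], [2.0, 3.0]])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def test_wilcoxon_exact_examples():
    w, p = wilcoxon_rank_sum([1, 2], [3, 4])
    assert w == 3.0
    assert p == pytest.approx(1 / 3)
    _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_wilcoxon_exact_matches_scipy_without_ties(rng):
    for nx, ny in ((3, 4), (5, 5), (4, 6)):
        x, y = rng.random(nx), rng.random(ny)
        _, p = wilcoxon_rank_sum(x, y)
        sp = stats.mannwhitneyu(x, y, method="exact",
                                alternative="two-sided").pvalue
        assert p == pytest.approx(sp, abs=1e-12)


def test_wilcoxon_approximation_close_to_enumeration(rng):
    for _ in range(5):
        x, y = rng.random(8), rng.random(8) + rng.normal(0, 0.3)
        _, p_exact = wilcoxon_rank_sum(x, y, method="exact")
        _, p_approx = wilcoxon_rank_sum(x, y, method="approx")
        assert abs(p_exact - p_approx) <= 0.02


def test_wilcoxon_empty_group():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0, 2.0])


# ---------------------------------------------------------------------------
# normality screen


def test_normality_screen_symmetric_vector():
    s = normality_screen([-2, -1, 0, 1, 2])
    assert s.skewness == pytest.approx(0.0, abs=1e-12)
    assert s.shapiro_w is None  # n < 8: no Shapiro-Wilk


def test_normality_screen_affine_invariance(rng):
    x = rng.normal(size=20)
    a = normality_screen(x)
    b = normality_screen(3.5 * x - 7.0)
    assert b.skewness == pytest.approx(a.skewness, abs=1e-10)
    assert b.excess_kurtosis == pytest.approx(a.excess_kurtosis, abs=1e-10)
    assert b.shapiro_w == pytest.approx(a.shapiro_w, abs=1e-8)


def test_normality_screen_constant_vector():
    with pytest.raises(ValueError, match="constant"):
        normality_screen([2.0, 2.0, 2.0, 2.0])


def test_significance_stars():
    assert [significance_stars(p) for p in (0.2, 0.04, 0.009, 0.0005)] == \
        ["", "*", "**", "***"]
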