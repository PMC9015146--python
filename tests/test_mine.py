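"""MINE statistics: characteristic matrix, MIC/MAS/MCN/MIC-R2/TIC."""

import itertools
import math

import numpy as np
import pytest

from hvindex import (MineParams, admissible_shapes, characteristic_matrix,
                     grid_bound, mine_stats)


def _mi_bits(counts):
    """Oracle mutual information from a contingency table, direct formula."""
    n = counts.sum()
    out = 0.0
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j]
            if c > 0:
                out += (c / n) * math.log2(c * n / (rows[i] * cols[j]))
    return out


def char_matrix_oracle(x, y, params):
    """Brute force: every pair of cut-point sets on both axes, per shape."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd, yd = np.unique(x), np.unique(y)
    xcuts = (xd[:-1] + xd[1:]) / 2.0
    ycuts = (yd[:-1] + yd[1:]) / 2.0
    out = {}
    for k, l in admissible_shapes(len(x), params.alpha):
        best = 0.0
        xsets = (itertools.combinations(xcuts, k - 1)
                 if len(xcuts) >= k - 1 else [tuple(xcuts)])
        ysets = (list(itertools.combinations(ycuts, l - 1))
                 if len(ycuts) >= l - 1 else [tuple(ycuts)])
        for xc in xsets:
            xb = np.searchsorted(np.asarray(xc), x)
            for yc in ysets:
                yb = np.searchsorted(np.asarray(yc), y)
                counts = np.zeros((k, l))
                for xi, yi in zip(xb, yb):
                    counts[xi, yi] += 1
                best = max(best, _mi_bits(counts))
        out[(k, l)] = best / math.log2(min(k, l))
    return out


def test_grid_bound_floor():
    assert grid_bound(10) == 4.0          # n^0.6 < 4 is floored
    assert grid_bound(58) == pytest.approx(58 ** 0.6)
    assert (2, 2) in admissible_shapes(8)


def test_identity_saturates_two_by_two(rng):
    x = rng.random(16)
    M = characteristic_matrix(x, x, method="heuristic")
    assert M[(2, 2)] == pytest.approx(1.0, abs=1e-9)


def test_small_n_matches_exhaustive_oracle(rng):
    params = MineParams(alpha=1.0)
    datasets = [
        (rng.random(10), rng.random(10)),                 # independent
        (rng.random(10), None),                           # cubic function
        (np.round(rng.random(12), 1), np.round(rng.random(12), 1)),  # ties
    ]
    for x, y in datasets:
        if y is None:
            y = x ** 3
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        got = characteristic_matrix(x, y, params=params)  # auto -> exhaustive
        expected = char_matrix_oracle(x, y, params)
        assert got.keys() == expected.keys()
        for shape in expected:
            assert got[shape] == pytest.approx(
                min(1.0, expected[shape]), abs=1e-10), shape


def test_all_five_stats_match_oracle_at_n10(rng):
    params = MineParams(alpha=1.0)
    x, y = rng.random(10), rng.random(10)
    res = mine_stats(x, y, params=params)
    M = char_matrix_oracle(x, y, params)
    M = {s: min(1.0, v) for s, v in M.items()}
    mic = max(M.values())
    assert res.mic == pytest.approx(mic, abs=1e-10)
    assert res.mas == pytest.approx(
        max(abs(M[(k, l)] - M[(l, k)]) for k, l in M), abs=1e-10)
    assert res.mcn == pytest.approx(
        math.log2(min(k * l for (k, l), v in M.items()
                      if v >= mic - 1e-9)), abs=1e-10)
    assert res.tic == pytest.approx(sum(M.values()), abs=1e-10)
    r = np.corrcoef(x, y)[0, 1]
    assert res.mic_r2 == pytest.approx(mic - r * r, abs=1e-10)


def test_heuristic_matches_exhaustive_on_monotone_data(rng):
    # equipartition is optimal for noiseless monotone data: both search
    # modes saturate every admissible grid shape
    x = np.sort(rng.random(12))
    y = np.exp(2 * x)
    h = characteristic_matrix(x, y, method="heuristic")
    e = characteristic_matrix(x, y, method="exhaustive")
    for shape in e:
        assert h[shape] == pytest.approx(e[shape], abs=1e-9)


def test_monotone_saturation_and_linear_mic_r2(rng):
    x = rng.random(32)
    res = mine_stats(x, np.exp(3 * x), method="heuristic")
    assert res.mic == pytest.approx(1.0, abs=1e-9)
    assert res.mcn == pytest.approx(2.0)  # a 2x2 grid attains the max
    lin = mine_stats(x, 2 * x - 1, method="heuristic")
    assert lin.mic_r2 == pytest.approx(0.0, abs=1e-9)


def test_symmetry_and_invariance(rng):
    x, y = rng.random(40), rng.random(40)
    a = mine_stats(x, y, method="heuristic")
    b = mine_stats(y, x, method="heuristic")
    assert a.mic == pytest.approx(b.mic, abs=1e-12)
    # strictly increasing transforms change nothing (rank-based search)
    c = mine_stats(np.exp(x), y ** 3, method="heuristic")
    assert c.mic == pytest.approx(a.mic, abs=1e-12)
    assert c.tic == pytest.approx(a.tic, abs=1e-12)


def test_matrix_entries_are_normalized(rng):
    x = rng.random(58)
    y = 0.5 * x + 0.3 * rng.random(58)
    M = characteristic_matrix(x, y, method="heuristic")
    assert set(M) == set(admissible_shapes(58))
    for v in M.values():
        assert 0.0 <= v <= 1.0
    res = mine_stats(x, y, method="heuristic")
    assert res.mas <= res.mic
    assert res.mcn >= 2.0
    assert res.tic == pytest.approx(sum(M.values()), abs=1e-12)


def test_shuffling_destroys_association(rng):
    x = rng.random(30)
    y = np.sin(4 * x) + 0.05 * rng.normal(size=30)
    base = characteristic_matrix(x, y, method="heuristic")[(2, 2)]
    shuffled = []
    for _ in range(100):
        shuffled.append(characteristic_matrix(
            x, rng.permutation(y), method="heuristic")[(2, 2)])
    assert np.mean(shuffled) < base


def test_constant_input_warns_and_zeroes():
    with pytest.warns(UserWarning, match="constant"):
        M = characteristic_matrix(np.ones(10), np.arange(10.0))
    assert all(v == 0.0 for v in M.values())


def test_input_validation():
    with pytest.raises(ValueError, match="n >= 8"):
        characteristic_matrix([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        MineParams(alpha=1.5)
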