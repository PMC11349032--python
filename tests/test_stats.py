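"""Statistical kernels against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mindwander.stats import (
    bh_adjust,
    edge_correlations,
    partial_spearman,
    pearson_corr,
    rank_sum_test,
    spearman_corr,
)


# ---------------------------------------------------------------------------
# oracles


def oracle_spearman_rho(x, y):
    """Rank-transform then Pearson, written independently of the package."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def oracle_ranksum_exact_p(a, b):
    """Exhaustive enumeration of the two-sided rank-sum null (tie-free)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    stats = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        stats.append(ranks[list(comb)].sum())
    stats = np.asarray(stats)
    return np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12)


def oracle_bh(pvals):
    """Sorted step-up recursion: q_(i) = min(q_(i+1), p_(i) * m / i)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_matches_rank_pearson_with_ties(rng):
    x = rng.integers(1, 9, size=40).astype(float)
    y = rng.integers(1, 9, size=40).astype(float)
    res = spearman_corr(x, y)
    assert res.rho == pytest.approx(oracle_spearman_rho(x, y), abs=1e-12)


def test_spearman_large_n_p_matches_t_approximation(rng):
    x = rng.normal(size=60)
    y = x + rng.normal(size=60)
    res = spearman_corr(x, y)
    ref = sps.spearmanr(x, y)
    assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_small_n_exact_p_by_enumeration(rng):
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
    y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
    res = spearman_corr(x, y)
    # independent enumeration over permutations of y
    rhos = [
        oracle_spearman_rho(x, np.asarray(p))
        for p in itertools.permutations(y)
    ]
    p_exact = np.mean(np.abs(rhos) >= abs(res.rho) - 1e-12)
    assert res.p == pytest.approx(p_exact, abs=1e-12)


def test_spearman_perfect_monotone():
    x = np.arange(12, dtype=float)
    assert spearman_corr(x, x**3).rho == pytest.approx(1.0)
    assert spearman_corr(x, -x).rho == pytest.approx(-1.0)


def test_spearman_constant_input_undefined():
    res = spearman_corr(np.ones(10), np.arange(10.0))
    assert np.isnan(res.rho)


# ---------------------------------------------------------------------------
# partial Spearman


def test_partial_with_constant_control_equals_plain(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    plain = spearman_corr(x, y)
    partial = partial_spearman(x, y, np.full(30, 3.0))
    assert partial.rho == pytest.approx(plain.rho, abs=1e-12)


def test_partial_fully_explained_by_control(rng):
    x = rng.normal(size=200)
    y = 0.6 * x + rng.normal(size=200)
    res = partial_spearman(x, y, control=x)
    assert abs(res.rho) < 0.05


def test_partial_independent_control_close_to_plain(rng):
    n = 10_000
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    c = rng.normal(size=n)
    plain = spearman_corr(x, y)
    partial = partial_spearman(x, y, c)
    assert partial.rho == pytest.approx(plain.rho, abs=0.02)


def test_partial_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "x": rng.normal(size=50),
        "y": rng.normal(size=50),
        "c": rng.normal(size=50),
    })
    ref = pingouin.partial_corr(df, x="x", y="y", covar="c", method="spearman")
    res = partial_spearman(df["x"], df["y"], df["c"])
    assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)


# ---------------------------------------------------------------------------
# rank-sum


@pytest.mark.parametrize("n1,n2", [(4, 5), (6, 6), (3, 8)])
def test_ranksum_exact_small_samples(rng, n1, n2):
    a = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
    b = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), a)
    _, p = rank_sum_test(a, b)
    assert p == pytest.approx(oracle_ranksum_exact_p(a, b), abs=1e-12)


def test_ranksum_identical_groups_nonsignificant(rng):
    a = rng.normal(size=30)
    _, p = rank_sum_test(a, a.copy())
    assert p > 0.99


def test_ranksum_ties_match_corrected_normal(rng):
    a = rng.integers(1, 5, size=25).astype(float)
    b = rng.integers(2, 6, size=30).astype(float)
    _, p = rank_sum_test(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_matches_recursion_oracle(rng):
    p = rng.uniform(size=20)
    assert bh_adjust(p) == pytest.approx(oracle_bh(p), abs=1e-12)


def test_bh_equal_pvalues_identity():
    p = np.full(20, 0.01)
    assert bh_adjust(p) == pytest.approx(p, abs=1e-15)


def test_bh_adjusted_at_least_raw_and_reorder_invariant(rng):
    p = rng.uniform(size=15)
    q = bh_adjust(p)
    assert (q >= p - 1e-15).all()
    perm = rng.permutation(15)
    assert bh_adjust(p[perm]) == pytest.approx(q[perm], abs=1e-15)


# ---------------------------------------------------------------------------
# vectorised edge correlations


def test_edge_correlations_match_pearsonr_loop(rng):
    X = rng.normal(size=(15, 45))
    y = rng.normal(size=15)
    r, p = edge_correlations(X, y)
    for e in range(45):
        ref = sps.pearsonr(X[:, e], y)
        assert r[e] == pytest.approx(ref.statistic, abs=1e-10)
        assert p[e] == pytest.approx(ref.pvalue, rel=1e-8)


def test_edge_correlations_constant_feature_never_selected(rng):
    X = rng.normal(size=(12, 3))
    X[:, 1] = 2.5
    r, p = edge_correlations(X, rng.normal(size=12))
    assert r[1] == 0.0 and p[1] == 1.0


def test_pearson_constant_is_nan():
    assert np.isnan(pearson_corr(np.ones(5), np.arange(5.0)))
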