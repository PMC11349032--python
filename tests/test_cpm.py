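"""Connectome-based predictive modeling: selection, strength, CV, permutation."""

import numpy as np
import pytest

from mindwander.cpm import (
    CPM,
    EdgeMasks,
    bbs_cross_validate,
    bbs_fit_predict,
    fit_predict,
    network_strength,
    select_edges,
)


def make_signal_data(rng, n=80, E=200, n_pos=6, n_neg=6, noise=0.3):
    y = rng.normal(size=n)
    X = rng.normal(size=(n, E))
    for e in range(n_pos):
        X[:, e] = y + noise * rng.normal(size=n)
    for e in range(n_pos, n_pos + n_neg):
        X[:, e] = -y + noise * rng.normal(size=n)
    return X, y


# ---------------------------------------------------------------------------
# selection


def test_select_edges_signs(rng):
    y = rng.normal(size=30)
    X = rng.normal(size=(30, 5))
    X[:, 0] = y
    X[:, 3] = -y
    masks = select_edges(X, y)
    assert 0 in masks.positive and 3 in masks.negative


def test_select_edges_null_rate(rng):
    rates = []
    for _ in range(50):
        X = rng.normal(size=(100, 10_000))
        y = rng.normal(size=100)
        masks = select_edges(X, y)
        rates.append(masks.n_edges / 10_000)
    assert np.mean(rates) == pytest.approx(0.01, abs=0.003)


def test_select_edges_requires_varying_outcome(rng):
    with pytest.raises(ValueError):
        select_edges(rng.normal(size=(20, 5)), np.ones(20))


def test_masks_must_be_disjoint():
    with pytest.raises(ValueError):
        EdgeMasks(positive=[1, 2], negative=[2, 3])


# ---------------------------------------------------------------------------
# strength


def test_network_strength_arithmetic():
    masks = EdgeMasks(positive=[0, 1], negative=[2])
    X = np.array([[0.6, 0.4, 0.4, 9.9]])
    assert network_strength(X, masks)[0] == pytest.approx(0.6)
    single = EdgeMasks(positive=[1], negative=[])
    assert network_strength(np.array([[0.0, 0.3, 0.0, 0.0]]), single)[0] == 0.3


def test_network_strength_empty_masks_warn():
    with pytest.warns(UserWarning):
        s = network_strength(np.ones((4, 3)), EdgeMasks(positive=[], negative=[]))
    assert (s == 0).all()


# ---------------------------------------------------------------------------
# fold-level fit/predict


def test_fit_predict_recovers_affine_relationship(rng):
    # every informative edge is an exact copy of +-y and all others are
    # constant, so network strength is exactly affine in y
    y = rng.normal(size=50)
    X = np.zeros((50, 20))
    X[:, :6] = y[:, None]
    X[:, 6:12] = -y[:, None]
    preds = fit_predict(X[:40], y[:40], X[40:])
    assert preds == pytest.approx(y[40:], abs=1e-10)


def test_sign_convention_invariance_exact(rng):
    X, y = make_signal_data(rng)
    a = CPM(X, y, strength_convention="pos_minus_neg").cross_validate("loo")
    b = CPM(X, y, strength_convention="neg_minus_pos").cross_validate("loo")
    assert np.max(np.abs(a.predicted - b.predicted)) < 1e-10


def test_empty_mask_fallback_predicts_train_mean(rng):
    X = rng.normal(size=(40, 30))
    y = rng.normal(size=40)
    preds = fit_predict(X[:30], y[:30], X[30:], p_thresh=1e-12)
    assert preds == pytest.approx(np.full(10, y[:30].mean()))


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_deterministic_in_seed(rng):
    X, y = make_signal_data(rng)
    a = CPM(X, y).cross_validate("kfold", n_iterations=5, seed=3)
    b = CPM(X, y).cross_validate("kfold", n_iterations=5, seed=3)
    assert a.r == b.r
    assert np.array_equal(a.r_per_iteration, b.r_per_iteration)


def test_cv_folds_partition_trials(rng):
    X, y = make_signal_data(rng, n=50)
    cv = CPM(X, y).cross_validate("kfold", n_iterations=1, seed=0)
    covered = np.sort(np.concatenate([t for _, t in cv.folds]))
    assert np.array_equal(covered, np.arange(50))
    for train, test in cv.folds:
        assert np.intersect1d(train, test).size == 0


def test_cv_high_snr_loo(recovery_dataset):
    _, X, y, *_ = recovery_dataset
    assert CPM(X, y).cross_validate("loo").r >= 0.5


def test_cv_permuted_outcome_near_zero(rng):
    # at the standard study scale the null LOO r is centred near zero (a
    # small negative leave-one-out artifact remains); the Monte Carlo
    # uncertainty of the 50-rep mean is accounted for in the band
    rs = []
    for _ in range(50):
        X = rng.normal(size=(120, 1225))
        y = rng.normal(size=120)
        rs.append(CPM(X, y).cross_validate("loo").r)
    sem = np.std(rs, ddof=1) / np.sqrt(len(rs))
    assert abs(np.mean(rs)) < 0.05 + 2 * sem


# ---------------------------------------------------------------------------
# permutation inference


def test_permutation_floor_when_observed_beats_all(recovery_dataset):
    _, X, y, *_ = recovery_dataset
    res = CPM(X, y).permutation_test(scheme="kfold", n_iterations=2,
                                     n_perm=100, seed=0)
    assert res.p_perm == pytest.approx(1 / 101)
    assert (res.null_r < res.observed_r).all()


def test_permutation_deterministic(rng):
    X, y = make_signal_data(rng, n=40, E=60)
    a = CPM(X, y).permutation_test(n_iterations=1, n_perm=100, seed=4)
    b = CPM(X, y).permutation_test(n_iterations=1, n_perm=100, seed=4)
    assert np.array_equal(a.null_r, b.null_r)


def test_partial_permutation_confound_absorption(rng):
    # outcome IS the confound: partial observed r collapses toward zero
    X = rng.normal(size=(60, 80))
    y = rng.normal(size=60)
    res = CPM(X, y).permutation_test(n_iterations=1, n_perm=100, seed=0,
                                     confounds=y.copy())
    assert res.statistic == "partial_pearson"
    assert abs(res.observed_r) < 0.2


def test_partial_with_independent_confounds_close_to_plain(rng):
    X, y = make_signal_data(rng, n=60, E=80)
    C = rng.normal(size=(60, 2))
    plain = CPM(X, y).permutation_test(n_iterations=1, n_perm=200, seed=0)
    part = CPM(X, y).permutation_test(n_iterations=1, n_perm=200, seed=0,
                                      confounds=C)
    assert part.p_perm == pytest.approx(plain.p_perm, abs=0.1)


def test_constant_confound_dropped_with_warning(rng):
    X, y = make_signal_data(rng, n=40, E=50)
    with pytest.warns(UserWarning, match="constant confound"):
        res = CPM(X, y).permutation_test(n_iterations=1, n_perm=100, seed=0,
                                         confounds=np.ones((40, 1)))
    assert res.statistic == "pearson"  # fell back to plain


def test_few_permutations_warn(rng):
    X, y = make_signal_data(rng, n=40, E=50)
    with pytest.warns(UserWarning, match="unstable"):
        CPM(X, y).permutation_test(n_iterations=1, n_perm=50, seed=0)


# ---------------------------------------------------------------------------
# brain basis set


def test_bbs_span_containment_noiseless(rng):
    n, E = 60, 40
    basis = rng.normal(size=(3, E))
    scores = rng.normal(size=(n, 3))
    X = scores @ basis
    y = scores @ np.array([1.0, -2.0, 0.5])
    preds = bbs_fit_predict(X[:40], y[:40], X[40:], n_components=10)
    assert preds == pytest.approx(y[40:], abs=1e-8)


def test_bbs_permuted_outcome_near_zero(rng):
    rs = []
    for rep in range(30):
        X = rng.normal(size=(120, 300))
        y = rng.normal(size=120)
        rs.append(bbs_cross_validate(X, y, scheme="kfold", k=5,
                                     n_iterations=1, seed=rep,
                                     n_components=75).r)
    assert abs(np.mean(rs)) < 0.05


def test_bbs_components_beyond_rank_do_not_change_predictions(rng):
    n, E = 30, 50
    basis = rng.normal(size=(4, E))
    X = rng.normal(size=(n, 4)) @ basis  # rank 4
    y = rng.normal(size=n)
    a = bbs_fit_predict(X[:20], y[:20], X[20:], n_components=4)
    b = bbs_fit_predict(X[:20], y[:20], X[20:], n_components=12)
    assert a == pytest.approx(b, abs=1e-8)


def test_bbs_reduces_components_with_warning(rng):
    X = rng.normal(size=(20, 100))
    y = rng.normal(size=20)
    with pytest.warns(UserWarning, match="reduced"):
        bbs_fit_predict(X[:15], y[:15], X[15:], n_components=75)
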