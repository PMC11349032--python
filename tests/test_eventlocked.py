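"""Event-locked activation statistics."""

import numpy as np
import pandas as pd
import pytest

from mindwander.atlas import Atlas, block_atlas
from mindwander.eventlocked import (
    TIMEPOINT_FRAMES,
    gamma_hrf,
    network_median,
    network_rank_order,
    partial_rating_corr,
    percent_signal_change,
    preprobe_mean,
    rating_activation_corr,
    region_glm,
    split_trials,
    timepoint_tests,
)
from mindwander.simulate import SimConfig, simulate_dataset
from mindwander.trials import filter_and_flag


# ---------------------------------------------------------------------------
# %SC and medians


def test_psc_constant_series_is_zero():
    run = np.full((3, 50), 7.0)
    assert (percent_signal_change(run) == 0).all()


def test_psc_ten_percent_deviation():
    run = np.full((1, 10), 100.0)
    run[0, 4] = 110.0
    psc = percent_signal_change(run)
    # mean is 101, so the deviation is relative to that
    assert psc[0, 4] == pytest.approx(100 * (110 - 101) / 101)


def test_psc_centering_identity(rng):
    run = rng.normal(1000, 10, size=(5, 200))
    psc = percent_signal_change(run)
    assert np.abs(psc.mean(axis=1)).max() < 1e-10


def test_psc_zero_mean_region_rejected():
    run = np.vstack([np.ones(10), np.tile([1.0, -1.0], 5)])  # exact zero mean
    with pytest.raises(ValueError, match="1"):
        percent_signal_change(run)


def test_network_median_conventions():
    atlas = Atlas(("A", "B", "B", "B", "C", "C", "C", "C"))
    x = np.array([[5.0], [1.0], [2.0], [3.0], [1.0], [2.0], [3.0], [4.0]])
    med = network_median(x, atlas)
    assert med["A"][0] == 5.0  # single region: identity
    assert med["B"][0] == 2.0  # odd count
    assert med["C"][0] == 2.5  # even count: midpoint


# ---------------------------------------------------------------------------
# pre-probe averaging


def test_preprobe_mean_constant_and_ramp():
    tr = 1.06
    series = np.full(100, 3.3)
    assert preprobe_mean(series, 50.0, tr) == pytest.approx(3.3)
    series = np.zeros(100)
    p = int(np.ceil(30.0 / tr))
    series[p - 9 : p] = np.arange(1, 10)
    assert preprobe_mean(series, 30.0, tr) == pytest.approx(5.0)


def test_preprobe_mean_early_probe_excluded():
    with pytest.raises(ValueError):
        preprobe_mean(np.zeros(100), 5.0, 1.06)


# ---------------------------------------------------------------------------
# correlations


def test_rating_corr_perfect_and_reversed():
    ratings = np.array([1, 3, 5, 2, 7, 8, 4, 6], dtype=float)
    assert rating_activation_corr(ratings, ratings).rho == pytest.approx(1.0)
    assert rating_activation_corr(-ratings, ratings).rho == pytest.approx(-1.0)


def test_partial_corr_control_equal_to_x(rng):
    x = rng.normal(size=300)
    y = 0.7 * x + rng.normal(size=300)
    assert abs(partial_rating_corr(x, y, x).rho) < 0.05


# ---------------------------------------------------------------------------
# high/low split and timepoint tests


def test_split_rule():
    df = pd.DataFrame({
        "rating": [1, 3, 4, 5, 6, 8, np.nan],
        "is_distracted": [False] * 6 + [True],
    })
    high, low = split_trials(df)
    assert sorted(high["rating"]) == [6, 8]
    assert sorted(low["rating"]) == [1, 3]


def test_split_all_intermediate_warns():
    df = pd.DataFrame({"rating": [4, 4, 5], "is_distracted": [False] * 3})
    with pytest.warns(UserWarning):
        high, low = split_trials(df)
    assert len(high) == 0 and len(low) == 0


def _flat_series_runs(n_trials, tr, value=0.0, jitter=None, rng=None):
    onsets = 45.0 + 50.0 * np.arange(n_trials)
    F = int(onsets.max() / tr) + 10
    series = np.zeros(F) if jitter is None else rng.normal(value, jitter, F)
    return {"run-00": series}, onsets, ["run-00"] * n_trials


def test_timepoint_tests_identical_groups_nonsignificant(rng):
    series = {"run-00": rng.normal(size=3000)}
    onsets = 45.0 + 50.0 * np.arange(40)
    runs = ["run-00"] * 40
    res = timepoint_tests(onsets, onsets, series, runs, runs, 1.06)
    assert (res.p_raw > 0.99).all()
    assert len(res.tr_offsets) == TIMEPOINT_FRAMES
    assert res.tr_offsets[0] == pytest.approx(-19 * 1.06)  # -20.14 s
    assert res.tr_offsets[-1] == 0.0


def test_timepoint_tests_detects_planted_offsets(rng):
    tr = 1.0
    n = 100
    onsets_h = 45.0 + 40.0 * np.arange(n)
    onsets_l = onsets_h + 20.0  # interleaved, same run
    F = int(onsets_l.max()) + 30
    series = rng.normal(size=F)
    # shift the low group down by 10 SD at 5 specific offsets
    shifted_offsets = [-1, -2, -3, -4, -5]
    for onset in onsets_l:
        p = int(np.ceil(onset / tr))
        for k in shifted_offsets:
            series[p + k] -= 10.0
    res = timepoint_tests(onsets_h, onsets_l, {"r": series}, ["r"] * n,
                          ["r"] * n, tr)
    sig = res.significant()
    for k in shifted_offsets:
        assert sig[TIMEPOINT_FRAMES - 1 + k]
    assert res.p_fdr.min() < 0.05
    assert (res.p_fdr >= res.p_raw - 1e-12).all()


# ---------------------------------------------------------------------------
# region GLM


def _toy_events(onsets, ratings, run_id="run-00"):
    df = pd.DataFrame({
        "onset": onsets,
        "response_raw": 9 - np.asarray(ratings),
        "run_id": run_id,
        "session_id": "ses-01",
        "fd_mean": 0.1,
    })
    return filter_and_flag(df)


def test_region_glm_self_regression_recovers_beta_one():
    tr = 1.0
    onsets = 45.0 + 50.0 * np.arange(8)
    ratings = np.array([1, 8, 3, 6, 2, 7, 4, 5])
    events = _toy_events(onsets, ratings)
    F = 500
    from mindwander.eventlocked import gamma_hrf
    from scipy.signal import fftconvolve

    z = (ratings - ratings.mean()) / ratings.std(ddof=0)
    reg = np.zeros(F)
    tf = np.arange(F) * tr
    for onset, rz in zip(onsets, z):
        reg[(tf >= onset - 10.0) & (tf < onset)] = rz
    x = fftconvolve(reg, gamma_hrf(tr))[:F]
    runs = {"run-00": 1000.0 + np.vstack([x, np.zeros(F) + 0.0 * x])}
    runs["run-00"][1] += 1.0  # flat region, nonzero mean
    res = region_glm(runs, events, tr)
    # region 0 is an exact affine image of the regressor (%SC rescales it)
    assert res.loc[0, "z"] >= 99.0  # capped large finite
    assert res.loc[0, "beta"] > 0


def test_region_glm_null_calibration(rng):
    # white-noise regions: |z| > 1.96 in about 5% of region-sims
    tr = 1.0
    onsets = 45.0 + 50.0 * np.arange(9)
    zs = []
    for rep in range(10):
        ratings = rng.integers(1, 9, size=9)
        while len(np.unique(ratings)) < 2:
            ratings = rng.integers(1, 9, size=9)
        events = _toy_events(onsets, ratings)
        runs = {"run-00": 1000.0 + rng.normal(size=(50, 500))}
        res = region_glm(runs, events, tr)
        zs.extend(res["z"].tolist())
    rate = np.mean(np.abs(zs) > 1.96)
    assert 0.02 < rate < 0.09


def test_region_glm_recovers_graded_coupling():
    coupling = tuple(np.linspace(0.0, 1.5, 20))
    cfg = SimConfig(n_regions=20, n_runs=8, activation_coupling=coupling,
                    rating_noise_sd=0.25, p_distracted=0.0, seed=21)
    runs, events, gt, atlas = simulate_dataset(cfg)
    table = filter_and_flag(events)
    res = region_glm(runs, table, cfg.tr)
    from mindwander.stats import spearman_corr

    rho = spearman_corr(res["beta"].to_numpy(), np.asarray(coupling)).rho
    assert rho >= 0.9


# ---------------------------------------------------------------------------
# network rank ordering


def test_rank_order_single_elevated_network():
    atlas = block_atlas(12, ("A", "B", "C"))
    stat = np.zeros(12)
    stat[atlas.regions_of("B")] = 1.0
    df = network_rank_order(stat, atlas)
    assert df.iloc[0]["network"] == "B"
    assert df.iloc[0]["median"] == 1.0


def test_rank_order_permutation_invariant(rng):
    atlas = block_atlas(15, ("A", "B", "C"))
    stat = rng.normal(size=15)
    a = network_rank_order(stat, atlas)
    # permuting regions *within* networks leaves the medians unchanged
    perm = np.arange(15)
    for net in atlas.networks:
        members = atlas.regions_of(net)
        perm[members] = rng.permutation(members)
    b = network_rank_order(stat[perm], atlas)
    pd.testing.assert_frame_equal(a, b)


def test_rank_order_matches_brute_force(rng):
    atlas = block_atlas(21, ("A", "B", "C", "D"))
    stat = rng.normal(size=21)
    df = network_rank_order(stat, atlas).set_index("network")
    for net in atlas.networks:
        vals = sorted(stat[atlas.regions_of(net)])
        n = len(vals)
        brute = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
        assert df.loc[net, "median"] == pytest.approx(brute)
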