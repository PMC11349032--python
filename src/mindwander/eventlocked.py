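"""Event-locked activation analyses.

Relates pre-probe BOLD activation to mind-wandering ratings: percent signal
change, per-network median time series, 9-TR pre-probe averaging, Spearman /
partial-Spearman correlation with ratings, TR-by-TR rank-sum tests with FDR
correction over the 20-TR pre-probe span, and a region-level parametric GLM
whose statistics are summarised as a rank-ordered per-network median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .atlas import Atlas
from .connectivity import probe_frame
from .stats import (
    bh_adjust,
    partial_spearman,
    rank_sum_test,
    spearman_corr,
    CorrelationResult,
)

__all__ = [
    "PREPROBE_MEAN_FRAMES",
    "TIMEPOINT_FRAMES",
    "percent_signal_change",
    "network_median",
    "preprobe_mean",
    "rating_activation_corr",
    "partial_rating_corr",
    "split_trials",
    "timepoint_tests",
    "TimepointTestResult",
    "gamma_hrf",
    "region_glm",
    "network_rank_order",
    "preprobe_table",
]

#: the ~10-s pre-probe period is operationalised as exactly 9 TRs (9.54 s)
PREPROBE_MEAN_FRAMES = 9
#: TR-by-TR tests span 20 TRs, -20.14 s ... 0 s relative to the probe frame
TIMEPOINT_FRAMES = 20
#: GLM z statistics are capped at this magnitude (zero-residual fits)
Z_CAP = 100.0


def percent_signal_change(run_data: np.ndarray) -> np.ndarray:
    """Per-region percent signal change: 100 * (x - mean) / mean.

    The mean is taken over the run. Regions with zero mean are rejected.
    """
    x = np.asarray(run_data, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    zero = np.flatnonzero(mu[:, 0] == 0)
    if zero.size:
        raise ValueError(f"zero-mean region(s) {zero.tolist()}: %SC undefined")
    return 100.0 * (x - mu) / mu


def network_median(run_psc: np.ndarray, atlas: Atlas) -> dict[str, np.ndarray]:
    """Per-frame median %SC across each network's regions."""
    x = np.asarray(run_psc, dtype=float)
    if x.shape[0] != atlas.n_regions:
        raise ValueError("matrix row count does not match atlas")
    return {
        net: np.median(x[atlas.regions_of(net)], axis=0) for net in atlas.networks
    }


def preprobe_mean(series: np.ndarray, onset: float, tr: float,
                  n_frames: int = PREPROBE_MEAN_FRAMES) -> float:
    """Mean of the ``n_frames`` frames immediately preceding the probe frame.

    Raises when the window does not fit; callers exclude the trial.
    """
    series = np.asarray(series, dtype=float)
    p = probe_frame(onset, tr)
    if p < n_frames or p > len(series):
        raise ValueError(
            f"probe at {onset:.2f} s: {n_frames} pre-probe frames unavailable"
        )
    return float(series[p - n_frames : p].mean())


def preprobe_table(
    runs: dict, events: pd.DataFrame, atlas: Atlas, tr: float,
    n_frames: int = PREPROBE_MEAN_FRAMES,
) -> pd.DataFrame:
    """Per-trial pre-probe %SC for every network.

    Returns the non-distracted event rows that had a full window, with one
    added column per network (``psc_<network>``).
    """
    median_cache = {
        run_id: network_median(percent_signal_change(data), atlas)
        for run_id, data in runs.items()
    }
    rows = []
    for idx, ev in events.iterrows():
        if bool(ev.get("is_distracted", False)):
            continue
        med = median_cache[ev["run_id"]]
        try:
            vals = {
                f"psc_{net}": preprobe_mean(series, float(ev["onset"]), tr, n_frames)
                for net, series in med.items()
            }
        except ValueError:
            warnings.warn(
                f"trial at {ev['onset']:.1f} s in run {ev['run_id']} excluded "
                f"from pre-probe averaging", stacklevel=2,
            )
            continue
        rows.append({**ev.to_dict(), **vals})
    if not rows:
        raise ValueError("no trial had a full pre-probe window")
    return pd.DataFrame(rows, index=None)


def rating_activation_corr(psc, ratings) -> CorrelationResult:
    """Spearman correlation between per-trial %SC and ratings."""
    psc = np.asarray(psc, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if len(psc) < 4:
        raise ValueError("need at least 4 trials")
    return spearman_corr(psc, ratings)


def partial_rating_corr(psc, ratings, control) -> CorrelationResult:
    """Partial Spearman of %SC vs ratings controlling for another series."""
    return partial_spearman(psc, ratings, control)


def split_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """High (rating 6-8) and low (rating 1-3) mind-wandering trial sets;
    intermediate ratings 4-5 are discarded, distracted trials never enter."""
    ok = table[~table["is_distracted"]]
    high = ok[ok["rating"].between(6, 8)]
    low = ok[ok["rating"].between(1, 3)]
    if len(high) == 0 or len(low) == 0:
        warnings.warn("empty high or low trial set; downstream tests will be skipped",
                      stacklevel=2)
    return high.copy(), low.copy()


@dataclass
class TimepointTestResult:
    """TR-by-TR group comparison over the 20-TR pre-probe span."""

    tr_offsets: np.ndarray  # seconds, -20.14 ... 0
    statistic: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    n_high: int
    n_low: int

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_fdr < alpha


def _timepoint_matrix(series: np.ndarray, onsets, tr: float) -> np.ndarray:
    """trials x 20 matrix of the network series at frames p-19 ... p."""
    out = []
    for onset in onsets:
        p = probe_frame(onset, tr)
        if p < TIMEPOINT_FRAMES - 1 or p >= len(series):
            continue
        out.append(series[p - (TIMEPOINT_FRAMES - 1) : p + 1])
    return np.asarray(out)


def timepoint_tests(
    high_onsets, low_onsets, series_by_run: dict, high_runs, low_runs, tr: float
) -> TimepointTestResult:
    """Wilcoxon rank-sum comparison of high vs low mind-wandering %SC at each
    of the 20 TRs spanning -20.14 to 0 s, BH-adjusted across offsets.

    ``series_by_run`` maps run_id to the network's per-frame %SC series;
    onsets/runs are parallel per-trial sequences. Trials without the full
    20-TR span are excluded from this analysis.
    """
    def gather(onsets, run_ids):
        rows = []
        for onset, rid in zip(onsets, run_ids):
            m = _timepoint_matrix(series_by_run[rid], [onset], tr)
            if m.size:
                rows.append(m[0])
        return np.asarray(rows)

    H = gather(high_onsets, high_runs)
    L = gather(low_onsets, low_runs)
    if len(H) < 2 or len(L) < 2:
        raise ValueError("both groups need at least 2 trials with a full span")
    stats_, pvals = [], []
    for k in range(TIMEPOINT_FRAMES):
        s, p = rank_sum_test(H[:, k], L[:, k])
        stats_.append(s)
        pvals.append(p)
    pvals = np.asarray(pvals)
    offsets = (np.arange(TIMEPOINT_FRAMES) - (TIMEPOINT_FRAMES - 1)) * tr
    return TimepointTestResult(
        tr_offsets=offsets,
        statistic=np.asarray(stats_),
        p_raw=pvals,
        p_fdr=bh_adjust(pvals),
        n_high=len(H),
        n_low=len(L),
    )


def gamma_hrf(tr: float, mean_lag: float = 6.0, sd: float = 3.0,
              duration: float = 24.0) -> np.ndarray:
    """Single-gamma HRF with given mean lag and SD, peak normalised to 1."""
    shape = (mean_lag / sd) ** 2
    scale = sd**2 / mean_lag
    t = np.arange(0, duration, tr)
    h = gamma_dist(shape, scale=scale).pdf(t)
    return h / h.max()


def region_glm(
    runs: dict,
    events: pd.DataFrame,
    tr: float,
    boxcar_seconds: float = 10.0,
    hrf: np.ndarray | None = None,
) -> pd.DataFrame:
    """Region-level parametric GLM of %SC on z-scored ratings.

    Per run the design is a boxcar of ``boxcar_seconds`` ending at each probe
    onset, with height equal to the trial's z-scored rating (z-scoring over
    the subject's full non-distracted trial set), convolved with a gamma HRF.
    Per-region OLS betas from each run are combined by fixed-effects
    inverse-variance averaging into a per-region z statistic.

    Runs flagged ``run_excluded_constant`` are skipped, as are distracted
    trials. Returns a DataFrame with columns region, beta, se, z.
    """
    ok = events[~events["is_distracted"]].copy()
    if len(ok) == 0:
        raise ValueError("no usable trials")
    mu, sd = ok["rating"].mean(), ok["rating"].std(ddof=0)
    if sd == 0:
        raise ValueError("ratings constant across the whole trial set")
    ok["rating_z"] = (ok["rating"] - mu) / sd
    if hrf is None:
        hrf = gamma_hrf(tr)

    betas, variances = [], []
    for run_id, data in runs.items():
        ev = ok[ok["run_id"] == run_id]
        if len(ev) == 0 or bool(ev["run_excluded_constant"].iloc[0]):
            continue
        psc = percent_signal_change(data)
        F = psc.shape[1]
        t_frames = np.arange(F) * tr
        reg = np.zeros(F)
        for _, row in ev.iterrows():
            onset = float(row["onset"])
            in_box = (t_frames >= onset - boxcar_seconds) & (t_frames < onset)
            reg[in_box] = row["rating_z"]
        x = fftconvolve(reg, hrf)[:F]
        D = np.column_stack([np.ones(F), x])
        DtD = D.T @ D
        if np.linalg.matrix_rank(DtD) < 2:
            warnings.warn(f"run {run_id}: rank-deficient design, skipped", stacklevel=2)
            continue
        DtDinv = np.linalg.inv(DtD)
        B = DtDinv @ (D.T @ psc.T)  # (2, R)
        resid = psc.T - D @ B
        dof = F - 2
        sigma2 = (resid**2).sum(axis=0) / dof
        betas.append(B[1])
        variances.append(sigma2 * DtDinv[1, 1])
    if not betas:
        raise ValueError("no run admissible for the GLM")
    B = np.asarray(betas)  # (n_runs, R)
    V = np.asarray(variances)
    V = np.where(V <= 0, np.finfo(float).tiny, V)
    W = 1.0 / V
    beta_fe = (W * B).sum(axis=0) / W.sum(axis=0)
    se_fe = np.sqrt(1.0 / W.sum(axis=0))
    z = np.clip(beta_fe / se_fe, -Z_CAP, Z_CAP)
    return pd.DataFrame({"region": np.arange(B.shape[1]), "beta": beta_fe,
                         "se": se_fe, "z": z})


def network_rank_order(stat: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """Median statistic per network, sorted descending (ties broken by
    network label order of first appearance)."""
    stat = np.asarray(stat, dtype=float)
    if len(stat) != atlas.n_regions:
        raise ValueError("statistic length does not match atlas")
    rows = [
        {"network": net, "median": float(np.median(stat[atlas.regions_of(net)]))}
        for net in atlas.networks
    ]
    df = pd.DataFrame(rows)
    order = {net: k for k, net in enumerate(atlas.networks)}
    df["_tie"] = df["network"].map(order)
    df = df.sort_values(["median", "_tie"], ascending=[False, True])
    return df.drop(columns="_tie").reset_index(drop=True)
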