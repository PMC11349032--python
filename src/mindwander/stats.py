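"""Rank-based statistical kernels shared across the pipeline.

Spearman and partial-Spearman correlations are implemented directly as
average-rank transforms followed by (partial) Pearson correlation, because the
pipeline needs (a) exact small-sample p-values by enumeration and (b) a partial
variant with the same tie convention. The Wilcoxon rank-sum test and
Benjamini-Hochberg adjustment delegate to scipy/statsmodels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "spearman_corr",
    "partial_spearman",
    "rank_sum_test",
    "bh_adjust",
    "pearson_corr",
    "edge_correlations",
]

#: below this sample size Spearman p-values are computed by exhaustive
#: enumeration of rank permutations rather than the t approximation
EXACT_SPEARMAN_N = 10


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its two-tailed p-value."""

    rho: float
    p: float
    n: int

    def __iter__(self):
        return iter((self.rho, self.p))


def _rankdata(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(np.asarray(x, dtype=float), method="average")


def pearson_corr(x, y) -> float:
    """Plain Pearson correlation; nan if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(xc @ yc) / denom


def _t_pvalue(r: float, n: int) -> float:
    if n < 3 or not np.isfinite(r):
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(sps.t.sf(abs(t), n - 2))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-tailed p by enumerating all permutations of one rank vector.

    Valid with ties: the observed average ranks are permuted as values, which
    enumerates the full permutation null of the paired statistic.
    """
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * (ryc * ryc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (ryc @ rxc) / denom
    rhos = rhos[np.isfinite(rhos)]
    # count as extreme with a small tolerance against float round-off
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_corr(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-tailed p-value.

    Ties receive average ranks. For n < 10 the p-value is exact (permutation
    enumeration); otherwise the large-sample t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n)
    rx, ry = _rankdata(x), _rankdata(y)
    rho = pearson_corr(rx, ry)
    if n < EXACT_SPEARMAN_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _t_pvalue(rho, n)
    return CorrelationResult(rho, p, n)


def partial_spearman(x, y, control) -> CorrelationResult:
    """Partial Spearman correlation of x and y controlling for one or more
    covariates.

    All series are average-rank transformed, then the partial Pearson
    correlation is computed from residuals of least-squares projections on the
    (rank-transformed) controls. p-value from the t approximation with
    n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    control = np.asarray(control, dtype=float)
    if control.ndim == 1:
        control = control[:, None]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations for a partial correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n)
    rx, ry = _rankdata(x), _rankdata(y)
    # constant controls carry no variance: drop them (partial -> plain)
    keep = [k for k in range(control.shape[1]) if np.ptp(control[:, k]) > 0]
    if not keep:
        res = spearman_corr(x, y)
        return CorrelationResult(res.rho, res.p, n)
    rc = np.column_stack([_rankdata(control[:, k]) for k in keep])
    design = np.column_stack([np.ones(n), rc])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0.0:
        # control collinear with x or y: partial correlation undefined
        return CorrelationResult(float("nan"), float("nan"), n)
    rho = float(ex @ ey) / denom
    k = rc.shape[1]
    df = n - 2 - k
    if df < 1 or abs(rho) >= 1.0:
        p = 0.0 if abs(rho) >= 1.0 else float("nan")
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return CorrelationResult(rho, p, n)


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (statistic, p). The statistic is the Mann-Whitney U of the first
    sample. Exact p for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's "auto" policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


def edge_correlations(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson correlation of every feature in X with every column
    of Y, with two-tailed t-approximation p-values.

    Parameters
    ----------
    X : (n, E) feature matrix (e.g. trials x edges)
    Y : (n,) or (n, m) outcome(s)

    Returns
    -------
    r, p : (E, m) arrays. Features or outcomes with zero variance yield r = 0,
        p = 1 (never selected downstream).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y disagree on the number of observations")
    if n < 3:
        raise ValueError("need at least 3 observations")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((Yc * Yc).sum(axis=0))
    denom = sx[:, None] * sy[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / denom
    bad = ~np.isfinite(r)
    r[bad] = 0.0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[bad] = 1.0
    if squeeze:
        return r[:, 0], p[:, 0]
    return r, p
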