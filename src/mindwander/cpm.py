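"""Idiographic connectome-based predictive modeling (CPM).

The model predicts a trial-wise behavioral score (the mind-wandering rating)
from trial-wise functional connectivity:

1.  *Edge selection*: within the training trials, every edge is correlated
    (Pearson) with the outcome; edges beyond an uncorrected two-tailed
    p < 0.01 form a positive mask (r > 0) and a negative mask (r < 0).
2.  *Network strength*: per trial, the summed positive-mask edge values minus
    the summed negative-mask edge values.
3.  *Linear map*: a least-squares line from network strength to the outcome,
    fitted on training trials and applied to held-out trials.

Validation is out-of-fold (leave-one-trial-out, or 5-fold repeated over 120
random partitions), with significance from permutation tests that re-run the
entire pipeline - selection inside folds - on shuffled outcomes. A
confound-controlled variant scores folds by partial correlation with the
confounds jointly shuffled alongside the outcome.

The class follows the model/results idiom: ``CPM(X, y, ...)`` holds data and
settings, ``fit()`` returns a :class:`CPMResults` carrying masks and the
linear map, and ``cross_validate()`` / ``permutation_test()`` return dedicated
result objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from .atlas import Atlas
from .connectivity import n_edges, upper_triangle_pairs
from .stats import edge_correlations, pearson_corr

__all__ = [
    "EdgeMasks",
    "CPM",
    "CPMResults",
    "CVResult",
    "PermutationResult",
    "select_edges",
    "network_strength",
    "fit_predict",
    "bbs_fit_predict",
    "bbs_cross_validate",
]

DEFAULT_SELECTION_P = 0.01


@dataclass
class EdgeMasks:
    """Positive and negative predictive edge sets (canonical edge ids)."""

    positive: np.ndarray
    negative: np.ndarray
    selection_p: float = DEFAULT_SELECTION_P
    atlas_id: str = ""

    def __post_init__(self):
        self.positive = np.asarray(self.positive, dtype=int)
        self.negative = np.asarray(self.negative, dtype=int)
        if np.intersect1d(self.positive, self.negative).size:
            raise ValueError("positive and negative masks must be disjoint")

    @property
    def n_edges(self) -> int:
        return len(self.positive) + len(self.negative)


def select_edges(X, y, p_thresh: float = DEFAULT_SELECTION_P,
                 atlas_id: str = "") -> EdgeMasks:
    """Threshold-based edge selection on the full (or given) trial set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("edge selection needs at least 10 trials")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; selection undefined")
    r, p = edge_correlations(X, y)
    sel = p < p_thresh
    return EdgeMasks(
        positive=np.flatnonzero(sel & (r > 0)),
        negative=np.flatnonzero(sel & (r < 0)),
        selection_p=p_thresh,
        atlas_id=atlas_id,
    )


def network_strength(X, masks: EdgeMasks, convention: str = "pos_minus_neg") -> np.ndarray:
    """Signed sum of selected edge values per trial.

    ``pos_minus_neg`` (the package convention) or ``neg_minus_pos``; the two
    differ only by sign, which the fitted slope absorbs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if masks.n_edges == 0:
        warnings.warn("both masks empty: network strength is identically 0",
                      stacklevel=2)
        return np.zeros(X.shape[0])
    s = X[:, masks.positive].sum(axis=1) - X[:, masks.negative].sum(axis=1)
    if convention == "neg_minus_pos":
        s = -s
    elif convention != "pos_minus_neg":
        raise ValueError(f"unknown strength convention {convention!r}")
    return s


def _fit_line(strength: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Least-squares slope/intercept; zero-variance strength degrades to the
    train-mean constant predictor (flagged)."""
    sm, ym = strength.mean(), y.mean()
    sc = strength - sm
    var = float(sc @ sc)
    if var == 0.0:
        return 0.0, float(ym), True
    slope = float(sc @ (y - ym)) / var
    return slope, float(ym - slope * sm), False


def fit_predict(X_train, y_train, X_test,
                p_thresh: float = DEFAULT_SELECTION_P,
                convention: str = "pos_minus_neg") -> np.ndarray:
    """One CPM fold: selection + strength + line on train, predict test."""
    masks = select_edges(X_train, y_train, p_thresh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s_tr = network_strength(X_train, masks, convention)
        s_te = network_strength(np.atleast_2d(X_test), masks, convention)
    slope, intercept, _ = _fit_line(s_tr, np.asarray(y_train, dtype=float))
    return slope * s_te + intercept


# ---------------------------------------------------------------------------
# vectorised internals (many outcome columns at once, for permutations)


def _make_kfold(n: int, k: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return [(np.setdiff1d(np.arange(n), test), test)
            for test in np.array_split(order, k)]


def _make_loo(n: int):
    idx = np.arange(n)
    return [(np.delete(idx, i), idx[i : i + 1]) for i in range(n)]


def _cv_predict_multi(X: np.ndarray, Y: np.ndarray, folds, p_thresh: float,
                      sign: float = 1.0) -> np.ndarray:
    """Out-of-fold CPM predictions for every outcome column of Y.

    Edge selection, strength, and the linear map are computed inside each
    training fold only (no leakage); columns whose fold outcome is constant
    or selects no edge fall back to the train-mean predictor.
    """
    preds = np.empty_like(Y, dtype=float)
    for train, test in folds:
        Xtr = X[train]
        Ytr = Y[train]
        r, p = edge_correlations(Xtr, Ytr)
        M = ((p < p_thresh) & (r > 0)).astype(float) - ((p < p_thresh) & (r < 0))
        M *= sign
        s_tr = Xtr @ M
        s_te = X[test] @ M
        sm = s_tr.mean(axis=0)
        ym = Ytr.mean(axis=0)
        sc = s_tr - sm
        var = (sc * sc).sum(axis=0)
        cov = (sc * (Ytr - ym)).sum(axis=0)
        slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
        intercept = ym - slope * sm
        preds[test] = s_te * slope + intercept
    return preds


def _pearson_columns(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Pc = P - P.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((Pc * Pc).sum(axis=0) * (Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Pc * Yc).sum(axis=0) / denom
    return np.where(np.isfinite(r), r, 0.0)


def _partial_pearson_columns(P: np.ndarray, Y: np.ndarray, C_list) -> np.ndarray:
    """Partial Pearson of each prediction column with its outcome column,
    controlling for that column's confound matrix."""
    n, m = Y.shape
    out = np.empty(m)
    for b in range(m):
        C = C_list[b]
        D = np.column_stack([np.ones(n), C])
        bp, *_ = np.linalg.lstsq(D, P[:, b], rcond=None)
        by, *_ = np.linalg.lstsq(D, Y[:, b], rcond=None)
        ep = P[:, b] - D @ bp
        ey = Y[:, b] - D @ by
        denom = np.sqrt((ep @ ep) * (ey @ ey))
        out[b] = (ep @ ey) / denom if denom > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# result containers


@dataclass
class CVResult:
    """Out-of-fold prediction performance."""

    scheme: str
    predicted: np.ndarray  # mean out-of-fold prediction per trial
    observed: np.ndarray
    r: float  # Pearson(predicted, observed); mean over iterations for kfold
    r_per_iteration: np.ndarray
    seed: int | None = None
    folds: list = field(default_factory=list, repr=False)  # audit trail

    def summary(self) -> str:
        lines = [
            "CPM cross-validation",
            f"  scheme:      {self.scheme}",
            f"  trials:      {len(self.observed)}",
            f"  iterations:  {len(self.r_per_iteration)}",
            f"  r (pred-obs): {self.r:.4f}",
        ]
        if len(self.r_per_iteration) > 1:
            lines.append(f"  r SD across iterations: {self.r_per_iteration.std(ddof=1):.4f}")
        return "\n".join(lines)


@dataclass
class PermutationResult:
    """Permutation inference on the cross-validated statistic."""

    observed_r: float
    null_r: np.ndarray
    p_perm: float
    statistic: str = "pearson"
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return len(self.null_r)

    def summary(self) -> str:
        return (
            "CPM permutation test\n"
            f"  statistic:   {self.statistic}\n"
            f"  observed r:  {self.observed_r:.4f}\n"
            f"  permutations: {self.n_perm}\n"
            f"  p_perm:      {self.p_perm:.4g}"
        )


@dataclass
class CPMResults:
    """A fitted CPM: masks plus the strength -> outcome line."""

    masks: EdgeMasks
    slope: float
    intercept: float
    strength_convention: str
    n_trials: int
    n_regions: int
    atlas_hash: str = ""
    training_trials: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = network_strength(X, self.masks, self.strength_convention)
        return self.slope * s + self.intercept

    def summary(self) -> str:
        return (
            "Connectome-based predictive model\n"
            f"  regions:        {self.n_regions}\n"
            f"  trials fitted:  {self.n_trials}\n"
            f"  positive edges: {len(self.masks.positive)}\n"
            f"  negative edges: {len(self.masks.negative)}\n"
            f"  selection p:    {self.masks.selection_p}\n"
            f"  convention:     {self.strength_convention}\n"
            f"  slope:          {self.slope:.6g}\n"
            f"  intercept:      {self.intercept:.6g}"
        )


# ---------------------------------------------------------------------------
# the model


class CPM:
    """Connectome-based predictive model over a trials x edges matrix.

    Parameters
    ----------
    X : (n_trials, n_edges) Fisher-z connectivity matrix in canonical edge
        order for ``n_regions`` regions.
    y : per-trial outcome (mind-wandering rating).
    atlas : optional :class:`Atlas`, required for lesion/retain.
    selection_p : uncorrected two-tailed selection threshold (default 0.01).
    candidate_edges : optional subset of edge ids eligible for selection
        (lesion/retention models restrict this; ids are always reported in
        the full enumeration).
    """

    def __init__(self, X, y, atlas: Atlas | None = None,
                 selection_p: float = DEFAULT_SELECTION_P,
                 candidate_edges: np.ndarray | None = None,
                 strength_convention: str = "pos_minus_neg"):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (n_trials, n_edges) matching y")
        if len(self.y) < 10:
            raise ValueError("CPM needs at least 10 trials")
        self.atlas = atlas
        if atlas is not None and n_edges(atlas.n_regions) != self.X.shape[1]:
            raise ValueError("edge count does not match the atlas")
        self.selection_p = float(selection_p)
        self.strength_convention = strength_convention
        if candidate_edges is None:
            candidate_edges = np.arange(self.X.shape[1])
        self.candidate_edges = np.asarray(candidate_edges, dtype=int)
        if self.candidate_edges.size == 0:
            raise ValueError("candidate edge set is empty")
        self._sign = -1.0 if strength_convention == "neg_minus_pos" else 1.0
        if strength_convention not in ("pos_minus_neg", "neg_minus_pos"):
            raise ValueError(f"unknown strength convention {strength_convention!r}")

    # -- helpers ----------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.y)

    @property
    def _Xc(self) -> np.ndarray:
        return self.X[:, self.candidate_edges]

    def _n_regions(self) -> int:
        if self.atlas is not None:
            return self.atlas.n_regions
        # invert E = R(R-1)/2
        E = self.X.shape[1]
        return int(round((1 + np.sqrt(1 + 8 * E)) / 2))

    def _folds(self, scheme: str, k: int, rng: np.random.Generator | None):
        if scheme == "loo":
            return _make_loo(self.n_trials)
        if scheme == "kfold":
            if self.n_trials < 20:
                raise ValueError("k-fold CV needs at least 20 trials")
            assert rng is not None
            return _make_kfold(self.n_trials, k, rng)
        raise ValueError(f"unknown CV scheme {scheme!r}")

    # -- fitting ----------------------------------------------------------

    def fit(self) -> CPMResults:
        """Fit on a single fold containing all trials."""
        masks_local = select_edges(self._Xc, self.y, self.selection_p,
                                   atlas_id=self.atlas.hash() if self.atlas else "")
        masks = EdgeMasks(
            positive=self.candidate_edges[masks_local.positive],
            negative=self.candidate_edges[masks_local.negative],
            selection_p=self.selection_p,
            atlas_id=masks_local.atlas_id,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = network_strength(self.X, masks, self.strength_convention)
        slope, intercept, degenerate = _fit_line(s, self.y)
        if degenerate:
            warnings.warn("zero-variance network strength: constant model",
                          stacklevel=2)
        return CPMResults(
            masks=masks,
            slope=slope,
            intercept=intercept,
            strength_convention=self.strength_convention,
            n_trials=self.n_trials,
            n_regions=self._n_regions(),
            atlas_hash=self.atlas.hash() if self.atlas else "",
            training_trials=np.arange(self.n_trials),
        )

    def cross_validate(self, scheme: str = "loo", k: int = 5,
                       n_iterations: int = 120, seed: int = 0) -> CVResult:
        """Out-of-fold predictions and the predicted-observed Pearson r.

        ``loo`` is deterministic; ``kfold`` draws ``n_iterations`` random
        unstratified k-fold partitions from ``seed`` and reports the mean r.
        """
        Y = self.y[:, None]
        if scheme == "loo":
            folds = self._folds("loo", k, None)
            P = _cv_predict_multi(self._Xc, Y, folds, self.selection_p, self._sign)
            r = float(_pearson_columns(P, Y)[0])
            return CVResult("loo", P[:, 0], self.y.copy(), r, np.array([r]),
                            seed=None, folds=folds)
        rng = np.random.default_rng(seed)
        rs = np.empty(n_iterations)
        acc = np.zeros(self.n_trials)
        first_folds: list = []
        for it in range(n_iterations):
            folds = self._folds("kfold", k, rng)
            if it == 0:
                first_folds = folds
            P = _cv_predict_multi(self._Xc, Y, folds, self.selection_p, self._sign)
            rs[it] = _pearson_columns(P, Y)[0]
            acc += P[:, 0]
        return CVResult(
            f"kfold(k={k}, iterations={n_iterations})",
            acc / n_iterations, self.y.copy(), float(rs.mean()), rs,
            seed=seed, folds=first_folds,
        )

    def permutation_test(self, scheme: str = "kfold", k: int = 5,
                         n_iterations: int = 120, n_perm: int = 1000,
                         seed: int = 0,
                         confounds: np.ndarray | None = None) -> PermutationResult:
        """Permutation inference: the full CV pipeline (selection inside
        folds) is re-run on each shuffled outcome.

        With ``confounds`` (n x c), the fold statistic is the partial Pearson
        correlation of predicted vs observed controlling for the confounds,
        and outcome + confound rows are shuffled jointly so their coupling is
        preserved under the null. p uses the add-one estimator, one-tailed in
        r; the floor at 1,000 permutations is 1/1001.
        """
        if n_perm < 100:
            warnings.warn("fewer than 100 permutations: p_perm is unstable",
                          stacklevel=2)
        rng = np.random.default_rng(seed)
        n = self.n_trials
        perms = [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]
        Y = np.column_stack([self.y[p] for p in perms])
        statistic = "pearson"
        C_list = None
        if confounds is not None:
            confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
            if confounds.shape[0] != n:
                confounds = confounds.T
            keep = [c for c in range(confounds.shape[1])
                    if np.ptp(confounds[:, c]) > 0]
            if len(keep) < confounds.shape[1]:
                warnings.warn("constant confound(s) dropped", stacklevel=2)
            if keep:
                confounds = confounds[:, keep]
                C_list = [confounds[p] for p in perms]
                statistic = "partial_pearson"

        if scheme == "loo":
            fold_sets = [self._folds("loo", k, None)]
        else:
            fold_sets = [self._folds("kfold", k, rng) for _ in range(n_iterations)]
        R = np.zeros(len(perms))
        for folds in fold_sets:
            P = _cv_predict_multi(self._Xc, Y, folds, self.selection_p, self._sign)
            if C_list is None:
                R += _pearson_columns(P, Y)
            else:
                R += _partial_pearson_columns(P, Y, C_list)
        R /= len(fold_sets)
        observed, null = float(R[0]), R[1:]
        p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
        return PermutationResult(observed, null, p, statistic=statistic, seed=seed)

    # -- network restriction ----------------------------------------------

    def _network_edges(self, network: str) -> np.ndarray:
        if self.atlas is None:
            raise ValueError("lesion/retain require an atlas")
        members = self.atlas.regions_of(network)
        iu, ju = upper_triangle_pairs(self.atlas.n_regions)
        touch = np.isin(iu, members) | np.isin(ju, members)
        return np.flatnonzero(touch)

    def lesion(self, network: str) -> "CPM":
        """Model with every edge touching ``network`` removed from the
        candidate set (training and testing)."""
        removed = self._network_edges(network)
        keep = np.setdiff1d(self.candidate_edges, removed)
        if keep.size == 0:
            raise ValueError(f"lesioning {network!r} removes every edge")
        return CPM(self.X, self.y, atlas=self.atlas, selection_p=self.selection_p,
                   candidate_edges=keep, strength_convention=self.strength_convention)

    def retain(self, network: str) -> "CPM":
        """Model keeping only edges with at least one endpoint in ``network``."""
        kept = np.intersect1d(self.candidate_edges, self._network_edges(network))
        if kept.size == 0:
            raise ValueError(f"no candidate edge touches {network!r}")
        return CPM(self.X, self.y, atlas=self.atlas, selection_p=self.selection_p,
                   candidate_edges=kept, strength_convention=self.strength_convention)


# ---------------------------------------------------------------------------
# brain-basis-set alternative


def bbs_fit_predict(X_train, y_train, X_test, n_components: int = 75) -> np.ndarray:
    """PCA-then-regression predictive model (brain basis set).

    Principal components are estimated from training edges only; the outcome
    is regressed on training component scores and predicted from the test
    projections. ``n_components`` is reduced (with a warning) when it exceeds
    n_train - 1.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train, dtype=float)
    limit = min(len(y_train) - 1, X_train.shape[1])
    nc = min(n_components, limit)
    if nc < n_components:
        warnings.warn(
            f"n_components reduced from {n_components} to {nc} "
            f"(training size limit)", stacklevel=2,
        )
    pca = PCA(n_components=nc)
    scores = pca.fit_transform(X_train)
    reg = LinearRegression().fit(scores, y_train)
    return reg.predict(pca.transform(X_test))


def bbs_cross_validate(X, y, scheme: str = "loo", k: int = 5,
                       n_iterations: int = 1, seed: int = 0,
                       n_components: int = 75) -> CVResult:
    """Out-of-fold brain-basis-set predictions (same fold schemes as CPM)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if scheme == "loo":
            folds_sets = [_make_loo(n)]
        else:
            rng = np.random.default_rng(seed)
            folds_sets = [_make_kfold(n, k, rng) for _ in range(n_iterations)]
        rs = []
        acc = np.zeros(n)
        for folds in folds_sets:
            P = np.empty(n)
            for train, test in folds:
                P[test] = bbs_fit_predict(X[train], y[train], X[test], n_components)
            rs.append(pearson_corr(P, y))
            acc += P
    rs = np.asarray(rs)
    label = "loo" if scheme == "loo" else f"kfold(k={k}, iterations={n_iterations})"
    return CVResult(label, acc / len(folds_sets), y.copy(),
                    float(np.nanmean(rs)), rs, seed=seed)
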