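"""Cross-subject model transfer and fixed-mask scoring.

A CPM trained within one subject (single fold, all trials) can be exported to
JSON and applied to another subject's trial-wise connectivity: network
strength is computed from the training subject's masks, the training
subject's line maps it to predicted ratings, and transfer performance is the
Spearman correlation of predicted vs observed ratings. Fixed, externally
supplied masks (population-derived models) are scored without any line —
Spearman is invariant to positive affine maps, so strength itself is
correlated with the observed ratings.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .cpm import CPM, CPMResults, EdgeMasks, network_strength
from .stats import spearman_corr, CorrelationResult

__all__ = [
    "export_model",
    "save_model",
    "load_model",
    "apply_external",
    "score_fixed_masks",
]


def export_model(X, y, atlas=None, selection_p: float = 0.01) -> CPMResults:
    """Train an exportable CPM on a single fold containing all trials."""
    model = CPM(X, y, atlas=atlas, selection_p=selection_p)
    results = model.fit()
    if results.masks.n_edges == 0:
        warnings.warn("exported model has empty masks", stacklevel=2)
    return results


def save_model(results: CPMResults, path) -> None:
    payload = {
        "positive_edges": results.masks.positive.tolist(),
        "negative_edges": results.masks.negative.tolist(),
        "selection_p": results.masks.selection_p,
        "slope": results.slope,
        "intercept": results.intercept,
        "strength_convention": results.strength_convention,
        "n_trials": results.n_trials,
        "n_regions": results.n_regions,
        "atlas_hash": results.atlas_hash,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_model(path) -> CPMResults:
    d = json.loads(Path(path).read_text())
    masks = EdgeMasks(
        positive=np.asarray(d["positive_edges"], dtype=int),
        negative=np.asarray(d["negative_edges"], dtype=int),
        selection_p=d["selection_p"],
        atlas_id=d["atlas_hash"],
    )
    return CPMResults(
        masks=masks,
        slope=d["slope"],
        intercept=d["intercept"],
        strength_convention=d["strength_convention"],
        n_trials=d["n_trials"],
        n_regions=d["n_regions"],
        atlas_hash=d["atlas_hash"],
    )


def _check_atlas(results: CPMResults, n_edges_test: int, atlas_hash: str | None):
    expected = results.n_regions * (results.n_regions - 1) // 2
    if n_edges_test != expected:
        raise ValueError(
            f"edge count mismatch: model expects {expected}, test data has "
            f"{n_edges_test}"
        )
    if atlas_hash is not None and results.atlas_hash and atlas_hash != results.atlas_hash:
        raise ValueError("atlas hash mismatch between model and test data")


def apply_external(results: CPMResults, X_test, y_test,
                   atlas_hash: str | None = None) -> CorrelationResult:
    """Score an externally trained model on new trials.

    Predicted ratings come from the training subject's masks and line;
    returns Spearman rho of predicted vs observed with a two-tailed p.
    """
    X_test = np.asarray(X_test, dtype=float)
    _check_atlas(results, X_test.shape[1], atlas_hash)
    predicted = results.predict(X_test)
    return spearman_corr(predicted, np.asarray(y_test, dtype=float))


def score_fixed_masks(masks: EdgeMasks, X_test, y_test) -> CorrelationResult:
    """Score fixed (e.g. population-derived) masks on trial data.

    Trial-wise strength (positive minus negative summed edges) is Spearman-
    correlated with observed ratings; no linear map is involved.
    """
    if masks.n_edges == 0:
        raise ValueError("cannot score empty masks")
    X_test = np.asarray(X_test, dtype=float)
    strength = network_strength(X_test, masks)
    return spearman_corr(strength, np.asarray(y_test, dtype=float))
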