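"""Network-level interpretation of CPM features.

Given the positive/negative masks of a fitted model, this module tallies
selected edges by network pair, computes per-region node degree, and runs the
computational lesion / single-network retention experiments (full CV and
permutation inference on restricted candidate edge sets).

An edge is "assigned to" a network when at least one endpoint lies in it, so
retention keeps both within-network and between-network edges of the named
network, and lesion + retention of the same network partition the candidate
edge space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import Atlas
from .connectivity import upper_triangle_pairs
from .cpm import CPM, CVResult, EdgeMasks, PermutationResult

__all__ = ["pair_tally", "node_degree", "lesion_cpm", "retain_cpm"]


def pair_tally(masks: EdgeMasks, atlas: Atlas) -> pd.DataFrame:
    """Count mask edges per unordered network pair.

    For N networks there are N(N+1)/2 pairs (within-network pairs included).
    Returns a tidy DataFrame with columns network_a, network_b, n_positive,
    n_negative; the per-mask counts sum to the mask sizes.
    """
    nets = atlas.networks
    iu, ju = upper_triangle_pairs(atlas.n_regions)
    labels = np.asarray(atlas.labels)

    def tally(ids: np.ndarray) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for e in ids:
            a, b = labels[iu[e]], labels[ju[e]]
            key = tuple(sorted((a, b), key=nets.index))
            counts[key] = counts.get(key, 0) + 1
        return counts

    pos = tally(masks.positive)
    neg = tally(masks.negative)
    rows = []
    for i, a in enumerate(nets):
        for b in nets[i:]:
            rows.append({
                "network_a": a,
                "network_b": b,
                "n_positive": pos.get((a, b), 0),
                "n_negative": neg.get((a, b), 0),
            })
    return pd.DataFrame(rows)


def node_degree(masks: EdgeMasks, n_regions: int) -> pd.DataFrame:
    """Per-region count of incident mask edges, separately by mask sign.

    Degrees obey the handshake lemma: they sum to twice the mask size.
    """
    iu, ju = upper_triangle_pairs(n_regions)
    pos = np.zeros(n_regions, dtype=int)
    neg = np.zeros(n_regions, dtype=int)
    np.add.at(pos, iu[masks.positive], 1)
    np.add.at(pos, ju[masks.positive], 1)
    np.add.at(neg, iu[masks.negative], 1)
    np.add.at(neg, ju[masks.negative], 1)
    return pd.DataFrame({
        "region": np.arange(n_regions),
        "pos_degree": pos,
        "neg_degree": neg,
    })


def _restricted_run(model: CPM, scheme: str, k: int, n_iterations: int,
                    n_perm: int, seed: int) -> tuple[CVResult, PermutationResult]:
    cv = model.cross_validate(scheme=scheme, k=k, n_iterations=n_iterations,
                              seed=seed)
    perm = model.permutation_test(scheme=scheme, k=k, n_iterations=n_iterations,
                                  n_perm=n_perm, seed=seed)
    return cv, perm


def lesion_cpm(model: CPM, network: str, scheme: str = "kfold", k: int = 5,
               n_iterations: int = 120, n_perm: int = 1000,
               seed: int = 0) -> tuple[CVResult, PermutationResult]:
    """Full CV + permutation inference with all edges touching ``network``
    removed before selection in every fold."""
    return _restricted_run(model.lesion(network), scheme, k, n_iterations,
                           n_perm, seed)


def retain_cpm(model: CPM, network: str, scheme: str = "kfold", k: int = 5,
               n_iterations: int = 120, n_perm: int = 1000,
               seed: int = 0) -> tuple[CVResult, PermutationResult]:
    """Full CV + permutation inference with only edges touching ``network``
    kept as candidates."""
    return _restricted_run(model.retain(network), scheme, k, n_iterations,
                           n_perm, seed)
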