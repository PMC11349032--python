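"""Trial-wise windowed functional connectivity.

Each thought probe yields one feature vector: the Fisher-z transformed Pearson
correlations between all region pairs, computed within the 28 frames
(~30 s at TR = 1.06 s) immediately preceding the probe frame. Edges are
enumerated in canonical row-major upper-triangle order (i < j), which every
mask and model in the package shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WINDOW_FRAMES",
    "ATANH_CLAMP",
    "n_edges",
    "edge_index",
    "edge_endpoints",
    "upper_triangle_pairs",
    "probe_frame",
    "extract_trial_window",
    "trial_fc",
    "build_trial_edge_matrix",
]

DEFAULT_WINDOW_FRAMES = 28
#: correlations are clamped to +/-(1 - 1e-7) before atanh to keep edges finite
ATANH_CLAMP = 1.0 - 1e-7


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def upper_triangle_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) endpoint arrays in canonical edge order (row-major, i < j)."""
    return np.triu_indices(n_regions, k=1)


def edge_index(i: int, j: int, n_regions: int) -> int:
    """Canonical edge id of the unordered pair (i, j)."""
    if i == j:
        raise ValueError("self-pairs are not edges")
    if i > j:
        i, j = j, i
    if j >= n_regions or i < 0:
        raise ValueError("region index out of range")
    return i * (2 * n_regions - i - 1) // 2 + (j - i - 1)


def edge_endpoints(edge_id: int, n_regions: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`."""
    if not 0 <= edge_id < n_edges(n_regions):
        raise ValueError("edge id out of range")
    i = 0
    offset = 0
    while True:
        row = n_regions - i - 1
        if edge_id < offset + row:
            return i, i + 1 + (edge_id - offset)
        offset += row
        i += 1


def probe_frame(onset: float, tr: float) -> int:
    """First frame whose acquisition time is at or after the probe onset."""
    return int(np.ceil(onset / tr - 1e-9))


def extract_trial_window(
    run_data: np.ndarray, onset: float, tr: float, n_frames: int = DEFAULT_WINDOW_FRAMES
) -> np.ndarray:
    """The region x frame block of the ``n_frames`` frames immediately
    preceding the probe frame (the probe frame itself is excluded).

    Raises ``ValueError`` when fewer than ``n_frames`` frames precede the
    probe; callers exclude such trials and log the reason.
    """
    run_data = np.asarray(run_data, dtype=float)
    p = probe_frame(onset, tr)
    if p > run_data.shape[1]:
        raise ValueError(f"probe onset {onset} s lies beyond the run")
    if p < n_frames:
        raise ValueError(
            f"only {p} frames precede the probe; {n_frames} required"
        )
    return run_data[:, p - n_frames : p]


@dataclass
class TrialEdgeVector:
    """Fisher-z connectivity over one pre-probe window."""

    values: np.ndarray  # length R(R-1)/2, canonical order
    window: tuple[int, int]  # [start_frame, probe_frame)
    n_frames: int
    constant_regions: np.ndarray  # region ids flagged constant in the window


def trial_fc(block: np.ndarray, window_start: int = 0) -> TrialEdgeVector:
    """Fisher-z edge vector for one trial window.

    Pearson r per region pair, clamped to +/-(1-1e-7), then atanh. Regions
    that are constant within the window produce undefined correlations; their
    edges are set to 0 and the region is flagged.
    """
    block = np.asarray(block, dtype=float)
    R, F = block.shape
    bc = block - block.mean(axis=1, keepdims=True)
    sd = np.sqrt((bc * bc).sum(axis=1))
    constant = np.flatnonzero(sd == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    C = (bc @ bc.T) / np.outer(sd_safe, sd_safe)
    iu, ju = upper_triangle_pairs(R)
    r = C[iu, ju]
    bad = np.isin(iu, constant) | np.isin(ju, constant)
    r = np.clip(r, -ATANH_CLAMP, ATANH_CLAMP)
    z = np.arctanh(r)
    z[bad] = 0.0
    return TrialEdgeVector(
        values=z,
        window=(window_start, window_start + F),
        n_frames=F,
        constant_regions=constant,
    )


def build_trial_edge_matrix(
    runs: dict,
    events: pd.DataFrame,
    tr: float,
    n_frames: int = DEFAULT_WINDOW_FRAMES,
    include_distracted: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble the trials x edges feature matrix across runs.

    Parameters
    ----------
    runs : mapping run_id -> region x frame array
    events : trial table with at least columns run_id, onset, rating,
        is_distracted
    tr : repetition time in seconds

    Returns
    -------
    X : (n_trials, n_edges) Fisher-z matrix
    kept : the event rows that produced a feature vector (others are excluded
        with a logged reason: distracted, or insufficient pre-probe frames)
    """
    rows = []
    vectors = []
    for idx, ev in events.iterrows():
        if not include_distracted and bool(ev.get("is_distracted", False)):
            continue
        run = runs[ev["run_id"]]
        p = probe_frame(float(ev["onset"]), tr)
        if p < n_frames or p > run.shape[1]:
            warnings.warn(
                f"trial at {ev['onset']:.1f} s in run {ev['run_id']} excluded: "
                f"insufficient pre-probe frames",
                stacklevel=2,
            )
            continue
        block = extract_trial_window(run, float(ev["onset"]), tr, n_frames)
        vectors.append(trial_fc(block, window_start=p - n_frames).values)
        rows.append(idx)
    if not vectors:
        raise ValueError("no trial produced a connectivity vector")
    X = np.vstack(vectors)
    return X, events.loc[rows].copy()
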