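"""Readers and writers for the pipeline's on-disk formats.

Run matrices are TSV (regions x frames, header row of frame indices),
optionally gzip-compressed; events are BIDS-style TSV with "n/a" for missing
values; the atlas is a two-column TSV; configs are YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas
from .trials import filter_and_flag

__all__ = [
    "read_run_matrix",
    "read_events",
    "read_dataset",
    "load_config",
]


def read_run_matrix(path) -> np.ndarray:
    """Read a regions x frames matrix TSV (plain or .gz).

    The header row lists frame indices; every data row must be numeric and of
    equal length. Ragged rows, NaNs and non-numeric cells raise a parse error
    naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    n_frames = df.shape[1]
    data = np.empty((df.shape[0], n_frames))
    for r in range(df.shape[0]):
        row = df.iloc[r]
        if row.isna().any():
            raise ValueError(f"{path.name}: ragged or missing cell at line {r + 2}")
        try:
            data[r] = row.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path.name}: non-numeric cell at line {r + 2}") from exc
    if np.isnan(data).any():
        bad = int(np.argwhere(np.isnan(data))[0, 0])
        raise ValueError(f"{path.name}: NaN cell at line {bad + 2}")
    return data


def read_events(path, run_length: float | None = None) -> pd.DataFrame:
    """Read a BIDS-style events TSV and return the recoded trial table.

    Requires columns ``onset`` and ``response_raw``; unknown columns are
    preserved. Rows with onsets beyond ``run_length`` (when given) are
    excluded with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for col in ("onset", "response_raw"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    if run_length is not None:
        beyond = df["onset"] > run_length
        if beyond.any():
            import warnings

            warnings.warn(
                f"{path.name}: {int(beyond.sum())} trial(s) beyond run length "
                f"excluded", stacklevel=2,
            )
            df = df[~beyond]
    return filter_and_flag(df.reset_index(drop=True))


def read_dataset(directory):
    """Load a generated dataset directory (manifest, matrices, events, atlas).

    Returns (runs, events, atlas, manifest).
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    runs: dict[str, np.ndarray] = {}
    frames = []
    for name in manifest["files"]:
        if "_bold" in name:
            run_id = name.split("_bold")[0]
            runs[run_id] = read_run_matrix(directory / name)
        elif name.endswith("_events.tsv"):
            frames.append(pd.read_csv(directory / name, sep="\t", na_values=["n/a"]))
    events = filter_and_flag(pd.concat(frames, ignore_index=True))
    atlas = Atlas.from_tsv(directory / "atlas.tsv")
    return runs, events, atlas, manifest


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
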