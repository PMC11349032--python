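"""Region -> network atlas label table.

The pipeline never performs parcellation itself; it consumes a flat table
mapping region ids (0-based, matching the rows of each run matrix) to named
functional networks (e.g. the seven canonical cortical networks).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEVEN_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "Salience",
    "Limbic",
    "Frontoparietal",
    "Default",
)


@dataclass(frozen=True)
class Atlas:
    """Immutable region->network lookup.

    ``labels[i]`` is the network name of region ``i``.
    """

    labels: tuple[str, ...]
    name: str = "atlas"
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("an atlas needs at least 2 regions")
        idx: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels):
            idx.setdefault(lab, []).append(i)
        object.__setattr__(self, "_index", {k: np.array(v) for k, v in idx.items()})

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> tuple[str, ...]:
        """Network names in first-appearance order."""
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def regions_of(self, network: str) -> np.ndarray:
        if network not in self._index:
            raise KeyError(f"unknown network label: {network!r}")
        return self._index[network].copy()

    def hash(self) -> str:
        payload = "\n".join(f"{i}\t{lab}" for i, lab in enumerate(self.labels))
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": np.arange(self.n_regions), "network_label": list(self.labels)}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "Atlas":
        df = pd.read_csv(path, sep="\t")
        for col in ("region_id", "network_label"):
            if col not in df.columns:
                raise ValueError(f"atlas table missing required column {col!r}")
        df = df.sort_values("region_id")
        ids = df["region_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("atlas region_id must be 0..R-1 without gaps")
        return cls(tuple(df["network_label"].astype(str)), name=name or str(path))


def block_atlas(n_regions: int, networks=SEVEN_NETWORKS, sizes=None, name="block") -> Atlas:
    """Atlas assigning regions to networks in contiguous blocks.

    ``sizes`` optionally gives explicit per-network region counts (must sum to
    ``n_regions``); by default regions are split as evenly as possible.
    """
    networks = tuple(networks)
    if sizes is None:
        base = n_regions // len(networks)
        rem = n_regions % len(networks)
        sizes = [base + (1 if k < rem else 0) for k in range(len(networks))]
    if sum(sizes) != n_regions:
        raise ValueError("network sizes must sum to n_regions")
    labels: list[str] = []
    for net, sz in zip(networks, sizes):
        labels.extend([net] * sz)
    return Atlas(tuple(labels), name=name)
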