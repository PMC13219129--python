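"""Resting-state network parcellations on a common voxel grid.

A parcellation assigns disjoint sets of voxels (flat indices into a 3-D
grid) to named resting-state networks (RSNs). The canonical atlas used
throughout the package has 15 networks covering sensorimotor, association
and subcortical systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical network order. Feature vectors, probability maps and effect-size
#: tables all follow this order.
NETWORK_NAMES: tuple[str, ...] = (
    "SMD",  # dorsal somatomotor
    "SMI",  # inferior somatomotor
    "CON",  # cingulo-opercular
    "AUD",  # auditory
    "DMN",  # default mode
    "PMN",  # parietal memory
    "VIS",  # visual
    "FPN",  # frontoparietal
    "SAL",  # salience
    "VAN",  # ventral attention
    "DAN",  # dorsal attention
    "MTL",  # medial temporal
    "REW",  # reward
    "THA",  # thalamus
    "BGA",  # basal ganglia
)


@dataclass(frozen=True)
class Parcellation:
    """Disjoint, non-empty voxel sets for each named network.

    Parameters
    ----------
    network_names:
        Ordered network labels; the order fixes the canonical feature order.
    voxel_ids:
        One integer array of flat voxel indices per network.
    grid_shape:
        Shape of the common 3-D grid the indices refer to.
    """

    network_names: tuple[str, ...]
    voxel_ids: tuple[np.ndarray, ...] = field(repr=False)
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.network_names) != len(self.voxel_ids):
            raise ValueError("one voxel set per network required")
        if len(set(self.network_names)) != len(self.network_names):
            raise ValueError("network names must be unique")
        n_grid = int(np.prod(self.grid_shape))
        seen: set[int] = set()
        for name, ids in zip(self.network_names, self.voxel_ids):
            ids = np.asarray(ids)
            if ids.size == 0:
                raise ValueError(f"network {name} has no voxels")
            if ids.min() < 0 or ids.max() >= n_grid:
                raise ValueError(f"network {name} has voxel ids outside the grid")
            as_set = set(int(v) for v in ids)
            if len(as_set) != ids.size:
                raise ValueError(f"network {name} has duplicate voxel ids")
            if seen & as_set:
                raise ValueError(f"network {name} overlaps another network")
            seen |= as_set

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    @property
    def n_features(self) -> int:
        """Number of within+between similarity features: n(n+1)/2."""
        n = self.n_networks
        return n * (n + 1) // 2

    def voxels(self, name: str) -> np.ndarray:
        return self.voxel_ids[self.network_names.index(name)]

    def label_volume(self) -> np.ndarray:
        """Integer label volume: 0 = background, g+1 = network g."""
        vol = np.zeros(int(np.prod(self.grid_shape)), dtype=np.int16)
        for g, ids in enumerate(self.voxel_ids):
            vol[np.asarray(ids)] = g + 1
        return vol.reshape(self.grid_shape)


def pair_labels(network_names: tuple[str, ...] | list[str]) -> tuple[tuple[str, str], ...]:
    """Canonical feature order: row-major upper triangle (incl. diagonal).

    For 15 networks this yields 15 within-network pairs (i == j) and 105
    between-network pairs, 120 in total.
    """
    names = tuple(network_names)
    out = []
    for i in range(len(names)):
        for j in range(i, len(names)):
            out.append((names[i], names[j]))
    return tuple(out)


def pair_index(network_names: tuple[str, ...] | list[str], a: str, b: str) -> int:
    """Index of the (a, b) similarity feature in the canonical order."""
    names = tuple(network_names)
    i, j = sorted((names.index(a), names.index(b)))
    n = len(names)
    return i * n - i * (i - 1) // 2 + (j - i)
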