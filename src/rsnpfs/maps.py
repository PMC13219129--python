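"""Map-level analyses on the common voxel grid.

Covers the cohort tumor-frequency map, the voxelwise (point-biserial)
association between tumor presence and PFS, per-network averaging of voxel
maps, Cliff's delta effect sizes between control and patient network
probability maps, per-network averaging of feature weights, and the
projection of network weights back onto voxel space through the probability
maps.

Voxels where a statistic is undefined carry NaN as the sentinel missing
value, which survives round-trips through standard float map formats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parcellation import Parcellation

#: Magnitude thresholds for Cliff's delta: below 0.33 negligible/small,
#: 0.33 to 0.47 moderate, 0.47 and above large.
CLIFFS_DELTA_THRESHOLDS = (0.33, 0.47)


def tumor_frequency_map(segmentations: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Voxelwise mean of binary tumor masks; values in [0, 1]."""
    seg = np.asarray(segmentations, dtype=float)
    if seg.ndim == 1:
        seg = seg[None, :]
    if ((seg != 0) & (seg != 1)).any():
        raise ValueError("segmentations must be binary masks")
    return seg.mean(axis=0)


def voxelwise_pfs_association(
    segmentations: np.ndarray, pfs_months: np.ndarray, min_per_group: int = 2
) -> np.ndarray:
    """Point-biserial correlation of tumor presence with PFS, per voxel.

    A voxel is retained only if at least ``min_per_group`` subjects have a
    tumor there and at least ``min_per_group`` do not; all other voxels are
    set to NaN. Positive values mark voxels where tumor presence goes with
    longer PFS.
    """
    seg = np.asarray(segmentations, dtype=float)
    y = np.asarray(pfs_months, dtype=float)
    if seg.ndim != 2 or seg.shape[0] != len(y):
        raise ValueError("segmentations must be (n_subjects, n_voxels) aligned with PFS")
    n = len(y)
    hits = seg.sum(axis=0)
    valid = (hits >= min_per_group) & (n - hits >= min_per_group)
    out = np.full(seg.shape[1], np.nan)
    if y.std() == 0 or not valid.any():
        return out
    yc = y - y.mean()
    mc = seg[:, valid] - seg[:, valid].mean(axis=0)
    num = mc.T @ yc
    den = np.sqrt((mc**2).sum(axis=0) * (yc**2).sum())
    out[valid] = num / den
    return out


def average_map_per_network(
    voxel_map: np.ndarray,
    parcellation: Parcellation | None = None,
    probability_maps: np.ndarray | None = None,
) -> np.ndarray:
    """Per-network mean of a voxel map, skipping NaN sentinel voxels.

    In parcellation mode the mean runs over each network's voxel set; in
    probability mode it is the probability-weighted mean over the grid.
    Exactly one of the two map definitions must be given.
    """
    v = np.asarray(voxel_map, dtype=float)
    if (parcellation is None) == (probability_maps is None):
        raise ValueError("pass exactly one of parcellation or probability_maps")
    if parcellation is not None:
        out = np.full(parcellation.n_networks, np.nan)
        for g, ids in enumerate(parcellation.voxel_ids):
            vals = v[np.asarray(ids)]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[g] = vals.mean()
        return out
    pm = np.asarray(probability_maps, dtype=float)
    if pm.ndim != 2 or pm.shape[1] != v.size:
        raise ValueError("probability_maps must be (n_networks, n_voxels)")
    finite = np.isfinite(v)
    out = np.full(pm.shape[0], np.nan)
    for g in range(pm.shape[0]):
        w = pm[g, finite]
        if w.sum() > 0:
            out[g] = float((w * v[finite]).sum() / w.sum())
    return out


def cliffs_delta(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Cliff's delta: (#{a > b} - #{a < b}) / (|A| |B|), ties contribute 0.

    Computed by a rank-based counting method (sorting B and locating each a
    by binary search), which agrees exactly with full pair enumeration.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    bs = np.sort(b)
    greater = np.searchsorted(bs, a, side="left")  # #{b < a} per a
    less = b.size - np.searchsorted(bs, a, side="right")  # #{b > a} per a
    return float((greater.sum() - less.sum()) / (a.size * b.size))


def delta_magnitude_label(delta: float) -> str:
    """Conventional magnitude label for a Cliff's delta value."""
    m = abs(delta)
    if m < CLIFFS_DELTA_THRESHOLDS[0]:
        return "negligible/small"
    if m < CLIFFS_DELTA_THRESHOLDS[1]:
        return "moderate"
    return "large"


def network_effect_sizes(
    control_maps: np.ndarray,
    patient_maps: np.ndarray,
    parcellation: Parcellation,
) -> pd.DataFrame:
    """Per-network Cliff's delta between control and patient probability maps.

    Each network's delta is computed over that network's own support voxels
    (off-network voxels would dilute the contrast). Positive deltas mean
    higher control probabilities, i.e. reduced network expression in
    patients. Returns a table with columns ``network``, ``delta``,
    ``magnitude``.
    """
    control = np.asarray(control_maps, dtype=float)
    patient = np.asarray(patient_maps, dtype=float)
    n = parcellation.n_networks
    if control.shape != patient.shape or control.shape[0] != n:
        raise ValueError("control/patient maps must be (n_networks, n_voxels) and aligned")
    rows = []
    for g, name in enumerate(parcellation.network_names):
        ids = np.asarray(parcellation.voxel_ids[g])
        d = cliffs_delta(control[g, ids], patient[g, ids])
        rows.append({"network": name, "delta": d, "magnitude": delta_magnitude_label(d)})
    return pd.DataFrame(rows)


def average_network_feature_weights(
    feature_weights: np.ndarray,
    pair_labels: tuple[tuple[str, str], ...],
    network_names: tuple[str, ...],
) -> np.ndarray:
    """Mean pair weight per network over all pairs that involve it.

    For a 15-network parcellation each network appears in 15 pairs (its
    within-network pair plus 14 between-network pairs).
    """
    w = np.asarray(feature_weights, dtype=float)
    if len(w) != len(pair_labels):
        raise ValueError("one weight per pair label required")
    out = np.empty(len(network_names))
    for g, name in enumerate(network_names):
        member = [i for i, (a, b) in enumerate(pair_labels) if name in (a, b)]
        if not member:
            raise ValueError(f"network {name} appears in no pair label")
        out[g] = w[member].mean()
    return out


def project_weights_to_voxels(
    network_weights: np.ndarray, probability_maps: np.ndarray
) -> np.ndarray:
    """Voxelwise dot product of network weights with the probability maps."""
    w = np.asarray(network_weights, dtype=float)
    pm = np.asarray(probability_maps, dtype=float)
    if pm.ndim != 2 or pm.shape[0] != w.size:
        raise ValueError("probability_maps must be (n_networks, n_voxels)")
    return w @ pm
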