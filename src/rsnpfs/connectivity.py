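"""Within- and between-network functional-connectivity (FC) features.

For each subject, voxelwise time series are extracted within every
network-specific ROI. Within-network similarity is the mean of the strictly
lower triangle of the voxel-voxel Pearson correlation matrix of that
network. Between-network similarity for a pair (i, j) is the mean of the
full voxel-to-voxel cross-correlation matrix between the two networks'
time-series sets. With 15 networks this yields 15 within- plus 105
between-network measures: the 120-element FC feature vector.

Missing or non-finite samples are imputed with the ROI-wise mean (the grand
mean over all finite entries of the network's voxels-by-timepoints block)
before any correlation is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .parcellation import pair_labels


@dataclass
class SubjectTimeseries:
    """Per-network voxels x timepoints matrices for one subject.

    ``blocks`` maps each network name to a 2-D float array. All networks of
    the subject's parcellation must be present, in canonical order, with a
    shared number of timepoints.
    """

    subject_id: str
    network_names: tuple[str, ...]
    blocks: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [n for n in self.network_names if n not in self.blocks]
        if missing:
            raise ValueError(f"subject {self.subject_id} missing networks: {missing}")
        n_t = {np.asarray(self.blocks[n]).shape[1] for n in self.network_names}
        if len(n_t) != 1:
            raise ValueError("all networks must share the same number of timepoints")
        if min(n_t) < 2:
            raise ValueError("at least 2 timepoints required")

    @property
    def n_timepoints(self) -> int:
        return np.asarray(self.blocks[self.network_names[0]]).shape[1]

    def ordered_blocks(self) -> list[np.ndarray]:
        return [np.asarray(self.blocks[n], dtype=float) for n in self.network_names]


@dataclass(frozen=True)
class FCFeatureVector:
    """Similarity values in canonical pair order (upper triangle, row-major)."""

    values: np.ndarray
    pair_labels: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.pair_labels):
            raise ValueError("one value per pair label required")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("similarity values must lie in [-1, 1]")

    def as_series_labels(self) -> list[str]:
        return [f"{a}x{b}" for a, b in self.pair_labels]


def impute_nonfinite(block: np.ndarray, name: str = "ROI") -> np.ndarray:
    """Replace non-finite entries by the mean of the block's finite entries.

    The replacement value is the grand mean over the whole
    voxels x timepoints block of the ROI, so the rule is well defined even
    when a full timepoint (or a full voxel) is missing. Finite entries are
    returned untouched; a block with no finite value is a hard error.
    """
    block = np.asarray(block, dtype=float)
    mask = np.isfinite(block)
    if mask.all():
        return block
    if not mask.any():
        raise ValueError(f"{name}: no finite time-series values to impute from")
    out = block.copy()
    out[~mask] = block[mask].mean()
    return out


def _corr_rows(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize; returns (z, valid) where constant rows are flagged."""
    block = np.asarray(block, dtype=float)
    mu = block.mean(axis=1, keepdims=True)
    centered = block - mu
    sd = centered.std(axis=1)
    valid = sd > 0
    z = np.zeros_like(centered)
    if valid.any():
        z[valid] = centered[valid] / sd[valid, None]
    return z, valid


def _warn_constant(n_bad: int, where: str) -> None:
    warnings.warn(
        f"{n_bad} zero-variance voxel series in {where}; "
        "their correlations are excluded from the similarity average",
        RuntimeWarning,
        stacklevel=3,
    )


def within_network_similarity(block: np.ndarray, name: str = "network") -> float:
    """Mean of the strictly lower triangle of the voxel correlation matrix.

    The self-correlation diagonal is excluded. Voxels with zero temporal
    variance have undefined correlations and are excluded from the average
    (with a warning).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[0] < 2:
        raise ValueError(f"{name}: within-network similarity needs >= 2 voxels")
    if block.shape[1] < 2:
        raise ValueError(f"{name}: at least 2 timepoints required")
    z, valid = _corr_rows(block)
    if (~valid).any():
        _warn_constant(int((~valid).sum()), name)
    zv = z[valid]
    if zv.shape[0] < 2:
        raise ValueError(f"{name}: fewer than 2 voxels with nonzero variance")
    corr = zv @ zv.T / block.shape[1]
    idx = np.tril_indices(zv.shape[0], k=-1)
    return float(np.clip(corr[idx].mean(), -1.0, 1.0))


def between_network_similarity(
    block_a: np.ndarray, block_b: np.ndarray, name: str = "pair"
) -> float:
    """Mean of all |A| x |B| voxel-to-voxel Pearson cross-correlations."""
    block_a = np.asarray(block_a, dtype=float)
    block_b = np.asarray(block_b, dtype=float)
    if block_a.ndim != 2 or block_b.ndim != 2 or not block_a.size or not block_b.size:
        raise ValueError(f"{name}: both blocks need >= 1 voxel")
    if block_a.shape[1] != block_b.shape[1] or block_a.shape[1] < 2:
        raise ValueError(f"{name}: blocks need matching >= 2 timepoints")
    za, va = _corr_rows(block_a)
    zb, vb = _corr_rows(block_b)
    n_bad = int((~va).sum() + (~vb).sum())
    if n_bad:
        _warn_constant(n_bad, name)
    if not va.any() or not vb.any():
        raise ValueError(f"{name}: a block has no voxel with nonzero variance")
    cross = za[va] @ zb[vb].T / block_a.shape[1]
    return float(np.clip(cross.mean(), -1.0, 1.0))


def fc_feature_vector(subject: SubjectTimeseries) -> FCFeatureVector:
    """Full similarity feature vector for one subject.

    Imputation is applied per network block first; the vector then holds the
    within-network similarity in each diagonal slot and the between-network
    similarity in each off-diagonal slot, in canonical pair order.

    Implemented on a single stacked correlation pass for speed; the
    element-wise definition is identical to composing
    :func:`within_network_similarity` / :func:`between_network_similarity`.
    """
    blocks = [
        impute_nonfinite(b, name=n)
        for n, b in zip(subject.network_names, subject.ordered_blocks())
    ]
    values = _fc_from_blocks(blocks, subject.network_names)
    return FCFeatureVector(values=values, pair_labels=pair_labels(subject.network_names))


def _fc_from_blocks(blocks: list[np.ndarray], names: tuple[str, ...]) -> np.ndarray:
    """Stacked-correlation computation of the full feature vector."""
    n_t = blocks[0].shape[1]
    stacked = np.vstack(blocks)
    z, valid = _corr_rows(stacked)
    if (~valid).any():
        _warn_constant(int((~valid).sum()), "stacked blocks")
    corr = z @ z.T / n_t
    sizes = [b.shape[0] for b in blocks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n = len(blocks)
    values = np.empty(n * (n + 1) // 2)
    k = 0
    for i in range(n):
        si = slice(offsets[i], offsets[i + 1])
        vi = valid[si]
        for j in range(i, n):
            sj = slice(offsets[j], offsets[j + 1])
            vj = valid[sj]
            sub = corr[si, sj][np.ix_(vi, vj)]
            if i == j:
                if sub.shape[0] < 2:
                    raise ValueError(
                        f"{names[i]}: fewer than 2 voxels with nonzero variance"
                    )
                tri = np.tril_indices(sub.shape[0], k=-1)
                values[k] = sub[tri].mean()
            else:
                if sub.size == 0:
                    raise ValueError(f"{names[i]}x{names[j]}: no valid voxel pairs")
                values[k] = sub.mean()
            k += 1
    return np.clip(values, -1.0, 1.0)
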