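"""Readers and writers for the pipeline's on-disk formats.

Volumetric data travel as NIfTI (float32 maps, int16 parcellation labels,
identity affine unless one is supplied); per-subject time series and all
tables as CSV; models, metrics and manifests as JSON. Every output
directory gets a reproducibility manifest recording the config hash, seeds,
package version and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .connectivity import FCFeatureVector, SubjectTimeseries
from .parcellation import Parcellation, pair_labels


# --------------------------------------------------------------------------
# NIfTI
# --------------------------------------------------------------------------

def save_map_nifti(path, values: np.ndarray, grid_shape, affine: np.ndarray | None = None) -> None:
    """Write a flat voxel map as a float32 NIfTI volume."""
    vol = np.asarray(values, dtype=np.float32).reshape(grid_shape)
    img = nib.Nifti1Image(vol, np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_map_nifti(path) -> tuple[np.ndarray, tuple[int, ...], np.ndarray]:
    """Read a NIfTI volume: (flat values, grid shape, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return data.ravel(), data.shape, img.affine


def save_parcellation_nifti(path, parcellation: Parcellation, affine: np.ndarray | None = None) -> None:
    """Write the parcellation as an integer label volume (0 = background)."""
    img = nib.Nifti1Image(
        parcellation.label_volume().astype(np.int16),
        np.eye(4) if affine is None else affine,
    )
    nib.save(img, str(path))


def load_parcellation_nifti(path, network_names: tuple[str, ...]) -> Parcellation:
    """Read an integer label volume back into a Parcellation."""
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()).astype(int)
    voxel_ids = []
    flat = labels.ravel()
    for g in range(len(network_names)):
        ids = np.flatnonzero(flat == g + 1)
        voxel_ids.append(ids)
    return Parcellation(
        network_names=tuple(network_names),
        voxel_ids=tuple(voxel_ids),
        grid_shape=labels.shape,
    )


# --------------------------------------------------------------------------
# time series / feature tables
# --------------------------------------------------------------------------

def save_timeseries_csv(path, subject: SubjectTimeseries) -> None:
    """One row per voxel: network, voxel index within network, t0..tN."""
    frames = []
    for name in subject.network_names:
        block = np.asarray(subject.blocks[name])
        df = pd.DataFrame(block, columns=[f"t{t}" for t in range(block.shape[1])])
        df.insert(0, "voxel", np.arange(block.shape[0]))
        df.insert(0, "network", name)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_timeseries_csv(path, subject_id: str, network_names: tuple[str, ...]) -> SubjectTimeseries:
    df = pd.read_csv(path)
    t_cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    t_cols = sorted(t_cols, key=lambda c: int(c[1:]))
    blocks = {}
    for name, grp in df.groupby("network", sort=False):
        blocks[name] = grp.sort_values("voxel")[t_cols].to_numpy(dtype=float)
    return SubjectTimeseries(subject_id=subject_id, network_names=tuple(network_names), blocks=blocks)


def save_feature_table(path, fc_matrix: np.ndarray, labels: tuple[tuple[str, str], ...],
                       subject_ids: list[str]) -> None:
    """Cohort feature CSV: subject_id column + one column per pair label."""
    cols = [f"{a}x{b}" for a, b in labels]
    df = pd.DataFrame(np.asarray(fc_matrix), columns=cols)
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, index=False)


def load_feature_table(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (fc matrix, pair-label strings, subject ids)."""
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    cols = [c for c in df.columns if c != "subject_id"]
    return df[cols].to_numpy(dtype=float), cols, ids


def save_outcomes_csv(path, pfs, os_months, pfs_event, os_event, subject_ids) -> None:
    pd.DataFrame(
        {
            "subject_id": subject_ids,
            "pfs_months": np.asarray(pfs, dtype=float),
            "os_months": np.asarray(os_months, dtype=float),
            "pfs_event": np.asarray(pfs_event, dtype=int),
            "os_event": np.asarray(os_event, dtype=int),
        }
    ).to_csv(path, index=False)


def load_outcomes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=str).encode()
    ).hexdigest()


def update_manifest(out_dir, stage: str, config_dict: dict, seed: int, files: list) -> Path:
    """Record (or extend) the reproducibility manifest for an output directory."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("version", __version__)
    manifest.setdefault("config_sha256", config_hash(config_dict))
    stages = manifest.setdefault("stages", {})
    stages[stage] = {
        "seed": int(seed),
        "outputs": {Path(f).name: _sha256(Path(f)) for f in files},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
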