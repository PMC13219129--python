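"""Declarative run configuration.

One YAML file controls every stage: cohort simulation, outcome coupling,
augmentation ranges, the model search grid, selection size, outcome cap and
the master seed (every stage seed is derived from it). Unknown keys are
rejected with their full key path so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Schema violation in a run configuration file."""


@dataclass
class CohortConfig:
    n_subjects: int = 45
    n_networks: int = 15
    voxels_per_network: int = 12
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_timepoints: int = 300
    rho_within_range: tuple[float, float] = (0.3, 0.7)
    noise_sd: float = 1.0


@dataclass
class OutcomeConfig:
    active_features: tuple[int, ...] | None = None  # None -> package default
    coefficients: tuple[float, ...] | None = None
    link: str = "sigmoid"
    noise_sd: float | None = None  # None -> 9:1 signal:noise variance ratio
    floor: float = 0.5
    event_rate: float = 1.0


@dataclass
class AugmentationConfig:
    timepoint_fraction_range: tuple[float, float] = (0.70, 0.80)
    voxel_fraction_range: tuple[float, float] = (0.70, 0.80)
    n_augmented_range: tuple[int, int] = (10, 500)
    val_fraction_range: tuple[float, float] = (0.05, 0.20)


@dataclass
class ModelSearchConfig:
    widths: tuple[int, ...] = (5, 10, 15)
    losses: tuple[str, ...] = ("mse", "mae", "huber")
    n_restarts: int = 50
    k: int = 15
    max_iterations: int = 500
    tolerance: float = 1e-7
    patience: int = 20
    pfs_cap: float = 24.0


@dataclass
class MapsConfig:
    attenuation: float = 0.7
    prob_noise_sd: float = 0.02
    location_pfs_coupling: float = 4.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "rsnpfs_out"
    verbosity: int = 1
    cohort: CohortConfig = field(default_factory=CohortConfig)
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: ModelSearchConfig = field(default_factory=ModelSearchConfig)
    maps: MapsConfig = field(default_factory=MapsConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "cohort": CohortConfig,
    "outcome": OutcomeConfig,
    "augmentation": AugmentationConfig,
    "model": ModelSearchConfig,
    "maps": MapsConfig,
}

_LIST_FIELDS = {"grid_shape", "rho_within_range", "timepoint_fraction_range",
                "voxel_fraction_range", "n_augmented_range", "val_fraction_range",
                "widths", "losses", "active_features", "coefficients"}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key '{path}{key}'")
    kwargs = {}
    for k, v in data.items():
        if k in _LIST_FIELDS and isinstance(v, (list, tuple)):
            v = tuple(v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid section '{path.rstrip('.')}': {err}") from err


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill gaps."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    top_known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}'")
    kwargs = {}
    for k, v in raw.items():
        if k in _SECTIONS:
            if not isinstance(v, dict):
                raise ConfigError(f"section '{k}' must be a mapping")
            kwargs[k] = _build_section(_SECTIONS[k], v, f"{k}.")
        else:
            kwargs[k] = v
    return RunConfig(**kwargs)


def save_config(path, config: RunConfig) -> None:
    d = config.to_dict()
    Path(path).write_text(yaml.safe_dump(_tuples_to_lists(d), sort_keys=True))


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj
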