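"""Synthetic cohort generator.

No public accession exists for the kind of preoperative glioblastoma
resting-state data this pipeline analyses, so every input the pipeline
consumes can be generated here: a spatially clustered parcellation,
voxelwise time series with planted network covariance, progression-free /
overall survival outcomes nonlinearly coupled to chosen FC features,
network probability maps for a control and a patient group, tumor
segmentation masks, and lesion measurement records.

The time-series model is a latent-signal model: every voxel in network g is

    x_v(t) = sqrt(rho_within_g) * L_g(t) + sqrt(1 - rho_within_g) * noise_sd * eps_v(t)

with unit-variance latent signals L drawn with cross-network correlation
``rho_between`` and i.i.d. standard-normal voxel noise eps. At
``noise_sd = 1`` the expected voxel-pair correlation within network g is
exactly ``rho_within_g`` and between networks (i, j) it is
``sqrt(rho_within_i * rho_within_j) * rho_between[i, j]`` — which makes the
expected FC features analytically available for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .connectivity import SubjectTimeseries, fc_feature_vector
from .parcellation import NETWORK_NAMES, Parcellation, pair_index


# --------------------------------------------------------------------------
# parcellation
# --------------------------------------------------------------------------

def _grow_region(
    rng: np.random.Generator,
    taken: np.ndarray,
    grid_shape: tuple[int, int, int],
    start: int,
    size: int,
) -> np.ndarray:
    """Seeded region growth: a mostly-connected voxel cluster of ``size``."""
    shape = np.asarray(grid_shape)
    region = [start]
    taken[start] = True
    frontier = {start}
    coords_of = lambda f: np.array(np.unravel_index(f, grid_shape))
    while len(region) < size:
        candidates: list[int] = []
        for f in frontier:
            c = coords_of(f)
            for ax in range(3):
                for d in (-1, 1):
                    cc = c.copy()
                    cc[ax] += d
                    if 0 <= cc[ax] < shape[ax]:
                        g = int(np.ravel_multi_index(cc, grid_shape))
                        if not taken[g]:
                            candidates.append(g)
        if candidates:
            pick = int(rng.choice(np.unique(candidates)))
        else:
            # boxed in: jump to the nearest free voxel (keeps determinism)
            free = np.flatnonzero(~taken)
            if free.size == 0:
                raise ValueError("grid exhausted during region growth")
            centroid = np.mean(
                np.array(np.unravel_index(np.array(region), grid_shape)).T, axis=0
            )
            free_coords = np.array(np.unravel_index(free, grid_shape)).T
            pick = int(free[np.argmin(((free_coords - centroid) ** 2).sum(axis=1))])
        taken[pick] = True
        region.append(pick)
        frontier.add(pick)
    return np.sort(np.array(region))


def make_parcellation(
    n_networks: int = 15,
    voxels_per_network: int = 12,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    network_names: tuple[str, ...] | None = None,
) -> Parcellation:
    """Disjoint, spatially clustered voxel sets, one per network.

    Deterministic for a fixed seed. Raises if the grid cannot hold
    ``n_networks * voxels_per_network`` voxels.
    """
    n_grid = int(np.prod(grid_shape))
    if n_grid < n_networks * voxels_per_network:
        raise ValueError(
            f"grid of {n_grid} voxels too small for "
            f"{n_networks} x {voxels_per_network} voxels"
        )
    if network_names is None:
        if n_networks <= len(NETWORK_NAMES):
            network_names = NETWORK_NAMES[:n_networks]
        else:
            network_names = tuple(f"N{i:02d}" for i in range(n_networks))
    rng = np.random.default_rng(seed)
    taken = np.zeros(n_grid, dtype=bool)
    voxel_ids = []
    for _ in range(n_networks):
        free = np.flatnonzero(~taken)
        start = int(rng.choice(free))
        voxel_ids.append(
            _grow_region(rng, taken, grid_shape, start, voxels_per_network)
        )
    return Parcellation(
        network_names=tuple(network_names),
        voxel_ids=tuple(voxel_ids),
        grid_shape=tuple(grid_shape),
    )


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------

@dataclass
class CovarianceSpec:
    """Targets for the planted covariance structure of one subject.

    rho_within:
        Scalar or per-network voxel correlation in [0, 1].
    rho_between:
        Symmetric PSD latent-signal correlation matrix (unit diagonal).
    noise_sd:
        Standard deviation of the voxel noise; at 1.0 the realized
        correlations match the rho targets exactly in expectation.
    n_timepoints:
        Length of the simulated run (frames).
    """

    rho_within: float | np.ndarray = 0.5
    rho_between: np.ndarray | None = None
    noise_sd: float = 1.0
    n_timepoints: int = 300

    def validate(self, n_networks: int) -> None:
        rw = np.broadcast_to(np.asarray(self.rho_within, dtype=float), (n_networks,))
        if (rw < 0).any() or (rw > 1).any():
            raise ValueError("rho_within must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        rb = self.between(n_networks)
        if rb.shape != (n_networks, n_networks):
            raise ValueError("rho_between has wrong shape")
        if not np.allclose(rb, rb.T, atol=1e-10):
            raise ValueError("rho_between must be symmetric")
        if not np.allclose(np.diag(rb), 1.0, atol=1e-10):
            raise ValueError("rho_between must have unit diagonal")
        if np.linalg.eigvalsh(rb).min() < -1e-8:
            raise ValueError("rho_between must be positive semi-definite")

    def between(self, n_networks: int) -> np.ndarray:
        if self.rho_between is None:
            return np.eye(n_networks)
        return np.asarray(self.rho_between, dtype=float)


def simulate_timeseries(
    parcellation: Parcellation,
    spec: CovarianceSpec,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
) -> SubjectTimeseries:
    """Draw one subject's voxelwise time series under the latent-signal model."""
    n = parcellation.n_networks
    spec.validate(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rb = spec.between(n)
    w, v = np.linalg.eigh(rb)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    latents = factor @ rng.standard_normal((n, spec.n_timepoints))
    rho_w = np.broadcast_to(np.asarray(spec.rho_within, dtype=float), (n,))
    blocks: dict[str, np.ndarray] = {}
    for g, name in enumerate(parcellation.network_names):
        n_vox = len(parcellation.voxel_ids[g])
        eps = rng.standard_normal((n_vox, spec.n_timepoints))
        blocks[name] = (
            np.sqrt(rho_w[g]) * latents[g]
            + np.sqrt(1.0 - rho_w[g]) * spec.noise_sd * eps
        )
    return SubjectTimeseries(
        subject_id=subject_id,
        network_names=parcellation.network_names,
        blocks=blocks,
    )


def random_correlation_matrix(
    n: int, rng: np.random.Generator, n_factors: int = 3, scale: float = 0.6
) -> np.ndarray:
    """Random unit-diagonal PSD correlation matrix via a low-rank factor model."""
    b = rng.normal(0.0, scale, size=(n, n_factors))
    c = b @ b.T + np.eye(n)
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def population_factors(
    n_networks: int = 15, n_factors: int = 3, scale: float = 0.6, seed: int = 20240917
) -> np.ndarray:
    """Fixed population-level connectivity modes (factor loadings).

    Cross-subject FC variation in resting-state cohorts is dominated by a
    few population-wide connectivity modes; sharing one loading matrix
    across subjects (with per-subject mode strengths) reproduces that
    low-rank structure. The seed is a structural constant of the generator,
    independent of any cohort seed.
    """
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, scale, size=(n_networks, n_factors))


def sample_subject_cov_spec(
    rng: np.random.Generator,
    n_networks: int,
    rho_within_range: tuple[float, float] = (0.3, 0.7),
    n_timepoints: int = 300,
    noise_sd: float = 1.0,
    base_factors: np.ndarray | None = None,
    loading_sd: float = 0.25,
    idio_sd: float = 0.20,
) -> CovarianceSpec:
    """Per-subject covariance targets: the source of between-subject FC variance.

    With ``base_factors`` (the population modes) the subject's latent
    correlation matrix comes from per-subject mode strengths plus a small
    idiosyncratic loading perturbation — cross-subject feature variation is
    then low-rank plus noise, as in real cohorts. Without it, each subject
    draws an independent random correlation matrix.
    """
    rho_w = rng.uniform(*rho_within_range, size=n_networks)
    if base_factors is None:
        rb = random_correlation_matrix(n_networks, rng)
    else:
        gains = 1.0 + rng.normal(0.0, loading_sd, size=(1, base_factors.shape[1]))
        b = base_factors * gains + rng.normal(0.0, idio_sd, size=base_factors.shape)
        c = b @ b.T + np.eye(n_networks)
        d = np.sqrt(np.diag(c))
        rb = c / np.outer(d, d)
    return CovarianceSpec(
        rho_within=rho_w, rho_between=rb, noise_sd=noise_sd, n_timepoints=n_timepoints
    )


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

#: Default planted predictors: five cross-network pairs linking thalamic and
#: association systems, expressed as canonical indices into the 120-vector.
DEFAULT_ACTIVE_FEATURES: tuple[int, ...] = tuple(
    pair_index(NETWORK_NAMES, a, b)
    for a, b in [
        ("SMD", "VAN"),
        ("SMI", "VIS"),
        ("DMN", "VAN"),
        ("PMN", "THA"),
        ("MTL", "THA"),
    ]
)


@dataclass
class OutcomeSpec:
    """How PFS/OS outcomes are coupled to the FC features.

    The planted signal is a weighted sum of the z-scored active features
    passed through a smooth saturating link. With ``noise_sd=None`` the
    noise level is set so the signal-to-noise variance ratio is 9:1
    (generative R^2 of 0.9). The default sigmoid steepness and shift are
    calibrated so the simulated cohort reproduces the target PFS
    distribution of a 45-patient glioblastoma cohort (median ~7, standard
    deviation ~5.5 months, right-skewed with rare long survivors near the
    24-month clip).
    """

    active_features: tuple[int, ...] = DEFAULT_ACTIVE_FEATURES
    coefficients: tuple[float, ...] = (1.0, -0.9, 0.8, -0.7, 0.6)
    link: str = "knee"  # "knee", "sigmoid" or "identity"
    noise_sd: float | None = None  # months; None -> 9:1 signal:noise variance
    floor: float = 0.5  # months; minimum physical PFS
    span: float = 23.5  # months; sigmoid output range above the floor
    steepness: float = 1.3
    shift: float = -1.0
    knee_base: float = 3.7  # months above the floor for low-index subjects
    knee_scale: float = 3.0
    knee_threshold: float = -0.8
    knee_softness: float = 3.0
    event_rate: float = 1.0
    os_extra_scale: float = 8.0  # months; mean OS excess over PFS

    def validate(self, n_features: int) -> None:
        if not self.active_features:
            raise ValueError("active feature set must be non-empty")
        if len(self.active_features) != len(self.coefficients):
            raise ValueError("one coefficient per active feature required")
        if any(i < 0 or i >= n_features for i in self.active_features):
            raise ValueError(f"active feature indices must lie in [0, {n_features})")
        if not (0.0 < self.event_rate <= 1.0):
            raise ValueError("event_rate must lie in (0, 1]")
        if self.floor <= 0:
            raise ValueError("PFS floor must be positive")
        if self.link not in ("knee", "sigmoid", "identity"):
            raise ValueError(f"unknown link: {self.link}")


def outcome_signal(fc: np.ndarray, spec: OutcomeSpec) -> np.ndarray:
    """Noiseless PFS signal (months) for a cohort feature matrix (n x p)."""
    fc = np.asarray(fc, dtype=float)
    spec.validate(fc.shape[1])
    cols = fc[:, list(spec.active_features)]
    sd = cols.std(axis=0)
    if (sd == 0).any():
        raise ValueError("an active feature is constant across the cohort")
    z = (cols - cols.mean(axis=0)) / sd
    s = z @ np.asarray(spec.coefficients)
    s_sd = s.std()
    if s_sd == 0:
        raise ValueError("planted signal has zero variance")
    u = s / s_sd
    if spec.link == "sigmoid":
        return spec.floor + spec.span * expit(spec.steepness * u + spec.shift)
    if spec.link == "knee":
        # flat near the floor below the threshold, rising sharply above it:
        # a smooth threshold-saturation response (saturating at the low end,
        # with long-survivor outliers handled by the pipeline's 24-month clip)
        k = spec.knee_softness
        soft = np.log1p(np.exp(np.clip(k * (u - spec.knee_threshold), -500, 500))) / k
        return spec.floor + spec.knee_base + spec.knee_scale * soft**2
    return 10.0 + 3.0 * u  # identity link: affine in the standardized score


def plant_outcome(
    fc: np.ndarray, spec: OutcomeSpec, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate (pfs_months, os_months, pfs_event, os_event) from FC features.

    PFS is the planted signal plus Gaussian noise, floored at ``spec.floor``
    months; OS is PFS plus an exponential excess, so OS >= PFS always.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal = outcome_signal(fc, spec)
    noise_sd = spec.noise_sd
    if noise_sd is None:
        noise_sd = signal.std() / 3.0  # variance ratio 9:1
    pfs = np.maximum(signal + rng.normal(0.0, noise_sd, size=signal.shape), spec.floor)
    os_months = pfs + rng.exponential(spec.os_extra_scale, size=signal.shape)
    pfs_event = (rng.random(signal.shape) < spec.event_rate).astype(int)
    os_event = (rng.random(signal.shape) < spec.event_rate).astype(int)
    return pfs, os_months, pfs_event, os_event


# --------------------------------------------------------------------------
# probability maps, segmentations, lesions
# --------------------------------------------------------------------------

def simulate_probability_maps(
    parcellation: Parcellation,
    attenuation: float | np.ndarray = 1.0,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.0,
    support_range: tuple[float, float] = (0.82, 0.98),
    background_level: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Control and patient RSN probability maps (n_networks x n_voxels).

    Control maps carry high probabilities (> 0.8) on each network's own
    support and a low background elsewhere. Patient maps are
    ``attenuation * control + noise``, clipped to [0, 1] — emulating the
    globally reduced network probabilities seen in tumor cohorts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = parcellation.n_networks
    n_vox = int(np.prod(parcellation.grid_shape))
    att = np.broadcast_to(np.asarray(attenuation, dtype=float), (n,))
    if (att <= 0).any() or (att > 1).any():
        raise ValueError("attenuation factors must lie in (0, 1]")
    control = rng.uniform(0.0, background_level, size=(n, n_vox))
    for g in range(n):
        ids = parcellation.voxel_ids[g]
        control[g, ids] = rng.uniform(*support_range, size=len(ids))
    patient = att[:, None] * control
    if noise_sd > 0:
        patient = patient + rng.normal(0.0, noise_sd, size=patient.shape)
    return np.clip(control, 0.0, 1.0), np.clip(patient, 0.0, 1.0)


def simulate_segmentations(
    n_subjects: int,
    parcellation: Parcellation,
    location_pfs_coupling: float = 4.0,
    short_pfs_networks: tuple[str, ...] = ("DAN", "VIS", "FPN", "DMN"),
    tumor_size_range: tuple[int, int] = (20, 60),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Connected binary tumor masks plus linked PFS shifts (months).

    Subjects whose tumor overlaps the designated short-PFS networks receive
    a negative shift proportional to the overlap fraction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_vox = int(np.prod(parcellation.grid_shape))
    short_ids = np.concatenate(
        [parcellation.voxels(n) for n in short_pfs_networks if n in parcellation.network_names]
    )
    short_mask = np.zeros(n_vox, dtype=bool)
    short_mask[short_ids] = True
    masks = np.zeros((n_subjects, n_vox), dtype=bool)
    shifts = np.zeros(n_subjects)
    for s in range(n_subjects):
        size = int(rng.integers(tumor_size_range[0], tumor_size_range[1] + 1))
        taken = np.zeros(n_vox, dtype=bool)  # per-tumor scratch: tumors may overlap
        start = int(rng.integers(0, n_vox))
        region = _grow_region(rng, taken, parcellation.grid_shape, start, size)
        masks[s, region] = True
        overlap = short_mask[region].mean()
        shifts[s] = -location_pfs_coupling * overlap
    return masks, shifts


def make_lesion_records(case_spec: list[dict]) -> pd.DataFrame:
    """Lesion measurement table for the RANO stage.

    Each case dict carries ``diameters_mm`` (two perpendicular diameters),
    ``axial_slices``, and optionally ``enhancing`` (default True),
    ``timepoint`` (default "baseline") and ``subject_id`` (default "s0").
    """
    rows = []
    for case in case_spec:
        d1, d2 = case["diameters_mm"]
        if d1 <= 0 or d2 <= 0:
            raise ValueError("lesion diameters must be positive")
        if case["axial_slices"] < 1:
            raise ValueError("axial slice count must be >= 1")
        rows.append(
            {
                "subject_id": case.get("subject_id", "s0"),
                "timepoint": case.get("timepoint", "baseline"),
                "diameter1_mm": float(d1),
                "diameter2_mm": float(d2),
                "axial_slices": int(case["axial_slices"]),
                "enhancing": bool(case.get("enhancing", True)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def make_cohort(
    n_subjects: int = 45,
    parcellation: Parcellation | None = None,
    outcome_spec: OutcomeSpec | None = None,
    n_timepoints: int = 300,
    rho_within_range: tuple[float, float] = (0.3, 0.7),
    noise_sd: float = 1.0,
    seed: int = 0,
    loading_sd: float = 0.25,
    idio_sd: float = 0.20,
):
    """Full synthetic study cohort: time series, FC features and outcomes.

    Defaults emulate the study conditions: 45 subjects, 15 networks (120 FC
    features), five active features coupled to PFS through a saturating
    nonlinear link with a 9:1 signal-to-noise variance ratio, PFS clipped
    later at 24 months by the pipeline. Deterministic for a fixed seed.
    """
    from .pipeline import Cohort  # deferred import: pipeline owns the container

    ss = np.random.SeedSequence(seed)
    parc_seed, *subject_seeds = ss.spawn(1 + n_subjects)
    outcome_seed = ss.spawn(1)[0]
    if parcellation is None:
        parcellation = make_parcellation(seed=int(parc_seed.generate_state(1)[0] % 2**31))
    if outcome_spec is None:
        outcome_spec = OutcomeSpec()
    base_factors = population_factors(parcellation.n_networks)
    subjects = []
    fc_rows = []
    for i, child in enumerate(subject_seeds):
        rng = np.random.default_rng(child)
        spec = sample_subject_cov_spec(
            rng,
            parcellation.n_networks,
            rho_within_range=rho_within_range,
            n_timepoints=n_timepoints,
            noise_sd=noise_sd,
            base_factors=base_factors,
            loading_sd=loading_sd,
            idio_sd=idio_sd,
        )
        subj = simulate_timeseries(parcellation, spec, seed=rng, subject_id=f"sub-{i:03d}")
        subjects.append(subj)
        fc_rows.append(fc_feature_vector(subj).values)
    fc = np.vstack(fc_rows)
    pfs, os_months, pfs_event, os_event = plant_outcome(
        fc, outcome_spec, seed=np.random.default_rng(outcome_seed)
    )
    return Cohort(
        subjects=subjects,
        pfs_months=pfs,
        os_months=os_months,
        pfs_event=pfs_event,
        os_event=os_event,
        parcellation=parcellation,
    )
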