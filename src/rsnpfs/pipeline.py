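"""End-to-end PFS prediction pipeline.

Leave-one-out cross-validation with, inside every fold: MRMR feature
selection on the fold's training subjects only, FC-level data augmentation
(subsampling 70-80% of timepoints and of voxels per network, recomputing
the feature vector), a validation split drawn from the augmented samples,
a hyperparameter search over the feed-forward regressor, and a prediction
for the held-out subject from its full-data features restricted to the
fold's selected features. A linear least-squares baseline shares the exact
fold structure and selected features for comparison.

Outcomes are clipped at 24 months before any modeling, mirroring the
handling of long-PFS outliers in small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ann import ModelConfig, TrainedModel, forward, hyperparameter_search
from .connectivity import FCFeatureVector, SubjectTimeseries, fc_feature_vector
from .parcellation import Parcellation
from .selection import FeatureRanking, mrmr_rank

PFS_CAP_MONTHS = 24.0


@dataclass
class Cohort:
    """Subjects with raw time series (or precomputed FC) plus outcomes."""

    subjects: list
    pfs_months: np.ndarray
    os_months: np.ndarray
    pfs_event: np.ndarray
    os_event: np.ndarray
    parcellation: Parcellation | None = None
    _fc_cache: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.subjects)
        for name in ("pfs_months", "os_months", "pfs_event", "os_event"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length does not match number of subjects")
            setattr(self, name, arr)
        if (self.pfs_months <= 0).any():
            raise ValueError("all PFS values must be positive")
        if (self.os_months < self.pfs_months - 1e-9).any():
            raise ValueError("OS must be >= PFS for every subject")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def has_raw_timeseries(self) -> bool:
        return all(isinstance(s, SubjectTimeseries) for s in self.subjects)

    def fc_matrix(self) -> np.ndarray:
        """Full-data FC feature matrix (n_subjects x n_features), cached."""
        if self._fc_cache is None:
            rows = []
            for s in self.subjects:
                if isinstance(s, SubjectTimeseries):
                    rows.append(fc_feature_vector(s).values)
                elif isinstance(s, FCFeatureVector):
                    rows.append(np.asarray(s.values, dtype=float))
                else:
                    rows.append(np.asarray(s, dtype=float))
            self._fc_cache = np.vstack(rows)
        return self._fc_cache


@dataclass(frozen=True)
class AugmentationSpec:
    """Ranges of the FC-level augmentation draws.

    Per augmented sample, a timepoint fraction and a voxel fraction are
    drawn uniformly from 70-80%; per optimization cycle, the number of
    augmented samples is drawn from 10-500 and a 5-20% validation subset is
    reserved for training termination.
    """

    timepoint_fraction_range: tuple[float, float] = (0.70, 0.80)
    voxel_fraction_range: tuple[float, float] = (0.70, 0.80)
    n_augmented_range: tuple[int, int] = (10, 500)
    val_fraction_range: tuple[float, float] = (0.05, 0.20)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.timepoint_fraction_range,
            self.voxel_fraction_range,
            self.val_fraction_range,
        ):
            if not (0 < lo <= hi <= 1):
                raise ValueError("fraction ranges must be ordered within (0, 1]")
        lo, hi = self.n_augmented_range
        if not (1 <= lo <= hi):
            raise ValueError("n_augmented_range must be ordered and >= 1")


@dataclass
class TrainingSet:
    """Augmented design with its validation split and source bookkeeping."""

    train_x: np.ndarray
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    train_sources: list[str]
    val_sources: list[str]


@dataclass
class PredictionResult:
    """Per-subject LOOCV predictions and the headline metrics."""

    predictions: np.ndarray
    actual: np.ndarray
    rmse: float
    mae: float
    r_squared: float
    p_value: float
    fold_rankings: list[FeatureRanking] = field(default_factory=list, repr=False)


def clip_outcomes(pfs_months: np.ndarray, cap: float = PFS_CAP_MONTHS) -> np.ndarray:
    """Clip outcome outliers at ``cap`` months (elementwise minimum)."""
    pfs = np.asarray(pfs_months, dtype=float)
    if (pfs <= 0).any():
        raise ValueError("PFS values must be positive")
    return np.minimum(pfs, cap)


def _subsample_counts(n: int, frac: float) -> int:
    return int(round(frac * n))


def augment_subject(
    subject: SubjectTimeseries,
    spec: AugmentationSpec,
    rng: np.random.Generator,
) -> FCFeatureVector:
    """One augmented feature vector from a subject's raw time series.

    Draws a timepoint fraction and a voxel fraction, subsamples without
    replacement, and recomputes the full feature vector on the subsample.
    The original subject is untouched. If a draw leaves fewer than 2
    timepoints or 2 voxels in any network, fractions are redrawn once; a
    second failure is an error.
    """
    if not isinstance(subject, SubjectTimeseries):
        raise TypeError("augmentation requires raw time series, not precomputed features")
    n_t = subject.n_timepoints
    blocks = subject.ordered_blocks()
    for attempt in range(2):
        tf = rng.uniform(*spec.timepoint_fraction_range)
        vf = rng.uniform(*spec.voxel_fraction_range)
        keep_t = _subsample_counts(n_t, tf)
        keep_v = [_subsample_counts(b.shape[0], vf) for b in blocks]
        if keep_t >= 2 and min(keep_v) >= 2:
            break
        if attempt == 1:
            raise ValueError(
                "augmentation subsample leaves <2 timepoints or <2 voxels in a network"
            )
    t_idx = np.sort(rng.choice(n_t, size=keep_t, replace=False))
    sub_blocks = {}
    for name, block, kv in zip(subject.network_names, blocks, keep_v):
        v_idx = np.sort(rng.choice(block.shape[0], size=kv, replace=False))
        sub_blocks[name] = block[np.ix_(v_idx, t_idx)]
    sub = SubjectTimeseries(
        subject_id=subject.subject_id,
        network_names=subject.network_names,
        blocks=sub_blocks,
    )
    return fc_feature_vector(sub)


def draw_validation_subjects(
    n_subjects: int, spec: AugmentationSpec, rng: np.random.Generator
) -> set[int]:
    """Pick the 5-20% of training-subject indices reserved for validation."""
    if n_subjects < 2:
        raise ValueError("need >= 2 training subjects to split off validation")
    val_frac = rng.uniform(*spec.val_fraction_range)
    n_val = min(max(1, int(round(val_frac * n_subjects))), n_subjects - 1)
    return set(rng.choice(n_subjects, size=n_val, replace=False).tolist())


def build_training_set(
    train_subjects: list[SubjectTimeseries],
    train_targets: np.ndarray,
    spec: AugmentationSpec,
    rng: np.random.Generator,
    feature_idx: np.ndarray | None = None,
    val_subjects: set[int] | None = None,
) -> TrainingSet:
    """Augmented training design plus a disjoint validation subset.

    Augmented samples inherit the (clipped) PFS of their source subject.
    Sources cycle through the training subjects in a random order, so every
    subject is covered as evenly as the draw of the augmented count allows.
    The validation subset is grouped by source subject (5-20% of the
    training subjects contribute only validation rows), so the validation
    loss measures cross-subject generalization rather than reconstruction
    of already-seen subjects. ``val_subjects`` fixes the validation group
    externally (the LOOCV driver draws it once per fold so that restarts
    are scored on the same subjects); by default it is drawn here. Only the
    given training subjects contribute; the held-out LOOCV subject must not
    be in the list.
    """
    train_targets = np.asarray(train_targets, dtype=float)
    n_subj = len(train_subjects)
    if n_subj != len(train_targets):
        raise ValueError("one target per training subject required")
    lo, hi = spec.n_augmented_range
    n_aug = int(rng.integers(lo, hi + 1))
    order = rng.permutation(n_subj)
    sources = np.array([order[t % n_subj] for t in range(n_aug)])
    feats = []
    for j in sources:
        v = augment_subject(train_subjects[j], spec, rng).values
        feats.append(v if feature_idx is None else v[feature_idx])
    x = np.vstack(feats)
    y = train_targets[sources]
    ids = [train_subjects[j].subject_id for j in sources]
    if val_subjects is None:
        val_subjects = draw_validation_subjects(n_subj, spec, rng)
    elif not val_subjects or not set(val_subjects) < set(range(n_subj)):
        raise ValueError("val_subjects must be a proper non-empty subset of train indices")
    is_val = np.array([s in val_subjects for s in sources])
    # a small augmented draw may not reach both groups: top up with one extra
    # augmented row from the missing group's subjects (never by reassignment)
    for need_val, pool in ((True, sorted(val_subjects)),
                           (False, sorted(set(range(n_subj)) - set(val_subjects)))):
        if not (is_val == need_val).any():
            j = int(rng.choice(pool))
            v = augment_subject(train_subjects[j], spec, rng).values
            x = np.vstack([x, v if feature_idx is None else v[feature_idx]])
            y = np.append(y, train_targets[j])
            ids.append(train_subjects[j].subject_id)
            is_val = np.append(is_val, need_val)
    val_i = np.flatnonzero(is_val)
    tr_i = np.flatnonzero(~is_val)
    return TrainingSet(
        train_x=x[tr_i],
        train_y=y[tr_i],
        val_x=x[val_i],
        val_y=y[val_i],
        train_sources=[ids[i] for i in tr_i],
        val_sources=[ids[i] for i in val_i],
    )


def compute_metrics(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float, float]:
    """(RMSE, MAE, R^2, p) where R^2 is the coefficient of determination
    and p is the two-sided test of zero correlation between actual and
    predicted values."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must be aligned")
    resid = a - p
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual values are constant; R^2 undefined")
    r2 = float(1.0 - np.sum(resid**2) / ss_tot)
    if np.std(p) == 0:
        pval = 1.0
    else:
        pval = float(stats.pearsonr(a, p).pvalue)
    return rmse, mae, r2, pval


def default_search_grid(
    widths: tuple[int, ...] = (5, 10, 15),
    losses: tuple[str, ...] = ("mse", "mae", "huber"),
    input_dim: int = 15,
    max_iterations: int = 500,
    tolerance: float = 1e-7,
    patience: int = 20,
) -> list[ModelConfig]:
    return [
        ModelConfig(
            input_dim=input_dim,
            hidden_sizes=(w, w, w),
            loss_kind=l,
            max_iterations=max_iterations,
            tolerance=tolerance,
            patience=patience,
        )
        for w in widths
        for l in losses
    ]


def _fold_seed_sequence(seed: int, fold: int) -> np.random.SeedSequence:
    # fold seeds depend only on (seed, fold index), never on the data
    return np.random.SeedSequence(entropy=seed, spawn_key=(fold,))


def loocv_run(
    cohort: Cohort,
    search_grid: list[ModelConfig] | None = None,
    aug_spec: AugmentationSpec | None = None,
    k: int = 15,
    n_restarts: int = 50,
    seed: int = 0,
    cap: float = PFS_CAP_MONTHS,
) -> PredictionResult:
    """Nested leave-one-out run of the full ANN pipeline.

    Per fold: the held-out subject is excluded before feature ranking; MRMR
    runs on the remaining subjects' full-data FC vectors; augmented
    training/validation sets are built from those subjects only, restricted
    to the selected features; the hyperparameter search picks the best
    model; the held-out subject is predicted from its full-data features.
    """
    if len(cohort) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if not cohort.has_raw_timeseries:
        raise ValueError("loocv_run requires raw time series (augmentation needs them)")
    aug_spec = aug_spec or AugmentationSpec()
    fc = cohort.fc_matrix()
    if search_grid is None:
        search_grid = default_search_grid(input_dim=k)
    for cfg in search_grid:
        if cfg.input_dim != k:
            raise ValueError("search grid input_dim must equal the selection size k")
    y = clip_outcomes(cohort.pfs_months, cap)
    n = len(cohort)
    preds = np.empty(n)
    rankings: list[FeatureRanking] = []
    for i in range(n):
        tr = np.array([j for j in range(n) if j != i])
        try:
            ranking = mrmr_rank(fc[tr], y[tr], k=k)
            sel = ranking.selected
            train_subjects = [cohort.subjects[j] for j in tr]
            train_targets = y[tr]
            fold_ss = _fold_seed_sequence(seed, i)
            val_ss, search_ss = fold_ss.spawn(2)
            # validation subjects fixed per fold: every restart is scored on
            # the same held-back subjects, making scores comparable
            val_subjects = draw_validation_subjects(
                len(tr), aug_spec, np.random.default_rng(val_ss)
            )

            def builder(rng, _subj=train_subjects, _tgt=train_targets, _sel=sel,
                        _val=val_subjects):
                ts = build_training_set(
                    _subj, _tgt, aug_spec, rng, feature_idx=_sel, val_subjects=_val
                )
                return ts.train_x, ts.train_y, ts.val_x, ts.val_y

            fold_seed = int(search_ss.generate_state(1)[0] % 2**31)
            best, _trace = hyperparameter_search(
                search_grid, builder, n_restarts=n_restarts, seed=fold_seed
            )
            preds[i] = forward(best, fc[i, sel][None, :])[0]
            rankings.append(ranking)
        except Exception as err:
            raise RuntimeError(f"LOOCV fold {i} failed: {err}") from err
    rmse, mae, r2, pval = compute_metrics(y, preds)
    return PredictionResult(
        predictions=preds,
        actual=y,
        rmse=rmse,
        mae=mae,
        r_squared=r2,
        p_value=pval,
        fold_rankings=rankings,
    )


def linear_baseline(
    cohort: Cohort,
    k: int = 15,
    seed: int = 0,
    cap: float = PFS_CAP_MONTHS,
) -> PredictionResult:
    """Ordinary least squares under the identical LOOCV fold structure.

    Uses the same per-fold MRMR-selected full-data features as
    :func:`loocv_run` (selection is deterministic given the fold data), with
    no augmentation.
    """
    if len(cohort) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    fc = cohort.fc_matrix()
    y = clip_outcomes(cohort.pfs_months, cap)
    n = len(cohort)
    preds = np.empty(n)
    rankings: list[FeatureRanking] = []
    for i in range(n):
        tr = np.array([j for j in range(n) if j != i])
        ranking = mrmr_rank(fc[tr], y[tr], k=k)
        sel = ranking.selected
        design = np.column_stack([np.ones(len(tr)), fc[tr][:, sel]])
        coef, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
        preds[i] = float(np.concatenate([[1.0], fc[i, sel]]) @ coef)
        rankings.append(ranking)
    rmse, mae, r2, pval = compute_metrics(y, preds)
    return PredictionResult(
        predictions=preds,
        actual=y,
        rmse=rmse,
        mae=mae,
        r_squared=r2,
        p_value=pval,
        fold_rankings=rankings,
    )
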