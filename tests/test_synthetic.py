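"""Synthetic generators: determinism, planted covariance, planted outcomes."""

import numpy as np
import pytest

from rsnpfs.connectivity import fc_feature_vector
from rsnpfs.maps import cliffs_delta
from rsnpfs.parcellation import pair_index
from rsnpfs.synthetic import (
    CovarianceSpec,
    OutcomeSpec,
    make_cohort,
    make_lesion_records,
    make_parcellation,
    outcome_signal,
    plant_outcome,
    simulate_probability_maps,
    simulate_segmentations,
    simulate_timeseries,
)


class TestParcellation:
    def test_counts_and_disjointness(self):
        parc = make_parcellation(15, 40, (20, 20, 20), seed=1)
        assert parc.n_networks == 15
        all_ids = np.concatenate(parc.voxel_ids)
        assert all(len(v) == 40 for v in parc.voxel_ids)
        assert len(np.unique(all_ids)) == 15 * 40

    def test_small_grid_distinct_ids(self):
        parc = make_parcellation(2, 3, (3, 3, 3), seed=7)
        all_ids = np.concatenate(parc.voxel_ids)
        assert len(np.unique(all_ids)) == 6

    def test_deterministic_for_fixed_seed(self):
        a = make_parcellation(4, 10, (10, 10, 10), seed=1)
        b = make_parcellation(4, 10, (10, 10, 10), seed=1)
        for va, vb in zip(a.voxel_ids, b.voxel_ids):
            assert np.array_equal(va, vb)

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            make_parcellation(5, 10, (3, 3, 3), seed=0)


class TestTimeseries:
    def test_degenerate_limit_identical_series(self, small_parcellation):
        spec = CovarianceSpec(rho_within=1.0, noise_sd=1.0, n_timepoints=30)
        subj = simulate_timeseries(small_parcellation, spec, seed=2)
        for name in subj.network_names:
            block = subj.blocks[name]
            assert np.allclose(block, block[0])

    def test_identity_between_correlation_near_zero(self):
        parc = make_parcellation(5, 8, (10, 10, 10), seed=3)
        spec = CovarianceSpec(rho_within=0.6, n_timepoints=4000)
        subj = simulate_timeseries(parc, spec, seed=4)
        vec = fc_feature_vector(subj)
        between = [
            v for v, (a, b) in zip(vec.values, vec.pair_labels) if a != b
        ]
        assert np.max(np.abs(between)) < 0.05

    def test_within_similarity_converges_to_target(self):
        parc = make_parcellation(3, 10, (8, 8, 8), seed=5)
        spec = CovarianceSpec(rho_within=0.8, n_timepoints=4000)
        subj = simulate_timeseries(parc, spec, seed=6)
        vec = fc_feature_vector(subj)
        within = [v for v, (a, b) in zip(vec.values, vec.pair_labels) if a == b]
        assert np.allclose(within, 0.8, atol=0.05)

    def test_non_psd_between_rejected(self, small_parcellation):
        bad = np.eye(15)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        spec = CovarianceSpec(rho_between=bad)
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_timeseries(small_parcellation, spec, seed=0)


class TestPlantedOutcome:
    def test_identity_link_monotone_and_deterministic(self, rng):
        fc = rng.uniform(-1, 1, size=(30, 10))
        spec = OutcomeSpec(
            active_features=(4,), coefficients=(1.0,), link="identity", noise_sd=0.0
        )
        pfs, _, _, _ = plant_outcome(fc, spec, seed=0)
        order = np.argsort(fc[:, 4])
        assert np.all(np.diff(pfs[order]) >= 0)

    def test_event_rate_one_sets_all_flags(self, rng):
        fc = rng.uniform(-1, 1, size=(20, 10))
        spec = OutcomeSpec(active_features=(0, 1), coefficients=(1.0, -1.0), event_rate=1.0)
        _, _, pfs_event, os_event = plant_outcome(fc, spec, seed=1)
        assert pfs_event.all() and os_event.all()

    def test_os_dominates_pfs_and_positivity(self, rng):
        fc = rng.uniform(-1, 1, size=(50, 12))
        spec = OutcomeSpec(active_features=(2, 5), coefficients=(1.0, 0.5))
        pfs, os_months, _, _ = plant_outcome(fc, spec, seed=3)
        assert (pfs > 0).all()
        assert (os_months >= pfs).all()

    def test_nine_to_one_noise_calibration(self, rng):
        # oracle: regress the generated PFS on the known noiseless signal at n=2000
        fc = rng.uniform(-1, 1, size=(2000, 8))
        spec = OutcomeSpec(active_features=(0, 3), coefficients=(1.0, -0.8))
        pfs, _, _, _ = plant_outcome(fc, spec, seed=4)
        signal = outcome_signal(fc, spec)
        design = np.column_stack([np.ones(len(signal)), signal])
        coef, *_ = np.linalg.lstsq(design, pfs, rcond=None)
        fitted = design @ coef
        r2 = 1 - np.sum((pfs - fitted) ** 2) / np.sum((pfs - pfs.mean()) ** 2)
        assert r2 == pytest.approx(0.9, abs=0.03)

    def test_empty_active_set_rejected(self, rng):
        fc = rng.uniform(-1, 1, size=(10, 5))
        with pytest.raises(ValueError, match="non-empty"):
            plant_outcome(fc, OutcomeSpec(active_features=(), coefficients=()), seed=0)


class TestProbabilityMaps:
    def test_no_attenuation_zero_delta(self, small_parcellation):
        control, patient = simulate_probability_maps(
            small_parcellation, attenuation=1.0, seed=0, noise_sd=0.0
        )
        assert np.array_equal(control, patient)
        for g, ids in enumerate(small_parcellation.voxel_ids):
            assert cliffs_delta(control[g, ids], patient[g, ids]) == 0.0

    def test_attenuated_network_has_largest_delta(self, small_parcellation):
        att = np.ones(15)
        att[3] = 0.2
        control, patient = simulate_probability_maps(
            small_parcellation, attenuation=att, seed=1, noise_sd=0.0
        )
        deltas = [
            cliffs_delta(control[g, ids], patient[g, ids])
            for g, ids in enumerate(small_parcellation.voxel_ids)
        ]
        assert np.argmax(deltas) == 3

    def test_two_network_toy_delta_oracle(self):
        parc = make_parcellation(2, 20, (6, 6, 6), seed=2)
        control, patient = simulate_probability_maps(
            parc, attenuation=np.array([1.0, 0.5]), seed=3, noise_sd=0.0
        )
        ids0, ids1 = parc.voxel_ids
        # exhaustive pairwise enumeration oracle
        def enum_delta(a, b):
            gt = sum(1 for x in a for y in b if x > y)
            lt = sum(1 for x in a for y in b if x < y)
            return (gt - lt) / (len(a) * len(b))

        assert cliffs_delta(control[0, ids0], patient[0, ids0]) == enum_delta(
            control[0, ids0], patient[0, ids0]
        ) == 0.0
        d1 = cliffs_delta(control[1, ids1], patient[1, ids1])
        assert d1 == enum_delta(control[1, ids1], patient[1, ids1])
        assert d1 > 0


class TestSegmentationsAndLesions:
    def test_masks_deterministic_and_coupled(self, small_parcellation):
        masks, shifts = simulate_segmentations(8, small_parcellation, seed=4)
        masks2, shifts2 = simulate_segmentations(8, small_parcellation, seed=4)
        assert np.array_equal(masks, masks2) and np.array_equal(shifts, shifts2)
        # oracle: shift proportional to overlap with the short-PFS networks
        short = np.zeros(masks.shape[1], dtype=bool)
        for name in ("DAN", "VIS", "FPN", "DMN"):
            short[small_parcellation.voxels(name)] = True
        for m, s in zip(masks, shifts):
            overlap = short[m].mean() if m.any() else 0.0
            assert s == pytest.approx(-4.0 * overlap)
        assert (shifts <= 0).all()

    def test_lesion_record_fixture(self):
        df = make_lesion_records(
            [{"diameters_mm": (12, 15), "axial_slices": 3}]
        )
        assert len(df) == 1
        row = df.iloc[0]
        assert row.diameter1_mm == 12 and row.axial_slices == 3 and row.enhancing


class TestCohort:
    def test_cohort_reproducible_and_valid(self, small_parcellation):
        a = make_cohort(n_subjects=5, parcellation=small_parcellation, n_timepoints=60, seed=9)
        b = make_cohort(n_subjects=5, parcellation=small_parcellation, n_timepoints=60, seed=9)
        assert np.array_equal(a.pfs_months, b.pfs_months)
        assert np.array_equal(a.fc_matrix(), b.fc_matrix())
        assert (a.pfs_months > 0).all()
        assert (a.os_months >= a.pfs_months).all()
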