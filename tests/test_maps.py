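"""Map-level analyses: frequency, PFS association, Cliff's delta, projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsnpfs.maps import (
    average_map_per_network,
    average_network_feature_weights,
    cliffs_delta,
    delta_magnitude_label,
    network_effect_sizes,
    project_weights_to_voxels,
    tumor_frequency_map,
    voxelwise_pfs_association,
)
from rsnpfs.parcellation import pair_labels
from rsnpfs.synthetic import make_parcellation, simulate_probability_maps


def enum_delta(a, b):
    """Exhaustive O(|A||B|) pair enumeration oracle."""
    gt = sum(1 for x in a for y in b if x > y)
    lt = sum(1 for x in a for y in b if x < y)
    return (gt - lt) / (len(a) * len(b))


class TestTumorFrequency:
    def test_identical_masks(self, rng):
        mask = (rng.random(50) < 0.3).astype(float)
        freq = tumor_frequency_map([mask, mask, mask])
        assert np.array_equal(freq, mask)

    def test_disjoint_masks(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        assert np.array_equal(tumor_frequency_map([a, b]), [0.5, 0.5, 0.5, 0.5])

    def test_voxelwise_sum_oracle(self, rng):
        masks = (rng.random((10, 64)) < 0.2).astype(float)
        assert np.allclose(tumor_frequency_map(masks), masks.sum(axis=0) / 10)

    def test_linear_in_mask_addition(self, rng):
        masks = (rng.random((4, 30)) < 0.4).astype(float)
        f4 = tumor_frequency_map(masks)
        assert np.allclose(f4, np.mean([tumor_frequency_map([m]) for m in masks], axis=0))


class TestPfsAssociation:
    def test_identical_tumors_all_sentinel(self):
        mask = np.tile(np.array([1.0, 0.0, 1.0]), (5, 1))
        out = voxelwise_pfs_association(mask, np.arange(1.0, 6.0))
        assert np.isnan(out).all()

    def test_hand_computed_point_biserial(self):
        seg = np.array(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]
        )
        pfs = np.array([10.0, 12.0, 3.0, 5.0])
        out = voxelwise_pfs_association(seg, pfs)
        expected0 = np.corrcoef(seg[:, 0], pfs)[0, 1]
        assert out[0] == pytest.approx(expected0)
        assert out[1] == pytest.approx(-expected0)

    def test_sign_flip_antisymmetry(self, rng):
        seg = (rng.random((12, 40)) < 0.5).astype(float)
        pfs = rng.uniform(1, 24, 12)
        a = voxelwise_pfs_association(seg, pfs)
        b = voxelwise_pfs_association(seg, -pfs)
        valid = np.isfinite(a)
        assert np.allclose(a[valid], -b[valid])
        assert np.array_equal(np.isfinite(a), np.isfinite(b))


class TestPerNetworkAverages:
    def test_constant_map(self):
        parc = make_parcellation(3, 5, (6, 6, 6), seed=0)
        v = np.full(216, 2.5)
        assert np.allclose(average_map_per_network(v, parcellation=parc), 2.5)

    def test_indicator_map(self):
        parc = make_parcellation(3, 5, (6, 6, 6), seed=1)
        v = np.zeros(216)
        v[parc.voxel_ids[0]] = 1.0
        got = average_map_per_network(v, parcellation=parc)
        assert np.allclose(got, [1.0, 0.0, 0.0])

    def test_masked_mean_oracle_with_sentinels(self, rng):
        parc = make_parcellation(4, 6, (6, 6, 6), seed=2)
        v = rng.normal(size=216)
        v[rng.choice(216, 30, replace=False)] = np.nan
        got = average_map_per_network(v, parcellation=parc)
        for g, ids in enumerate(parc.voxel_ids):
            vals = v[ids]
            vals = vals[np.isfinite(vals)]
            assert got[g] == pytest.approx(vals.mean())

    def test_probability_weighted_mode(self, rng):
        pm = rng.random((2, 20))
        v = rng.normal(size=20)
        got = average_map_per_network(v, probability_maps=pm)
        for g in range(2):
            assert got[g] == pytest.approx((pm[g] * v).sum() / pm[g].sum())


class TestCliffsDelta:
    def test_identical_multisets(self):
        a = np.array([1.0, 2.0, 2.0, 3.0])
        assert cliffs_delta(a, a) == 0.0

    def test_complete_dominance(self):
        assert cliffs_delta([5.0, 6.0], [1.0, 2.0]) == 1.0
        assert cliffs_delta([1.0, 2.0], [5.0, 6.0]) == -1.0

    def test_worked_example(self):
        assert cliffs_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.lists(st.integers(-5, 5), min_size=1, max_size=25),
        b=st.lists(st.integers(-5, 5), min_size=1, max_size=25),
    )
    def test_matches_enumeration_and_antisymmetry(self, a, b):
        d = cliffs_delta(a, b)
        assert d == pytest.approx(enum_delta(a, b), abs=1e-12)
        assert cliffs_delta(b, a) == pytest.approx(-d, abs=1e-12)
        assert abs(d) <= 1

    def test_magnitude_labels(self):
        assert delta_magnitude_label(0.32) == "negligible/small"
        assert delta_magnitude_label(0.40) == "moderate"
        assert delta_magnitude_label(-0.40) == "moderate"
        assert delta_magnitude_label(0.47) == "large"
        assert delta_magnitude_label(0.81) == "large"


class TestNetworkEffectSizes:
    def test_identical_groups_all_zero(self):
        parc = make_parcellation(4, 8, (8, 8, 8), seed=3)
        control, _ = simulate_probability_maps(parc, seed=4)
        table = network_effect_sizes(control, control.copy(), parc)
        assert (table["delta"] == 0).all()
        assert (table["magnitude"] == "negligible/small").all()

    def test_attenuation_ordering(self):
        parc = make_parcellation(3, 10, (8, 8, 8), seed=5)
        # mild attenuations keep the distributions overlapping (delta < 1)
        att = np.array([1.0, 0.97, 0.90])
        control, patient = simulate_probability_maps(parc, attenuation=att, seed=6, noise_sd=0.0)
        table = network_effect_sizes(control, patient, parc)
        deltas = table["delta"].to_numpy()
        assert deltas[0] == 0.0
        assert deltas[2] > deltas[1] > 0  # stronger attenuation, larger delta


class TestFeatureWeightMaps:
    def test_all_ones_average_to_one(self):
        names = ("A", "B", "C")
        labels = pair_labels(names)
        got = average_network_feature_weights(np.ones(len(labels)), labels, names)
        assert np.allclose(got, 1.0)

    def test_single_between_pair_counting(self):
        from rsnpfs.parcellation import NETWORK_NAMES, pair_index

        labels = pair_labels(NETWORK_NAMES)
        w = np.zeros(120)
        w[pair_index(NETWORK_NAMES, "SMD", "SMI")] = 1.0
        got = average_network_feature_weights(w, labels, NETWORK_NAMES)
        assert got[NETWORK_NAMES.index("SMD")] == pytest.approx(1 / 15)
        assert got[NETWORK_NAMES.index("SMI")] == pytest.approx(1 / 15)
        others = [g for i, g in enumerate(got) if NETWORK_NAMES[i] not in ("SMD", "SMI")]
        assert np.allclose(others, 0.0)

    def test_label_membership_oracle(self, rng):
        names = ("A", "B", "C", "D")
        labels = pair_labels(names)
        w = rng.normal(size=len(labels))
        got = average_network_feature_weights(w, labels, names)
        for g, name in enumerate(names):
            member = [w[i] for i, (a, b) in enumerate(labels) if name in (a, b)]
            assert got[g] == pytest.approx(np.mean(member))


class TestProjection:
    def test_unit_vector_recovers_map(self, rng):
        pm = rng.random((4, 25))
        w = np.zeros(4)
        w[0] = 1.0
        assert np.array_equal(project_weights_to_voxels(w, pm), pm[0])

    def test_zero_weights_zero_map(self, rng):
        pm = rng.random((4, 25))
        assert np.array_equal(project_weights_to_voxels(np.zeros(4), pm), np.zeros(25))

    def test_dot_product_oracle_and_linearity(self, rng):
        pm = rng.random((5, 30))
        w1 = rng.normal(size=5)
        w2 = rng.normal(size=5)
        expected = np.array([(w1 * pm[:, v]).sum() for v in range(30)])
        assert np.allclose(project_weights_to_voxels(w1, pm), expected)
        assert np.allclose(
            project_weights_to_voxels(2 * w1 + w2, pm),
            2 * project_weights_to_voxels(w1, pm) + project_weights_to_voxels(w2, pm),
        )
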