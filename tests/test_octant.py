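"""Octant assignment, the four feature groups, and oracle equivalence of
every network-topology metric."""

import itertools

import numpy as np
import pytest

from pecg_ira import VCGRecord, assign_octants, build_octant_network, extract_all
from pecg_ira.octant import (
    FEATURE_NAMES,
    GROUP_I_NAMES,
    GROUP_II_NAMES,
    GROUP_III_NAMES,
    GROUP_IV_NAMES,
    OctantNetwork,
    OctantFeatureExtractor,
    local_octant_features,
    residence_features,
    topology_features,
    transition_features,
)

import graph_oracle


def _vcg(x, y, z, fs=10.0):
    return VCGRecord(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float), fs)


def _seq_from_octants(indices, fs=10.0):
    """Build a VCG whose octant sequence equals ``indices``."""
    signs = []
    for k in indices:
        b = k - 1
        signs.append((1 - 2 * (b // 4), 1 - 2 * ((b // 2) % 2), 1 - 2 * (b % 2)))
    arr = np.array(signs, float)
    return assign_octants(_vcg(arr[:, 0], arr[:, 1], arr[:, 2], fs))


class TestOctantAssignment:
    def test_sign_convention_corners(self):
        seq = assign_octants(_vcg([1, -1], [1, -1], [1, -1]))
        assert seq.octant[0] == 1
        assert seq.octant[1] == 8

    def test_hand_written_trajectory_matches_sign_oracle(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(6, 3))
        seq = assign_octants(_vcg(xyz[:, 0], xyz[:, 1], xyz[:, 2]))
        for i, (x, y, z) in enumerate(xyz):
            expected = 1 + 4 * (x < 0) + 2 * (y < 0) + (z < 0)
            assert seq.octant[i] == expected

    def test_zero_vector_keeps_previous_octant(self):
        seq = assign_octants(_vcg([1, 0, -1], [1, 0, -1], [1, 0, -1]))
        assert list(seq.octant) == [1, 1, 8]

    def test_spherical_coordinates(self):
        seq = assign_octants(_vcg([1.0], [1.0], [np.sqrt(2.0)]))
        assert seq.magnitude[0] == pytest.approx(2.0)
        assert seq.azimuth[0] == pytest.approx(45.0)
        assert seq.elevation[0] == pytest.approx(45.0)


class TestLocalOctantFeatures:
    def test_output_inventory(self):
        seq = assign_octants(_vcg([1.0, 1.0], [1.0, 1.0], [1.0, 1.0]))
        feats = local_octant_features(seq)
        assert len(feats) == 48
        assert set(feats) == set(GROUP_I_NAMES)

    def test_constant_vector_statistics(self):
        seq = assign_octants(_vcg([1, 1, 1], [1, 1, 1], [1, 1, 1]))
        feats = local_octant_features(seq)
        mag = np.sqrt(3.0)
        assert feats["Oct1Min"] == pytest.approx(mag)
        assert feats["Oct1Avg"] == pytest.approx(mag)
        assert feats["Oct1Max"] == pytest.approx(mag)
        assert feats["Oct1Var"] == pytest.approx(0.0, abs=1e-15)
        assert feats["Oct2Min"] == 0.0  # unvisited fill

    def test_random_trajectory_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(size=(100, 3))
        vcg = _vcg(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        seq = assign_octants(vcg)
        feats = local_octant_features(seq)
        for i in range(1, 9):
            sel = [
                j for j in range(100)
                if 1 + 4 * (xyz[j, 0] < 0) + 2 * (xyz[j, 1] < 0) + (xyz[j, 2] < 0) == i
            ]
            mags = [np.linalg.norm(xyz[j]) for j in sel]
            if not mags:
                assert feats[f"Oct{i}Min"] == 0.0
                continue
            assert feats[f"Oct{i}Min"] == pytest.approx(min(mags))
            assert feats[f"Oct{i}Avg"] == pytest.approx(np.mean(mags))
            assert feats[f"Oct{i}Var"] == pytest.approx(np.var(mags))
            assert feats[f"Oct{i}Max"] == pytest.approx(max(mags))
            peak = sel[int(np.argmax(mags))]
            x, y, z = xyz[peak]
            assert feats[f"Oct{i}Azm"] == pytest.approx(np.degrees(np.arctan2(y, x)))
            assert feats[f"Oct{i}Elv"] == pytest.approx(
                np.degrees(np.arctan2(z, np.hypot(x, y)))
            )


class TestResidenceFeatures:
    def test_single_octant_trajectory(self):
        seq = _seq_from_octants([3] * 40)
        feats = residence_features(seq)
        assert feats["Oct3Num"] == pytest.approx(4.0)  # 40 samples at 10 Hz
        assert sum(feats[f"Oct{i}Num"] for i in range(1, 9)) == pytest.approx(4.0)
        for name in ("SlowTran", "FastTran", "MeanTran", "VarTran"):
            assert feats[name] == 0.0

    def test_output_inventory(self):
        feats = residence_features(_seq_from_octants([1, 2, 1, 2]))
        assert len(feats) == 12
        assert set(feats) == set(GROUP_II_NAMES)

    def test_alternating_sequence_rates(self):
        n = 50
        seq = _seq_from_octants([1, 2] * n, fs=10.0)
        feats = residence_features(seq, window=1.0)
        # every consecutive pair transitions: (2n-1) changes in 10 s
        total_rate = (2 * n - 1) / seq.duration
        assert feats["MeanTran"] == pytest.approx(total_rate, rel=0.05)
        assert feats["VarTran"] == pytest.approx(0.0, abs=1e-9)

    def test_sojourn_conservation(self):
        rng = np.random.default_rng(2)
        seq = _seq_from_octants(rng.integers(1, 9, size=200))
        feats = residence_features(seq)
        total = sum(feats[f"Oct{i}Num"] for i in range(1, 9))
        assert total == pytest.approx(seq.duration)


class TestTransitionFeatures:
    def test_no_transitions(self):
        feats = transition_features(_seq_from_octants([5] * 10))
        assert len(feats) == 16
        assert all(v == 0.0 for v in feats.values())

    def test_flow_conservation(self):
        rng = np.random.default_rng(3)
        seq = _seq_from_octants(rng.integers(1, 9, size=300))
        feats = transition_features(seq)
        total_in = sum(feats[f"InOct{i}Rate"] for i in range(1, 9))
        total_out = sum(feats[f"OutOct{i}Rate"] for i in range(1, 9))
        changes = int(np.sum(np.diff(seq.octant) != 0))
        assert total_in == pytest.approx(changes / seq.duration)
        assert total_out == pytest.approx(total_in)

    def test_time_reversal_swaps_in_and_out(self):
        rng = np.random.default_rng(4)
        idx = rng.integers(1, 9, size=100)
        fwd = transition_features(_seq_from_octants(idx))
        rev = transition_features(_seq_from_octants(idx[::-1]))
        for i in range(1, 9):
            assert fwd[f"InOct{i}Rate"] == pytest.approx(rev[f"OutOct{i}Rate"])


class TestOctantNetwork:
    def test_single_octant_has_no_edges(self):
        net = build_octant_network(_seq_from_octants([2] * 10))
        assert net.total_transitions == 0

    def test_hand_counted_cycle(self):
        net = build_octant_network(_seq_from_octants([1, 2, 3, 1]))
        assert net.weights[0, 1] == 1
        assert net.weights[1, 2] == 1
        assert net.weights[2, 0] == 1
        assert net.total_transitions == 3

    def test_weight_sum_equals_index_changes(self):
        rng = np.random.default_rng(5)
        idx = rng.integers(1, 9, size=500)
        net = build_octant_network(_seq_from_octants(idx))
        assert net.total_transitions == int(np.sum(np.diff(idx) != 0))

    def test_self_loops_rejected(self):
        w = np.zeros((8, 8), int)
        w[0, 0] = 1
        with pytest.raises(ValueError):
            OctantNetwork(w, duration=1.0)


def _compare_with_oracle(weights):
    net = OctantNetwork(np.asarray(weights), duration=10.0)
    got = topology_features(net)
    expected = graph_oracle.all_features([list(r) for r in np.asarray(weights)])
    assert set(got) == set(expected)
    for name in expected:
        assert got[name] == pytest.approx(expected[name], abs=1e-8), name


class TestTopologyOracle:
    def test_output_inventory(self):
        feats = topology_features(OctantNetwork(np.zeros((8, 8), int), 10.0))
        assert len(feats) == 85
        assert set(feats) == set(GROUP_IV_NAMES)

    def test_empty_network_conventions(self):
        feats = topology_features(OctantNetwork(np.zeros((8, 8), int), 10.0))
        assert feats["Jbl"] == 8.0
        assert feats["Nden"] == 0.0
        assert feats["Kden"] == 0.0
        assert all(feats[f"Degr{i}"] == 0.0 for i in range(1, 9))

    def test_three_node_ring(self):
        w = np.zeros((8, 8), int)
        w[0, 1] = w[1, 2] = w[2, 0] = 1
        feats = topology_features(OctantNetwork(w, 10.0))
        for i in (1, 2, 3):
            assert feats[f"InDgr{i}"] == 1.0
            assert feats[f"OutDgr{i}"] == 1.0
            # symmetrized triangle at half the possible triad weight
            assert feats[f"Clust{i}"] == pytest.approx(0.5)
        assert feats["DiameterNet"] == pytest.approx(2.0)
        assert feats["RadiusNet"] == pytest.approx(2.0)
        _compare_with_oracle(w)

    def test_exhaustive_two_node_graphs(self):
        for w01, w10 in itertools.product((0, 1, 2), repeat=2):
            w = np.zeros((8, 8), int)
            w[0, 1], w[1, 0] = w01, w10
            _compare_with_oracle(w)

    def test_sampled_three_and_four_node_graphs(self):
        rng = np.random.default_rng(6)
        for nodes in (3, 4):
            pairs = list(itertools.permutations(range(nodes), 2))
            for _ in range(60):
                w = np.zeros((8, 8), int)
                for i, j in pairs:
                    w[i, j] = rng.integers(0, 3)
                _compare_with_oracle(w)

    def test_record_network_matches_oracle(self, noisy_record):
        _, vcg = noisy_record
        net = build_octant_network(assign_octants(vcg))
        _compare_with_oracle(net.weights)


class TestFeatureAssembly:
    def test_vector_length_and_names(self, noisy_record):
        _, vcg = noisy_record
        feats = extract_all(vcg)
        assert len(feats) == 161
        assert list(feats.index) == list(FEATURE_NAMES)
        assert np.all(np.isfinite(feats.to_numpy()))

    def test_group_sizes(self):
        assert len(GROUP_I_NAMES) == 48
        assert len(GROUP_II_NAMES) == 12
        assert len(GROUP_III_NAMES) == 16
        assert len(GROUP_IV_NAMES) == 85

    def test_determinism(self, noisy_record):
        _, vcg = noisy_record
        a = extract_all(vcg)
        b = extract_all(vcg)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_transformer_interface(self, noisy_record):
        _, vcg = noisy_record
        ext = OctantFeatureExtractor()
        frame = ext.fit_transform([vcg, vcg])
        assert frame.shape == (2, 161)
        assert ext.get_params() == {"window": 1.0}
        np.testing.assert_array_equal(frame.iloc[0], frame.iloc[1])
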