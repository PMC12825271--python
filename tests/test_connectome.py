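"""Streamline geometry, endpoint assignment, W construction, TCK I/O."""

import numpy as np
import pandas as pd
import pytest

import safconn as sc


class TestStreamlineLength:
    def test_three_four_five_triangle(self):
        assert sc.streamline_length([(0, 0, 0), (3, 4, 0)]) == 5.0

    def test_semicircle_arc_length(self):
        t = np.linspace(0, np.pi, 10_001)
        arc = np.stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)], axis=1)
        assert sc.streamline_length(arc) == pytest.approx(10 * np.pi, abs=1e-3)

    def test_single_point_is_zero(self):
        assert sc.streamline_length([(1.0, 2.0, 3.0)]) == 0.0


class TestAssignEndpoints:
    def test_interior_endpoint_gets_containing_label(self, ribbon5):
        parc, _ = ribbon5
        vox = np.argwhere(parc.label_grid == 3)[0]
        point = vox * np.asarray(parc.voxel_size_mm)
        tract = sc.Tractogram([np.array([point, point])])
        assert sc.assign_endpoints(tract, parc) == [(3, 3)]

    def test_far_endpoint_unassigned(self, ribbon5):
        parc, _ = ribbon5
        center = (np.asarray(parc.label_grid.shape) - 1) / 2.0
        tract = sc.Tractogram([np.array([center, center])])  # deep inside annulus hole
        assert sc.assign_endpoints(tract, parc, search_radius_mm=2.0) == [None]

    def test_synthetic_tractogram_full_recovery(self, ribbon5, tract_60_40):
        parc, _ = ribbon5
        tract, labels = tract_60_40
        got = sc.assign_endpoints(tract, parc)
        assert got == labels

    def test_nearest_label_fallback_tie_breaks_low_id(self):
        grid = np.zeros((3, 1, 1), dtype=np.int32)
        grid[0, 0, 0] = 5
        grid[2, 0, 0] = 2
        regions = pd.DataFrame(
            {"id": [2, 5], "name": ["a", "b"], "hemisphere": ["L", "L"]}
        )
        parc = sc.Parcellation(grid, regions)
        point = np.array([1.0, 0.0, 0.0])  # equidistant from both labels
        tract = sc.Tractogram([np.array([point, point])])
        assert sc.assign_endpoints(tract, parc, search_radius_mm=1.5) == [(2, 2)]


class TestBuildConnectivity:
    @pytest.fixture
    def regions(self):
        return pd.DataFrame(
            {"id": [1, 2, 3, 4], "name": ["a", "b", "a", "b"],
             "hemisphere": ["L", "L", "R", "R"]}
        )

    def test_counting_symmetric(self, regions):
        cm = sc.build_connectivity(
            [(1, 2)] * 3, [10.0] * 3, [1.0] * 3, regions
        )
        assert cm.w.loc[1, 2] == 3 and cm.w.loc[2, 1] == 3

    def test_cross_hemisphere_dropped(self, regions):
        cm = sc.build_connectivity([(1, 3)], [10.0], [1.0], regions)
        assert cm.w.to_numpy().sum() == 0
        assert cm.drop_report["cross_hemisphere"] == 1

    def test_intra_regional_excluded_by_default(self, regions):
        cm = sc.build_connectivity([(1, 1)], [10.0], [1.0], regions)
        assert cm.w.to_numpy().sum() == 0
        assert cm.drop_report["intra_excluded"] == 1

    def test_intra_goes_to_diagonal_once(self, regions):
        cm = sc.build_connectivity([(1, 1)], [10.0], [2.5], regions, include_intra=True)
        assert cm.w.loc[1, 1] == 2.5
        assert cm.w.to_numpy().sum() == 2.5

    def test_conservation_and_order_invariance(self, regions):
        rng = np.random.default_rng(7)
        pairs = [(1, 2), (2, 1), (1, 1), (3, 4), (1, 3), None] * 10
        lengths = rng.uniform(5, 60, len(pairs))
        weights = rng.uniform(0.5, 2.0, len(pairs))
        cm = sc.build_connectivity(pairs, lengths, weights, regions, include_intra=True)
        retained_inter = sum(
            w for p, w in zip(pairs, weights)
            if p is not None and p[0] != p[1] and (p[0] <= 2) == (p[1] <= 2)
        )
        retained_intra = sum(
            w for p, w in zip(pairs, weights) if p is not None and p[0] == p[1]
        )
        off = cm.w.to_numpy().sum() - np.diag(cm.w.to_numpy()).sum()
        assert off == pytest.approx(2 * retained_inter)
        assert np.diag(cm.w.to_numpy()).sum() == pytest.approx(retained_intra)
        # permutation invariance
        perm = rng.permutation(len(pairs))
        cm2 = sc.build_connectivity(
            [pairs[i] for i in perm], lengths[perm], weights[perm], regions,
            include_intra=True,
        )
        assert np.allclose(cm.w.to_numpy(), cm2.w.to_numpy())

    def test_length_threshold_numerator_only(self, regions):
        pairs = [(1, 2), (1, 2)]
        cm = sc.build_connectivity(
            pairs, [30.0, 80.0], [1.0, 1.0], regions, length_threshold_mm=50.0
        )
        assert cm.w.loc[1, 2] == 2
        assert cm.saf_numerator.loc[1, 2] == 1

    def test_infinite_threshold_numerator_equals_w(self, regions):
        pairs = [(1, 2), (3, 4)]
        cm = sc.build_connectivity(
            pairs, [30.0, 80.0], [1.0, 1.0], regions, length_threshold_mm=np.inf
        )
        assert np.array_equal(cm.saf_numerator.to_numpy(), cm.w.to_numpy())

    def test_unknown_region_id_raises(self, regions):
        with pytest.raises(ValueError, match="absent"):
            sc.build_connectivity([(1, 99)], [1.0], [1.0], regions)


class TestEndToEnd:
    def test_known_counts_give_known_gscf(self, ribbon5, tract_60_40):
        parc, adj = ribbon5
        tract, _ = tract_60_40
        cm = sc.connectivity_from_tractogram(tract, parc)
        assert cm.w.to_numpy().sum() == 200  # 2 x 100 retained streamlines
        assert sc.gscf(cm, adj) == pytest.approx(0.6, abs=0)


class TestTckIO:
    def test_round_trip_float32(self, tmp_path, tract_60_40):
        tract, _ = tract_60_40
        path = tmp_path / "t.tck"
        wpath = tmp_path / "w.txt"
        sc.write_tractogram_tck(tract, path, wpath)
        back = sc.read_tractogram_tck(path, wpath)
        assert len(back) == len(tract)
        for a, b in zip(back.streamlines, tract.streamlines):
            assert a.shape == b.shape
            assert np.array_equal(a, b.astype(np.float32))
        assert np.allclose(back.weights, tract.weights)

    def test_empty_tractogram_round_trip(self, tmp_path):
        path = tmp_path / "e.tck"
        sc.write_tractogram_tck(sc.Tractogram([]), path)
        assert len(sc.read_tractogram_tck(path)) == 0

    def test_weight_count_mismatch_raises(self, tmp_path, tract_60_40):
        tract, _ = tract_60_40
        path = tmp_path / "t.tck"
        sc.write_tractogram_tck(tract, path)
        (tmp_path / "w.txt").write_text("1.0\n2.0\n")
        with pytest.raises(ValueError, match="weights"):
            sc.read_tractogram_tck(path, tmp_path / "w.txt")

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.tck"
        bad.write_text("not a tck header\n")
        with pytest.raises(Exception):
            sc.read_tractogram_tck(bad)
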