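import numpy as np
import pytest

from enteroquant.imgio import LabelMap
from enteroquant.spatial import (
    SpatialConfig,
    _round_up_half,
    cross_type_pn,
    edge_distance_graph,
    estimate_threshold,
    local_thickness,
    neighbor_count_map,
    pn_counts,
    pn_histogram,
)

from conftest import random_label_image, random_mask
from oracles import brute_edge_gaps, brute_local_thickness


def _labels(arr, px=1.0):
    return LabelMap(np.asarray(arr, dtype=np.int32), px)


class TestEdgeDistanceGraph:
    def test_two_point_cells_11px_apart(self):
        arr = np.zeros((5, 15), dtype=np.int32)
        arr[2, 1] = 1
        arr[2, 12] = 2
        g = edge_distance_graph(_labels(arr), SpatialConfig(threshold_um=6.5, search_radius_um=30))
        assert g.gap(1, 2) == pytest.approx(10.0)

    def test_adjacent_labels_touch(self):
        arr = np.zeros((4, 4), dtype=np.int32)
        arr[1, 1] = 1
        arr[1, 2] = 2
        g = edge_distance_graph(_labels(arr))
        assert g.gap(1, 2) == 0.0

    def test_symmetry_and_radius_cut(self):
        arr = np.zeros((3, 40), dtype=np.int32)
        arr[1, 0] = 1
        arr[1, 30] = 2
        g = edge_distance_graph(_labels(arr), SpatialConfig(threshold_um=5, search_radius_um=20))
        assert g.gap(1, 2) is None and g.gap(2, 1) is None

    def test_fewer_than_two_cells_empty_graph(self):
        arr = np.zeros((4, 4), dtype=np.int32)
        arr[1, 1] = 1
        assert edge_distance_graph(_labels(arr)).gaps == {}

    def test_matches_brute_force(self, rng):
        for k in range(10):
            lab = random_label_image(rng, (64, 64), 12, "discs" if k % 2 else "voronoi")
            px = float(rng.uniform(0.3, 1.5))
            g = edge_distance_graph(_labels(lab, px), SpatialConfig(5.0, 20.0))
            oracle = brute_edge_gaps(lab, px, 20.0)
            assert set(g.gaps) == set(oracle)
            for key, val in oracle.items():
                assert g.gaps[key] == pytest.approx(val, abs=1e-12)


class TestPnCounts:
    def _chain(self, gaps_px):
        # point cells on one row separated by given center distances
        arr = np.zeros((3, 64), dtype=np.int32)
        c = 1
        arr[1, c] = 1
        for i, d in enumerate(gaps_px, start=2):
            c += d
            arr[1, c] = i
        return _labels(arr)

    def test_chain_counts(self):
        lab = self._chain([6, 6])  # center distance 6 px -> gap 5 um at 1 um/px
        g = edge_distance_graph(lab, SpatialConfig(6.5))
        assert list(pn_counts(g, SpatialConfig(6.5)).counts) == [1, 2, 1]

    def test_gap_exactly_threshold_is_counted(self):
        lab = self._chain([8])  # gap exactly 7.0 um
        res = pn_counts(edge_distance_graph(lab, SpatialConfig(7.0)), SpatialConfig(7.0))
        assert list(res.counts) == [1, 1]

    def test_isolated_cell_zero(self):
        arr = np.zeros((4, 4), dtype=np.int32)
        arr[1, 1] = 1
        res = pn_counts(edge_distance_graph(_labels(arr)))
        assert list(res.counts) == [0]

    def test_histogram(self):
        raw, norm = pn_histogram(np.array([1, 2, 1]))
        assert raw == {1: 2, 2: 1}
        assert norm[1] == pytest.approx(2 / 3)
        assert sum(norm.values()) == pytest.approx(1.0)

    def test_histogram_empty_errors(self):
        with pytest.raises(ValueError):
            pn_histogram(np.array([]))

    def test_rigid_invariance(self, rng):
        lab = random_label_image(rng, (64, 64), 10, "discs")
        base = pn_counts(edge_distance_graph(_labels(lab), SpatialConfig(5.0)), SpatialConfig(5.0))
        rot = np.rot90(lab)
        shifted = np.zeros((70, 70), dtype=lab.dtype)
        shifted[3:67, 5:69] = lab
        for other in (rot, shifted):
            res = pn_counts(edge_distance_graph(_labels(other), SpatialConfig(5.0)), SpatialConfig(5.0))
            assert sorted(res.counts) == sorted(base.counts)


class TestCrossTypePn:
    def test_chain_flags(self):
        arr = np.zeros((3, 20), dtype=np.int32)
        arr[1, 1], arr[1, 5], arr[1, 9] = 1, 2, 3  # A-B-C, gaps 3 um
        g = edge_distance_graph(_labels(arr), SpatialConfig(6.5))
        res = cross_type_pn(g, flags_neighbor=np.array([False, True, False]))
        assert list(res.counts) == [1, 0, 1]

    def test_all_true_reduces_to_pn_counts(self, rng):
        lab = random_label_image(rng, (64, 64), 10, "discs")
        g = edge_distance_graph(_labels(lab), SpatialConfig(5.0))
        plain = pn_counts(g, SpatialConfig(5.0))
        cross = cross_type_pn(g, np.ones(len(g.ids), bool), config=SpatialConfig(5.0))
        assert list(cross.counts) == list(plain.counts)

    def test_no_centers_errors(self):
        arr = np.zeros((3, 10), dtype=np.int32)
        arr[1, 1], arr[1, 4] = 1, 2
        g = edge_distance_graph(_labels(arr))
        with pytest.raises(ValueError):
            cross_type_pn(g, np.array([True, True]), np.array([False, False]))


class TestNeighborCountMap:
    def test_values(self):
        arr = np.zeros((3, 10), dtype=np.int32)
        arr[1, 1], arr[1, 8] = 1, 2
        lab = _labels(arr)
        res = pn_counts(edge_distance_graph(lab, SpatialConfig(3.0)), SpatialConfig(3.0))
        cmap = neighbor_count_map(lab, res)
        assert set(np.unique(cmap)) == {-1, 0}
        assert cmap[1, 1] == 0 and cmap[0, 0] == -1

    def test_missing_count_errors(self):
        arr = np.zeros((3, 10), dtype=np.int32)
        arr[1, 1], arr[1, 8] = 1, 2
        lab = _labels(arr)
        res = pn_counts(edge_distance_graph(lab))
        bad = LabelMap(np.where(arr == 2, 3, arr), 1.0)
        with pytest.raises(ValueError):
            neighbor_count_map(bad, res)


class TestLocalThickness:
    def test_disc_radius_10(self):
        # pixel-center rasterization bites ~0.7 px off the ideal disc, so the
        # exact inscribed diameter sits slightly below 20
        yy, xx = np.ogrid[:32, :32]
        mask = (yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 10**2
        lt = local_thickness(mask)
        assert lt.max() == pytest.approx(20.0, rel=0.07)
        assert lt.max() <= 20.0

    def test_solid_rectangle_width_4(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[3:7, 5:25] = True
        lt = local_thickness(mask)
        # interior pixels see the full inscribed diameter 4; the four corner
        # pixels are 0.12 px too far from any radius-2 disc center and get 3
        interior = np.zeros_like(mask)
        interior[4:6, 6:24] = True
        assert np.all(lt[interior] == pytest.approx(4.0))
        assert np.all(lt[mask] >= 3.0)

    def test_single_pixel_line(self):
        mask = np.zeros((8, 20), dtype=bool)
        mask[4, 2:18] = True
        lt = local_thickness(mask)
        assert np.all(lt[mask] == pytest.approx(1.0))

    def test_empty_mask_all_zero(self):
        assert np.all(local_thickness(np.zeros((6, 6), dtype=bool)) == 0)

    def test_pixel_size_scaling(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[3:7, 5:25] = True
        assert np.max(local_thickness(mask, 0.5)) == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            mask = random_mask(rng, (28, 28))
            assert np.allclose(local_thickness(mask), brute_local_thickness(mask), atol=1e-9, rtol=0)


class TestEstimateThreshold:
    def test_constant_gap_slab(self):
        # two solid slabs separated by a 6 um slab of inter-cell space
        px = 0.5
        arr = np.zeros((40, 60), dtype=np.int32)
        arr[4:16] = 1
        arr[28:40] = 2  # rows 16..27 empty: 12 px = 6.0 um wide slab
        ganglia = np.zeros_like(arr)
        ganglia[4:40, :] = 1
        est = estimate_threshold(_labels(arr, px), ganglia)
        assert est.mean_um == pytest.approx(6.0, rel=0.15)

    def test_fully_occupied_errors(self):
        arr = np.ones((5, 5), dtype=np.int32)
        with pytest.raises(ValueError):
            estimate_threshold(_labels(arr), np.ones((5, 5), dtype=np.int32))

    def test_rounding_convention(self):
        assert _round_up_half(6.32) == 6.5
        assert _round_up_half(6.0) == 6.0
        assert _round_up_half(6.51) == 7.0

    def test_suggested_threshold_rounds_up(self):
        px = 0.5
        arr = np.zeros((40, 60), dtype=np.int32)
        arr[4:16] = 1
        arr[28:40] = 2
        ganglia = np.ones_like(arr)
        est = estimate_threshold(_labels(arr, px), ganglia)
        assert est.suggested_threshold_um == pytest.approx(np.ceil(est.mean_um / 0.5) * 0.5)


class TestSpatialConfig:
    def test_default_search_radius(self):
        cfg = SpatialConfig(threshold_um=6.5)
        assert cfg.search_radius_um == pytest.approx(26.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            SpatialConfig(threshold_um=-1)
        with pytest.raises(ValueError):
            SpatialConfig(threshold_um=5, search_radius_um=2)
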