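import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from enteroquant.ganglia import (
    assign_cells,
    default_expand_um,
    ganglia_by_expansion,
    ganglia_from_probability,
    ganglia_stats,
)
from enteroquant.imgio import LabelMap
from enteroquant.segment import build_cell_table

_EIGHT = np.ones((3, 3), dtype=bool)


def _two_squares(gap_px, size=6, px=1.0):
    """Two size×size squares on one row with a center-column gap of gap_px."""
    w = 2 * size + gap_px + 20
    arr = np.zeros((size + 20, w), dtype=np.int32)
    arr[10 : 10 + size, 10 : 10 + size] = 1
    c0 = 10 + size + gap_px
    arr[10 : 10 + size, c0 : c0 + size] = 2
    return LabelMap(arr, px)


class TestExpansion:
    def test_merge_iff_gap_below_twice_expand(self):
        # edge gap convention: closest centers sit gap_cols+1 apart, so the
        # edge-to-edge gap of _two_squares(gap_cols) is exactly gap_cols um
        expand = 3.0  # merge iff gap < 6 um at 1 um/px
        for gap_cols, expect_merge in [(3, True), (5, True), (6, False), (9, False)]:
            lab = _two_squares(gap_cols)
            g = ganglia_by_expansion(lab, expand)
            assert g.n_ganglia == (1 if expect_merge else 2), gap_cols

    def test_boundary_is_strict(self):
        # gap exactly equal to 2*expand must NOT merge
        lab = _two_squares(6)  # gap 6.0 um
        assert ganglia_by_expansion(lab, 3.0).n_ganglia == 2
        assert ganglia_by_expansion(lab, 3.001).n_ganglia == 1

    def test_zero_expansion_is_connected_components(self):
        arr = np.zeros((12, 12), dtype=np.int32)
        arr[2:5, 2:5] = 1
        arr[5:8, 5:8] = 2  # 8-adjacent at the corner
        arr[9:11, 9:11] = 3
        g = ganglia_by_expansion(LabelMap(arr, 1.0), 0.0)
        assert g.n_ganglia == 2
        assert np.array_equal(g.labels.labels > 0, arr > 0)

    def test_each_ganglion_single_component(self):
        from enteroquant.synth import SceneSpec, generate_scene

        scene = generate_scene(SceneSpec(seed=7))
        g = ganglia_by_expansion(scene.gt_cells, 3.16)
        for gid in g.ids:
            _, n = ndimage.label(g.labels.labels == gid, structure=_EIGHT)
            assert n == 1

    def test_mask_is_euclidean_dilation(self):
        lab = _two_squares(30)
        g = ganglia_by_expansion(lab, 2.0)
        dist = ndimage.distance_transform_edt(lab.labels == 0)
        assert np.array_equal(g.labels.labels > 0, dist <= 2.0)

    def test_default_expand_is_half_mean_equivalent_diameter(self):
        arr = np.zeros((20, 20), dtype=np.int32)
        arr[2:6, 2:6] = 1  # 16 px
        expected = np.sqrt(16 / np.pi)  # radius of the equal-area disc
        assert default_expand_um(LabelMap(arr, 1.0)) == pytest.approx(expected)

    def test_negative_expand_errors(self):
        with pytest.raises(ValueError):
            ganglia_by_expansion(_two_squares(4), -1.0)

    def test_empty_labels(self):
        g = ganglia_by_expansion(LabelMap(np.zeros((8, 8), dtype=np.int32), 1.0), 2.0)
        assert g.n_ganglia == 0


class TestProbability:
    def test_threshold_inclusive(self):
        prob = np.zeros((8, 8))
        prob[2:4, 2:4] = 0.8
        prob[6:8, 6:8] = 0.79
        g = ganglia_from_probability(prob, threshold=0.8)
        assert g.n_ganglia == 1

    def test_min_area_filter(self):
        prob = np.zeros((12, 12))
        prob[1:2, 1:2] = 1.0
        prob[5:10, 5:10] = 1.0
        g = ganglia_from_probability(prob, threshold=0.5, min_area_um2=4.0)
        assert g.n_ganglia == 1

    def test_invalid_values_error(self):
        with pytest.raises(ValueError):
            ganglia_from_probability(np.full((4, 4), 1.5))


class TestAssignAndStats:
    def test_assignment_and_counts(self):
        lab = _two_squares(30)
        cells = build_cell_table(lab)
        g = ganglia_by_expansion(lab, 2.0)
        cells = assign_cells(cells, lab, g)
        assert cells["ganglion_id"].notna().all()
        stats = ganglia_stats(cells, g)
        assert stats.n_ganglia == 2
        assert list(stats.per_ganglion["n_cells"]) == [1, 1]
        assert stats.mean_cells_per_ganglion == 1.0
        assert stats.n_assigned == 2 and stats.n_unassigned == 0

    def test_density_neurons_per_mm2(self):
        lab = _two_squares(4)
        cells = build_cell_table(lab)
        g = ganglia_by_expansion(lab, 3.0)
        cells = assign_cells(cells, lab, g)
        stats = ganglia_stats(cells, g)
        assert stats.neurons_per_mm2 == pytest.approx(
            stats.n_assigned / (stats.total_area_um2 / 1e6)
        )

    def test_unassigned_cell(self):
        lab = _two_squares(30)
        cells = build_cell_table(lab)
        # a ganglia mask that misses cell 2 entirely
        gm = ganglia_by_expansion(
            LabelMap(np.where(lab.labels == 1, 1, 0).astype(np.int32), 1.0), 2.0
        )
        cells = assign_cells(cells, lab, gm)
        assert cells["ganglion_id"].isna().sum() == 1
        stats = ganglia_stats(cells, gm)
        assert stats.n_unassigned == 1

    def test_stats_requires_assignment(self):
        lab = _two_squares(4)
        cells = build_cell_table(lab)
        g = ganglia_by_expansion(lab, 3.0)
        with pytest.raises(ValueError):
            ganglia_stats(cells, g)
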