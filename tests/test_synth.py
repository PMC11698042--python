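import numpy as np
import pytest
from scipy import ndimage

from enteroquant.synth import (
    SceneSpec,
    generate_scene,
    stretch_scene,
    truth_summary,
)

_EIGHT = np.ones((3, 3), dtype=bool)


class TestSpec:
    def test_invalid(self):
        with pytest.raises(ValueError):
            SceneSpec(marker_proportions={"calb": 1.5})
        with pytest.raises(ValueError):
            SceneSpec(n_ganglia=0)
        with pytest.raises(ValueError):
            SceneSpec(gap_mean_um=0.3, gap_min_um=0.5)


class TestDeterminism:
    def test_bit_identical(self):
        spec = SceneSpec(seed=11, marker_proportions={"calb": 0.3})
        a = generate_scene(spec)
        b = generate_scene(spec)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.gt_cells.labels, b.gt_cells.labels)
        assert np.array_equal(a.gt_ganglia.labels.labels, b.gt_ganglia.labels.labels)
        assert a.gt_flags.equals(b.gt_flags)

    def test_seed_override_changes_scene(self):
        spec = SceneSpec(seed=11)
        a = generate_scene(spec)
        b = generate_scene(spec, seed=12)
        assert not np.array_equal(a.gt_cells.labels, b.gt_cells.labels)


class TestStructure:
    def test_programmed_counts(self):
        spec = SceneSpec(
            n_ganglia=2,
            cells_per_ganglion_mean=5.0,
            cells_per_ganglion_sd=0.0,
            cells_per_ganglion_min=5,
            seed=4,
        )
        scene = generate_scene(spec)
        assert scene.n_cells == 10
        assert scene.gt_cells.n_objects == 10
        assert sorted(np.bincount(scene.cell_ganglion)[1:]) == [5, 5]

    def test_labels_match_polygons(self, default_scene):
        # every label id appears, cell count is consistent everywhere
        s = default_scene
        assert s.gt_cells.n_objects == s.n_cells == len(s.gt_flags)
        assert list(s.gt_cells.ids) == list(range(1, s.n_cells + 1))

    def test_ganglia_cover_their_cells(self, default_scene):
        s = default_scene
        glab = s.gt_ganglia.labels.labels
        assert np.all(glab[s.gt_cells.labels > 0] > 0)

    def test_ganglia_connected(self, default_scene):
        glab = default_scene.gt_ganglia.labels.labels
        for gid in default_scene.gt_ganglia.ids:
            _, n = ndimage.label(glab == gid, structure=_EIGHT)
            assert n == 1

    def test_drawn_gaps_respect_truncation(self, default_scene):
        s = default_scene
        assert len(s.drawn_gaps_um) == s.n_cells - s.spec.n_ganglia
        assert s.drawn_gaps_um.min() >= s.spec.gap_min_um


class TestCalibration:
    def test_mean_area_single_scene(self, default_scene):
        # per-scene sampling noise is a few percent; the pooled 20-seed check
        # with the ±10% band lives in the acceptance tests
        t = default_scene.truth
        assert t["realized_mean_area_px2"] == pytest.approx(t["target_area_px2"], rel=0.12)

    def test_marker_proportions_binomial(self):
        # pooled over 5 scenes the realized fraction must sit inside a 4-sigma
        # binomial band around the programmed probability
        spec = SceneSpec(seed=100, marker_proportions={"calb": 0.3})
        flags = np.concatenate(
            [generate_scene(spec, seed=100 + i).gt_flags["calb"].to_numpy() for i in range(5)]
        )
        n, p = len(flags), 0.3
        band = 4.0 * np.sqrt(p * (1 - p) / n)
        assert abs(flags.mean() - p) <= band

    def test_truth_summary_table(self, default_scene):
        df = truth_summary(default_scene)
        assert set(df.columns) == {"quantity", "programmed", "realized"}
        row = df.set_index("quantity").loc["n_cells"]
        assert row["programmed"] == row["realized"] == default_scene.n_cells
        gap = df.set_index("quantity").loc["gap_mean_um"]
        n_draws = len(default_scene.drawn_gaps_um)
        se = default_scene.spec.gap_sd_um / np.sqrt(n_draws)
        assert abs(gap["realized"] - gap["programmed"]) <= 2.5 * se

    def test_image_channels(self):
        scene = generate_scene(SceneSpec(seed=2, marker_proportions={"calb": 0.5, "nnos": 0.4}))
        assert scene.image.channel_names == ["hu", "calb", "nnos"]
        assert scene.image.pixel_size_um == 0.568
        # marker channel is bright exactly on flagged cells
        calb = scene.image.channel("calb")
        flags = scene.gt_flags["calb"].to_numpy()
        pos = np.isin(scene.gt_cells.labels, np.flatnonzero(flags) + 1)
        neg = (scene.gt_cells.labels > 0) & ~pos
        assert calb[pos].mean() > 5 * calb[neg].mean()


class TestStretch:
    def test_identity_stretch(self, default_scene):
        out = stretch_scene(default_scene, 1.0, 1.0)
        assert np.array_equal(out.gt_cells.labels, default_scene.gt_cells.labels)

    def test_area_ratio_isotropic(self, default_scene):
        out = stretch_scene(default_scene, 1.25, 1.25)
        a0 = default_scene.truth["realized_mean_area_px2"]
        a1 = out.truth["realized_mean_area_px2"]
        assert a1 / a0 == pytest.approx(1.5625, rel=0.03)

    def test_density_ratio(self, default_scene):
        sx = sy = 1.25
        out = stretch_scene(default_scene, sx, sy)
        d0 = default_scene.n_cells / np.prod(default_scene.gt_cells.shape)
        d1 = out.n_cells / np.prod(out.gt_cells.shape)
        assert d1 / d0 == pytest.approx(1 / (sx * sy), rel=0.05)

    def test_flags_and_count_preserved(self, default_scene):
        out = stretch_scene(default_scene, 1.3, 1.1)
        assert out.n_cells == default_scene.n_cells
        assert out.gt_flags.equals(default_scene.gt_flags)

    def test_shrink_rejected(self, default_scene):
        with pytest.raises(ValueError):
            stretch_scene(default_scene, 0.9, 1.0)
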