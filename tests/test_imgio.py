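import numpy as np
import pandas as pd
import pytest
import shapely

from enteroquant.imgio import (
    CalibratedImage,
    LabelMap,
    PolygonRoi,
    compact_labels,
    rasterize_rois,
    read_calibrated_image,
    read_cell_table,
    read_label_map,
    read_roi_archive,
    write_calibrated_image,
    write_cell_table,
    write_label_map,
    write_roi_archive,
)


class TestTypes:
    def test_calibrated_image_validation(self):
        img = CalibratedImage(np.zeros((8, 8)), 0.5)
        assert img.n_channels == 1 and img.shape == (8, 8)
        with pytest.raises(ValueError):
            CalibratedImage(np.zeros((8, 8)), -1)
        with pytest.raises(ValueError):
            CalibratedImage(np.zeros((2, 8, 8)), 0.5, ["only-one"])

    def test_channel_access(self):
        img = CalibratedImage(np.stack([np.zeros((4, 4)), np.ones((4, 4))]), 1.0, ["hu", "calb"])
        assert img.channel("calb").sum() == 16
        assert img.channel(0).sum() == 0

    def test_label_map_validation(self):
        with pytest.raises(ValueError):
            LabelMap(np.array([[0.5]]), 1.0)
        with pytest.raises(ValueError):
            LabelMap(np.array([[-1]]), 1.0)
        lm = LabelMap(np.array([[0, 3], [3, 7]]), 1.0)
        assert list(lm.ids) == [3, 7] and lm.n_objects == 2

    def test_compact_labels(self):
        arr = np.array([[0, 5], [9, 5]])
        out = compact_labels(arr)
        assert set(np.unique(out)) == {0, 1, 2}
        assert out[0, 1] == out[1, 1]  # same object keeps one id


class TestTiffRoundtrip:
    def test_calibrated_image(self, tmp_path):
        img = CalibratedImage(np.random.default_rng(0).random((2, 16, 16)).astype(np.float32), 0.568, ["hu", "calb"])
        write_calibrated_image(img, tmp_path / "img.tif")
        back = read_calibrated_image(tmp_path / "img.tif")
        assert back.pixel_size_um == pytest.approx(0.568, rel=1e-4)
        assert back.channel_names == ["hu", "calb"]
        assert np.allclose(back.pixels, img.pixels)

    def test_label_map(self, tmp_path):
        lm = LabelMap(np.arange(64, dtype=np.int32).reshape(8, 8), 0.9)
        write_label_map(lm, tmp_path / "lab.tif")
        back = read_label_map(tmp_path / "lab.tif")
        assert back.pixel_size_um == pytest.approx(0.9, rel=1e-4)
        assert np.array_equal(back.labels, lm.labels)

    def test_missing_calibration_defaults_with_warning(self, tmp_path, caplog):
        import tifffile

        tifffile.imwrite(tmp_path / "raw.tif", np.zeros((4, 4), dtype=np.uint8))
        with caplog.at_level("WARNING"):
            img = read_calibrated_image(tmp_path / "raw.tif")
        assert img.pixel_size_um == 1.0
        assert any("resolution metadata" in r.getMessage() for r in caplog.records)

    def test_explicit_override_wins(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "raw.tif", np.zeros((4, 4), dtype=np.uint8))
        img = read_calibrated_image(tmp_path / "raw.tif", pixel_size_um=0.25)
        assert img.pixel_size_um == 0.25


class TestRoiArchive:
    def test_roundtrip_vertices(self, tmp_path):
        tri = PolygonRoi("cell-0001", np.array([[2.0, 3.0], [10.5, 4.25], [6.0, 12.0]]))
        quad = PolygonRoi("cell-0002", np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0], [0.0, 5.0]]))
        write_roi_archive([tri, quad], tmp_path / "rois.zip")
        back = read_roi_archive(tmp_path / "rois.zip")
        assert [r.name for r in back] == ["cell-0001", "cell-0002"]
        assert np.allclose(back[0].vertices, tri.vertices)
        assert np.allclose(back[1].vertices, quad.vertices)

    def test_rasterize_point_in_polygon(self, rng):
        rois = []
        for i in range(4):
            c = rng.uniform(8, 56, 2)
            ang = np.sort(rng.uniform(0, 2 * np.pi, 7))
            rad = rng.uniform(3, 7, 7)
            rois.append(PolygonRoi(f"r{i}", np.column_stack([c[0] + rad * np.cos(ang), c[1] + rad * np.sin(ang)])))
        lm = rasterize_rois(rois, (64, 64))
        # oracle: later-wins shapely point-in-polygon per pixel center
        expected = np.zeros((64, 64), dtype=int)
        for i, roi in enumerate(rois, start=1):
            poly = roi.to_shapely()
            for y in range(64):
                for x in range(64):
                    if shapely.intersects_xy(poly, float(x), float(y)):
                        expected[y, x] = i
        assert np.array_equal(lm.labels, expected)

    def test_out_of_bounds_vertices_clipped(self):
        roi = PolygonRoi("big", np.array([[-10.0, -10.0], [70.0, -10.0], [70.0, 70.0], [-10.0, 70.0]]))
        lm = rasterize_rois([roi], (16, 16))
        assert np.all(lm.labels == 1)


class TestCellTable:
    def test_roundtrip_types(self, tmp_path):
        cells = pd.DataFrame(
            {
                "id": [1, 2],
                "centroid_x_um": [1.5, 2.5],
                "centroid_y_um": [0.5, 3.5],
                "area_um2": [10.0, 20.0],
                "polygon": [np.zeros((3, 2)), np.zeros((3, 2))],
                "marker_calb": [True, False],
                "ganglion_id": pd.array([1, None], dtype="Int64"),
            }
        )
        write_cell_table(cells, tmp_path / "cells.csv")
        back = read_cell_table(tmp_path / "cells.csv")
        assert "polygon" not in back.columns
        assert back["marker_calb"].dtype == bool
        assert back["ganglion_id"].dtype.name == "Int64"
        assert back["ganglion_id"].isna().tolist() == [False, True]
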