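"""Calibrated image / label-map / ROI / table I/O under one coordinate convention.

Conventions used throughout the package:

* rasters are indexed ``(row, col)``, origin top-left, 0-based;
* polygon vertices are ``(x=col, y=row)`` pixel-center coordinates, so the
  center of pixel ``[r, c]`` is the point ``(c, r)``;
* physical positions are pixel-center coordinates times ``pixel_size_um``;
* areas are ``pixel count * pixel_size_um**2`` (µm²);
* pixel sizes are isotropic — anisotropic TIFF calibration is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from . import _ijroi

logger = logging.getLogger(__name__)

__all__ = [
    "CalibratedImage",
    "LabelMap",
    "PolygonRoi",
    "read_calibrated_image",
    "read_label_map",
    "write_label_map",
    "read_roi_archive",
    "write_roi_archive",
    "rasterize_rois",
    "compact_labels",
    "write_cell_table",
    "read_cell_table",
]


@dataclass
class CalibratedImage:
    """Multi-channel 2D intensity raster with isotropic physical pixel size."""

    pixels: np.ndarray  # (channels, rows, cols)
    pixel_size_um: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError(f"expected 2D or (channel, row, col) data, got shape {self.pixels.shape}")
        if self.pixels.shape[1] < 1 or self.pixels.shape[2] < 1:
            raise ValueError("image must have at least one row and column")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[0])]
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str | int) -> np.ndarray:
        if isinstance(name, int):
            return self.pixels[name]
        return self.pixels[self.channel_names.index(name)]


@dataclass
class LabelMap:
    """2D instance label raster; 0 is background, each positive value one object."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("label map must be 2D")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise ValueError("label map has non-integral values")
            arr = arr.astype(np.int32)
        if arr.size and arr.min() < 0:
            raise ValueError("label values must be >= 0")
        self.labels = arr
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]

    @property
    def n_objects(self) -> int:
        return len(self.ids)

    def compacted(self) -> "LabelMap":
        return LabelMap(compact_labels(self.labels), self.pixel_size_um)


@dataclass
class PolygonRoi:
    """Named closed polygon in (x, y) pixel-center coordinates."""

    name: str
    vertices: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")

    def to_shapely(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)  # cleanup of self-intersections
        return poly

    @property
    def area_px(self) -> float:
        return self.to_shapely().area


def compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel positive values to consecutive 1..n, preserving order of ids."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(ids.max()) + 1 if len(ids) else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return lut[labels]


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    unit_um = 1.0
    # ImageJ metadata stores the unit; plain TIFF ResolutionUnit 3 means cm.
    ij = tif.imagej_metadata or {}
    unit = ij.get("unit", "")
    if unit in ("micron", "um", "µm", "µm"):
        unit_um = 1.0
    elif unit == "mm":
        unit_um = 1000.0
    elif unit == "cm":
        unit_um = 10000.0
    elif "ResolutionUnit" in tags and tags["ResolutionUnit"].value == 3:
        unit_um = 10000.0
    elif "ResolutionUnit" in tags and tags["ResolutionUnit"].value == 2:
        unit_um = 25400.0
    elif not unit and "ResolutionUnit" in tags and tags["ResolutionUnit"].value == 1:
        return None  # ResolutionUnit "none" without an ImageJ unit: uncalibrated
    if xres is None:
        return None

    def _to_float(v) -> float:
        if isinstance(v, tuple):
            num, den = v
            if num == 0 or den == 0:
                return 0.0
            return float(Fraction(int(num), int(den)))
        return float(v)

    px_x = _to_float(xres.value)
    if px_x == 0:
        return None
    size_x = unit_um / px_x  # resolution is pixels per unit
    if yres is not None:
        px_y = _to_float(yres.value)
        if px_y:
            size_y = unit_um / px_y
            if not np.isclose(size_x, size_y, rtol=1e-3):
                raise ValueError(
                    f"anisotropic pixel size ({size_x:g} x {size_y:g} µm) is not supported"
                )
    return size_x


def read_calibrated_image(path: str | Path, pixel_size_um: float | None = None) -> CalibratedImage:
    """Read a 2D or multi-channel TIFF with its physical calibration.

    The pixel size comes from the TIFF resolution metadata (ImageJ unit aware);
    when absent it defaults to 1.0 µm/px with a logged warning.  An explicit
    ``pixel_size_um`` overrides the file metadata.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
        ij = tif.imagej_metadata or {}
        channel_names = [str(n) for n in (ij.get("Labels") or [])]
    if not np.issubdtype(np.asarray(data).dtype, np.number):
        raise ValueError(f"{path}: non-numeric pixel data")
    if data.ndim > 3:
        raise ValueError(f"{path}: more than 3 axes ({data.shape}); project stacks upstream")
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] > 4:
        data = np.moveaxis(data, -1, 0)  # interleaved RGB(A) -> channel-first
    if pixel_size_um is None:
        if meta_px is None:
            logger.warning("%s: no resolution metadata; assuming 1.0 µm/px", path)
            pixel_size_um = 1.0
        else:
            pixel_size_um = meta_px
    n_channels = 1 if data.ndim == 2 else data.shape[0]
    if len(channel_names) != n_channels:
        channel_names = []
    return CalibratedImage(data, pixel_size_um, channel_names)


def read_label_map(path: str | Path, pixel_size_um: float | None = None) -> LabelMap:
    img = read_calibrated_image(path, pixel_size_um=pixel_size_um)
    if img.n_channels != 1:
        raise ValueError(f"{path}: label maps must be single-channel")
    return LabelMap(img.pixels[0], img.pixel_size_um)


def write_label_map(labels: LabelMap | np.ndarray, path: str | Path, pixel_size_um: float | None = None) -> None:
    if isinstance(labels, LabelMap):
        arr, px = labels.labels, labels.pixel_size_um
    else:
        arr, px = np.asarray(labels), pixel_size_um or 1.0
    arr = arr.astype(np.int32 if arr.max(initial=0) > np.iinfo(np.uint16).max else np.uint16)
    tifffile.imwrite(
        str(path),
        arr,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"unit": "um", "axes": "YX"},
        imagej=True,
    )


def write_calibrated_image(image: CalibratedImage, path: str | Path) -> None:
    px = image.pixel_size_um
    data = image.pixels
    tifffile.imwrite(
        str(path),
        data.astype(np.float32) if np.issubdtype(data.dtype, np.floating) else data,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"unit": "um", "axes": "CYX", "Labels": list(image.channel_names)},
        imagej=True,
    )


def read_roi_archive(path: str | Path) -> list[PolygonRoi]:
    """Import an ImageJ .roi file or .zip archive as polygons (file order)."""
    return [PolygonRoi(name, verts) for name, verts in _ijroi.read_archive(str(path))]


def write_roi_archive(rois: list[PolygonRoi], path: str | Path) -> None:
    _ijroi.write_archive([(r.name, r.vertices) for r in rois], str(path))


def rasterize_rois(
    rois: list[PolygonRoi], shape: tuple[int, int], pixel_size_um: float = 1.0
) -> LabelMap:
    """Paint ROI i as label i (1-based, file order); later ROIs win overlaps.

    A pixel belongs to a polygon when its center lies inside or on the
    polygon boundary.  Vertices outside ``shape`` are effectively clipped.
    """
    out = np.zeros(shape, dtype=np.int32)
    for i, roi in enumerate(rois, start=1):
        poly = roi.to_shapely()
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor(minx)))
        c1 = min(shape[1] - 1, int(np.ceil(maxx)))
        r0 = max(0, int(np.floor(miny)))
        r1 = min(shape[0] - 1, int(np.ceil(maxy)))
        if c1 < c0 or r1 < r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        inside = shapely.intersects_xy(poly, cols.ravel().astype(float), rows.ravel().astype(float))
        inside = inside.reshape(rows.shape)
        out[r0 : r1 + 1, c0 : c1 + 1][inside] = i
    return LabelMap(out, pixel_size_um)


def outline_to_roi(vertices_xy: np.ndarray, name: str) -> PolygonRoi:
    return PolygonRoi(name, vertices_xy)


_NON_CSV_COLUMNS = ("polygon",)


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell table as UTF-8 CSV (one row per cell, header always).

    Object-valued columns (the boundary polygons) are omitted; floats are
    written with enough digits to read back to 6 significant figures.
    """
    df = cells.drop(columns=[c for c in _NON_CSV_COLUMNS if c in cells], errors="ignore")
    df.to_csv(path, index=False, float_format="%.8g", encoding="utf-8")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if "ganglion_id" in df:
        df["ganglion_id"] = df["ganglion_id"].astype("Int64")
    for col in df.columns:
        if col.startswith("marker_"):
            df[col] = df[col].astype(bool)
    return df
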