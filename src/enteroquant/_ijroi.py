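"""Minimal codec for the ImageJ ROI binary format (.roi files and .zip archives).

Only the ROI flavours the toolbox needs are handled: polygon, freehand,
traced, and oval.  Ovals are converted to 64-vertex polygons on read.
Unsupported types are skipped with a warning rather than failing the whole
archive, so archives exported from Fiji sessions containing e.g. line ROIs
remain importable.

Layout of the 64-byte big-endian header (offsets follow ImageJ's RoiDecoder):

====  =======================
0-3   magic "Iout"
4-5   version (int16)
6     roi type byte
8-15  top, left, bottom, right (int16)
16-17 n coordinates (uint16)
50-51 options (bit 7 = sub-pixel resolution)
60-63 header2 offset (int32)
64..  n int16 x coords (relative to left), n int16 y coords (relative to top),
      then, when sub-pixel: n float32 absolute x, n float32 absolute y
====  =======================

Header2 carries the ROI name as UTF-16BE at (name_offset, name_length).
"""

from __future__ import annotations

import io
import logging
import struct
import zipfile
from typing import BinaryIO

import numpy as np

logger = logging.getLogger(__name__)

_MAGIC = b"Iout"
_VERSION = 228

# roi type bytes used by ImageJ
TYPE_POLYGON = 0
TYPE_RECT = 1
TYPE_OVAL = 2
TYPE_FREEHAND = 7
TYPE_TRACED = 8

_POLYGON_TYPES = (TYPE_POLYGON, TYPE_FREEHAND, TYPE_TRACED)

_OPT_SUBPIXEL = 1 << 7

_OVAL_VERTICES = 64


class RoiDecodeError(ValueError):
    """Raised when an entry is not a decodable ImageJ ROI."""


def _oval_polygon(top: float, left: float, bottom: float, right: float) -> np.ndarray:
    """64-gon approximation of the oval inscribed in the given bounding box.

    ImageJ box coordinates are pixel-corner based; returned vertices are in
    0-based pixel-center coordinates (x, y), hence the -0.5 shift.
    """
    cy = (top + bottom) / 2.0 - 0.5
    cx = (left + right) / 2.0 - 0.5
    ry = (bottom - top) / 2.0
    rx = (right - left) / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, _OVAL_VERTICES, endpoint=False)
    return np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])


def decode_roi(data: bytes, name: str = "") -> tuple[str, np.ndarray] | None:
    """Decode one .roi blob to ``(name, vertices)``.

    Vertices are float64, shape (n, 2), columns (x, y), 0-based pixel-center
    coordinates.  Returns ``None`` for ROI types the toolbox does not support.
    Raises :class:`RoiDecodeError` for blobs that are not ImageJ ROIs at all.
    """
    if len(data) < 64 or data[:4] != _MAGIC:
        raise RoiDecodeError(f"entry {name!r}: missing 'Iout' magic bytes")
    version = struct.unpack_from(">h", data, 4)[0]
    roi_type = data[6]
    top, left, bottom, right = struct.unpack_from(">4h", data, 8)
    n = struct.unpack_from(">H", data, 16)[0]
    options = struct.unpack_from(">H", data, 50)[0]

    stored = _decode_name(data)
    if stored:
        name = stored

    if roi_type == TYPE_OVAL:
        return name, _oval_polygon(top, left, bottom, right)
    if roi_type == TYPE_RECT:
        verts = np.array(
            [
                [left, top],
                [right - 1, top],
                [right - 1, bottom - 1],
                [left, bottom - 1],
            ],
            dtype=float,
        )
        return name, verts
    if roi_type not in _POLYGON_TYPES:
        logger.warning("entry %r: unsupported ROI type %d skipped", name, roi_type)
        return None
    if n < 3:
        logger.warning("entry %r: polygon with %d < 3 vertices skipped", name, n)
        return None

    subpixel = bool(options & _OPT_SUBPIXEL) and version >= 222
    if subpixel and len(data) >= 64 + 4 * n + 8 * n:
        off = 64 + 4 * n
        xs = np.frombuffer(data, dtype=">f4", count=n, offset=off).astype(float)
        ys = np.frombuffer(data, dtype=">f4", count=n, offset=off + 4 * n).astype(float)
    else:
        if len(data) < 64 + 4 * n:
            raise RoiDecodeError(f"entry {name!r}: truncated coordinate block")
        xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
        ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return name, np.column_stack([xs, ys])


def _decode_name(data: bytes) -> str:
    h2 = struct.unpack_from(">i", data, 60)[0]
    if h2 <= 0 or h2 + 24 > len(data):
        return ""
    name_off = struct.unpack_from(">i", data, h2 + 16)[0]
    name_len = struct.unpack_from(">i", data, h2 + 20)[0]
    if name_off <= 0 or name_len <= 0 or name_off + 2 * name_len > len(data):
        return ""
    return data[name_off : name_off + 2 * name_len].decode("utf-16-be", errors="replace")


def encode_roi(vertices: np.ndarray, name: str = "") -> bytes:
    """Encode a polygon as a sub-pixel-resolution ImageJ polygon ROI."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs an (n>=3, 2) vertex array")
    n = len(verts)
    xs, ys = verts[:, 0], verts[:, 1]
    left, top = int(np.floor(xs.min())), int(np.floor(ys.min()))
    right, bottom = int(np.ceil(xs.max())) + 1, int(np.ceil(ys.max())) + 1

    buf = bytearray(64)
    buf[:4] = _MAGIC
    struct.pack_into(">h", buf, 4, _VERSION)
    buf[6] = TYPE_POLYGON
    struct.pack_into(">4h", buf, 8, top, left, bottom, right)
    struct.pack_into(">H", buf, 16, n)
    struct.pack_into(">H", buf, 50, _OPT_SUBPIXEL)

    body = bytearray()
    body += np.round(xs - left).astype(">i2").tobytes()
    body += np.round(ys - top).astype(">i2").tobytes()
    body += xs.astype(">f4").tobytes()
    body += ys.astype(">f4").tobytes()

    h2_offset = 64 + len(body)
    struct.pack_into(">i", buf, 60, h2_offset)
    header2 = bytearray(64)
    name_bytes = name.encode("utf-16-be")
    struct.pack_into(">i", header2, 16, h2_offset + 64)  # name offset
    struct.pack_into(">i", header2, 20, len(name))  # name length (chars)
    return bytes(buf) + bytes(body) + bytes(header2) + name_bytes


def read_archive(source: str | BinaryIO) -> list[tuple[str, np.ndarray]]:
    """Read a single .roi file or a .zip of .roi entries.

    Returns ``(name, vertices)`` pairs in file order; unsupported ROI types
    are skipped with a warning.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, "rb") as fh:
            data = fh.read()
    out: list[tuple[str, np.ndarray]] = []
    if data[:4] == b"PK\x03\x04":
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            for info in zf.infolist():
                if not info.filename.lower().endswith(".roi"):
                    continue
                decoded = decode_roi(zf.read(info), name=info.filename[:-4])
                if decoded is not None:
                    out.append(decoded)
    else:
        decoded = decode_roi(data)
        if decoded is not None:
            out.append(decoded)
    return out


def write_archive(rois: list[tuple[str, np.ndarray]], path: str) -> None:
    """Write polygons to a .zip of .roi entries (or one .roi if path ends so)."""
    if str(path).lower().endswith(".roi"):
        if len(rois) != 1:
            raise ValueError("a .roi file holds exactly one ROI; use .zip")
        name, verts = rois[0]
        with open(path, "wb") as fh:
            fh.write(encode_roi(verts, name))
        return
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, (name, verts) in enumerate(rois):
            entry = name or f"roi_{i + 1:04d}"
            zf.writestr(entry + ".roi", encode_roi(verts, entry))
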