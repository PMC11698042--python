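"""Brute-force reference implementations used as oracles in the tests.

These deliberately share no code with the package: edge gaps via an all-pairs
pixel-center scan, and local thickness via an exhaustive search over every
refined-grid disc center with explicit point-to-square distances (no distance
transform anywhere).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_edge_gaps(labels: np.ndarray, pixel_size_um: float, search_radius_um: float) -> dict:
    """All-pairs minimum pixel-center distance scan.

    gap(i, j) = max(0, min ||p_i − p_j|| − 1 px) · pixel_size; pairs whose gap
    exceeds the search radius are omitted.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    coords = {int(i): np.argwhere(labels == i).astype(float) for i in ids}
    dmax = search_radius_um / pixel_size_um + 1.0
    gaps = {}
    for a, i in enumerate(ids):
        for j in ids[a + 1 :]:
            dmin = cdist(coords[int(i)], coords[int(j)]).min()
            if dmin <= dmax:
                gaps[(int(i), int(j))] = max(0.0, dmin - 1.0) * pixel_size_um
    return gaps


def brute_local_thickness(mask: np.ndarray, pixel_size_um: float = 1.0) -> np.ndarray:
    """Exhaustive largest-inscribed-disc search under unit-square pixel geometry.

    Disc centers live on the half-integer refined grid covering the pixel
    boundary; the inscribed radius at a center is the minimum distance to any
    background pixel square or to the image border (outside counts as
    background).  LT(p) is the largest diameter over all discs whose center is
    within their radius of the pixel center p.
    """
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    out = np.zeros((H, W), dtype=np.float64)
    if not mask.any():
        return out

    qy = ((np.arange(2 * H + 1) - 1.0) / 2.0)[:, None]  # (A, 1)
    qx = ((np.arange(2 * W + 1) - 1.0) / 2.0)[None, :]  # (1, B)
    # distance to the image border (outside the raster is background)
    r = np.minimum.reduce(
        [
            np.broadcast_to(qy + 0.5, (qy.size, qx.size)).copy(),
            np.broadcast_to((H - 0.5) - qy, (qy.size, qx.size)),
            np.broadcast_to(qx + 0.5, (qy.size, qx.size)),
            np.broadcast_to((W - 0.5) - qx, (qy.size, qx.size)),
        ]
    )
    # distance to every background pixel square (point-to-box, vectorized)
    for row, col in np.argwhere(~mask):
        dy = np.maximum(np.maximum(row - 0.5 - qy, 0.0), qy - (row + 0.5))
        dx = np.maximum(np.maximum(col - 0.5 - qx, 0.0), qx - (col + 0.5))
        r = np.minimum(r, np.sqrt(dy * dy + dx * dx))
    r = np.maximum(r, 0.0)

    pys, pxs = np.mgrid[0:H, 0:W]
    for a, b in np.argwhere(r > 0):
        ra = r[a, b]
        cy, cx = (a - 1.0) / 2.0, (b - 1.0) / 2.0
        covered = (pys - cy) ** 2 + (pxs - cx) ** 2 <= ra * ra
        out[covered] = np.maximum(out[covered], 2.0 * ra)
    out[~mask] = 0.0
    return out * pixel_size_um
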