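"""Shared fixtures: expensive synthetic scenes are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from enteroquant.synth import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default scene with marker channels, reused across fast tests."""
    return generate_scene(SceneSpec(seed=3, marker_proportions={"calb": 0.3, "nnos": 0.4}))


@pytest.fixture(scope="session")
def default_scenes_20():
    """The 20 default scenes (seeds 0..19) used by the calibration criteria."""
    return [generate_scene(SceneSpec(seed=s)) for s in range(20)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_label_image(rng: np.random.Generator, shape=(64, 64), n_cells=12, style="discs") -> np.ndarray:
    """Random instance label images: scattered discs (gaps) or a Voronoi
    partition of a random mask (adjacent labels)."""
    H, W = shape
    out = np.zeros(shape, dtype=np.int32)
    if style == "discs":
        for i in range(1, n_cells + 1):
            r = rng.uniform(1.5, 5.0)
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            yy, xx = np.ogrid[:H, :W]
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            out[disc & (out == 0)] = i
    else:  # voronoi partition of random blobs
        seeds_y = rng.integers(0, H, n_cells)
        seeds_x = rng.integers(0, W, n_cells)
        yy, xx = np.mgrid[:H, :W]
        d2 = (yy[..., None] - seeds_y) ** 2 + (xx[..., None] - seeds_x) ** 2
        vor = np.argmin(d2, axis=-1) + 1
        mask = np.zeros(shape, dtype=bool)
        for _ in range(4):
            r = rng.uniform(4, 12)
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        out = np.where(mask, vor, 0).astype(np.int32)
    return out


def random_mask(rng: np.random.Generator, shape=(32, 32)) -> np.ndarray:
    """Random binary masks as unions of discs and rectangles."""
    H, W = shape
    yy, xx = np.ogrid[:H, :W]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(int(rng.integers(1, 5))):
        if rng.random() < 0.5:
            r = rng.uniform(1.0, 8.0)
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        else:
            r0, c0 = rng.integers(0, H - 2), rng.integers(0, W - 2)
            r1 = rng.integers(r0 + 1, min(H, r0 + 14))
            c1 = rng.integers(c0 + 1, min(W, c0 + 14))
            mask[r0:r1, c0:c1] = True
    return mask
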