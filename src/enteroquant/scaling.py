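"""Pixel-size normalisation to the species-specific working resolution.

Mouse and rat wholemounts are analysed at 0.568 µm/px and human tissue at
0.9 µm/px (human enteric neurons are larger); images acquired at any other
resolution are resampled to the target before segmentation and results are
mapped back to the native grid afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform

from .imgio import CalibratedImage, LabelMap

__all__ = ["RescalePolicy", "rescale_factor", "resample_intensity", "resample_labels", "restore_labels"]

DEFAULT_TARGETS = {"mouse": 0.568, "rat": 0.568, "human": 0.9}


@dataclass(frozen=True)
class RescalePolicy:
    """Target pixel sizes (µm/px) per species, with an optional override."""

    targets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    custom_target: float | None = None

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.targets.values()):
            raise ValueError("all pixel-size targets must be positive")
        if self.custom_target is not None and self.custom_target <= 0:
            raise ValueError("custom_target must be positive")

    def target_for(self, species: str | None) -> float:
        if self.custom_target is not None:
            return self.custom_target
        if species is None or species not in self.targets:
            raise KeyError(f"unknown species {species!r} and no custom_target set")
        return self.targets[species]


def rescale_factor(pixel_size_um: float, policy: RescalePolicy | None = None, species: str | None = "mouse") -> float:
    """Zoom factor mapping the native grid onto the target grid.

    ``factor = pixel_size_um / target``; output dimensions are
    ``round(dim * factor)`` (half away from zero) and the output pixel size is
    ``pixel_size_um / factor`` which equals the target.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    policy = policy or RescalePolicy()
    return pixel_size_um / policy.target_for(species)


def _out_dim(dim: int, factor: float) -> int:
    out = int(np.floor(dim * factor + 0.5))  # round half away from zero (positive dims)
    if out < 1:
        raise ValueError(f"rescale factor {factor} collapses a {dim}-px axis to zero")
    return out


def resample_intensity(image: CalibratedImage, factor: float) -> CalibratedImage:
    """Bilinear resampling of all channels by ``factor``; factor 1 is identity."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1.0:
        return CalibratedImage(image.pixels.copy(), image.pixel_size_um, list(image.channel_names))
    rows, cols = image.shape
    out_shape = (_out_dim(rows, factor), _out_dim(cols, factor))
    out = np.stack(
        [
            transform.resize(ch.astype(float), out_shape, order=1, mode="edge",
                             anti_aliasing=factor < 1, preserve_range=True)
            for ch in image.pixels
        ]
    )
    return CalibratedImage(out, image.pixel_size_um / factor, list(image.channel_names))


def resample_labels(labels: LabelMap, factor: float) -> LabelMap:
    """Nearest-neighbour resampling of a label map (no label mixing)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1.0:
        return LabelMap(labels.labels.copy(), labels.pixel_size_um)
    rows, cols = labels.shape
    out_shape = (_out_dim(rows, factor), _out_dim(cols, factor))
    out = transform.resize(labels.labels, out_shape, order=0, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    return LabelMap(out.astype(labels.labels.dtype), labels.pixel_size_um / factor)


def restore_labels(labels: LabelMap, original_shape: tuple[int, int], original_pixel_size_um: float | None = None) -> LabelMap:
    """Map a label map produced at working resolution back to the native grid."""
    if labels.shape == tuple(original_shape):
        return LabelMap(labels.labels.copy(), original_pixel_size_um or labels.pixel_size_um)
    out = transform.resize(labels.labels, original_shape, order=0, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    if original_pixel_size_um is None:
        original_pixel_size_um = labels.pixel_size_um * labels.shape[0] / original_shape[0]
    return LabelMap(out.astype(labels.labels.dtype), original_pixel_size_um)
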