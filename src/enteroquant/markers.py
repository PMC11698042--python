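"""Neurochemical-marker positivity calls and multi-marker combinations.

Two calling modes are provided, configurable per marker:

* ``label_overlap`` — when a subtype segmentation exists: a Hu cell is
  positive when at least a fraction ``f`` (default 0.5) of its pixels are
  covered by any subtype label;
* ``intensity`` — otherwise: positive when the cell's mean channel intensity
  exceeds the robust background level, ``median + k·MAD`` of the non-cell
  pixels (default k = 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgio import LabelMap

__all__ = [
    "MarkerRule",
    "positive_by_overlap",
    "positive_by_intensity",
    "combine_markers",
    "marker_summary",
]


@dataclass(frozen=True)
class MarkerRule:
    """How a marker is called: exactly one of the two modes."""

    marker_name: str
    mode: str = "label_overlap"  # or "intensity"
    overlap_fraction: float = 0.5
    intensity_k: float = 3.0
    channel: str | None = None  # intensity mode: channel name
    labels_path: str | None = None  # overlap mode: subtype label map source

    def __post_init__(self) -> None:
        if self.mode not in ("label_overlap", "intensity"):
            raise ValueError(f"unknown marker mode {self.mode!r}")
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in (0, 1]")


def positive_by_overlap(
    cells: pd.DataFrame,
    cell_labels: LabelMap,
    subtype_labels: LabelMap | np.ndarray,
    f: float = 0.5,
) -> np.ndarray:
    """Positive iff (cell pixels covered by any subtype label) / cell area >= f."""
    sub = subtype_labels.labels if isinstance(subtype_labels, LabelMap) else np.asarray(subtype_labels)
    if sub.shape != cell_labels.shape:
        raise ValueError("subtype label map must match the cell label map shape")
    if not (0 < f <= 1):
        raise ValueError("f must lie in (0, 1]")
    labels = cell_labels.labels
    n_max = int(labels.max()) + 1
    area = np.bincount(labels.ravel(), minlength=n_max)
    covered = np.bincount(labels.ravel(), weights=(sub > 0).ravel(), minlength=n_max)
    with np.errstate(invalid="ignore"):
        frac = np.where(area > 0, covered / np.maximum(area, 1), 0.0)
    return np.array([frac[int(i)] >= f for i in cells["id"]], dtype=bool)


def positive_by_intensity(
    cells: pd.DataFrame,
    cell_labels: LabelMap,
    channel: np.ndarray,
    k: float = 3.0,
) -> np.ndarray:
    """Positive iff mean cell intensity >= background median + k · background MAD.

    Background statistics come from the non-cell pixels of the channel.  With
    k = 0 a cell is positive whenever its mean exceeds the background median.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != cell_labels.shape:
        raise ValueError("channel must match the cell label map shape")
    labels = cell_labels.labels
    bg = channel[labels == 0]
    if bg.size == 0:
        raise ValueError("no background pixels to estimate the threshold from")
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    cut = med + k * mad
    n_max = int(labels.max()) + 1
    area = np.bincount(labels.ravel(), minlength=n_max)
    total = np.bincount(labels.ravel(), weights=channel.ravel(), minlength=n_max)
    mean = np.where(area > 0, total / np.maximum(area, 1), 0.0)
    return np.array([mean[int(i)] >= cut for i in cells["id"]], dtype=bool)


def combine_markers(
    flags_a: np.ndarray, flags_b: np.ndarray, op: str = "AND"
) -> tuple[np.ndarray, dict[str, float]]:
    """Element-wise boolean combination plus proportion summary.

    The summary reports counts and percentages of the total (Hu) cell count
    for each flag and for the combination.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag arrays must have equal length")
    ops = {
        "AND": a & b,
        "OR": a | b,
        "XOR": a ^ b,
        "A_NOT_B": a & ~b,
        "B_NOT_A": b & ~a,
    }
    if op not in ops:
        raise ValueError(f"unknown op {op!r}; choose from {sorted(ops)}")
    combined = ops[op]
    n = a.size
    summary = {
        "n_cells": n,
        "count_a": int(a.sum()),
        "count_b": int(b.sum()),
        "count_combined": int(combined.sum()),
        "percent_a": 100.0 * a.mean() if n else 0.0,
        "percent_b": 100.0 * b.mean() if n else 0.0,
        "percent_combined": 100.0 * combined.mean() if n else 0.0,
    }
    return combined, summary


def marker_summary(cells: pd.DataFrame) -> pd.DataFrame:
    """Counts and % of total Hu cells for every marker_* column in the table."""
    rows = []
    n = len(cells)
    for col in cells.columns:
        if not col.startswith("marker_"):
            continue
        count = int(cells[col].sum())
        rows.append(
            {
                "marker": col[len("marker_"):],
                "count": count,
                "percent_of_hu": 100.0 * count / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["marker", "count", "percent_of_hu"])
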