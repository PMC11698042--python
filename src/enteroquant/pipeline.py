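"""End-to-end orchestration: validated run configuration, the quantification
pipeline (rescale → segment/import → ganglia → assign → markers → spatial →
write), multi-image aggregation, and the tile-sampling experiment.

A run is fully described by a :class:`RunConfig` (optionally loaded from a
TOML file with an explicit schema version; unknown keys are errors so typos
fail loudly) and is deterministic: rerunning the same config writes
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
import tomllib
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .ganglia import (
    GangliaMask,
    GanglionStats,
    assign_cells,
    ganglia_by_expansion,
    ganglia_from_probability,
    ganglia_stats,
)
from .imgio import (
    CalibratedImage,
    LabelMap,
    outline_to_roi,
    read_calibrated_image,
    read_label_map,
    write_cell_table,
    write_label_map,
    write_roi_archive,
)
from .markers import MarkerRule, positive_by_intensity, positive_by_overlap
from .scaling import RescalePolicy, rescale_factor, resample_intensity, resample_labels
from .segment import SegmentationParams, build_cell_table, segment_cells_baseline
from .spatial import PnResult, SpatialConfig, edge_distance_graph, neighbor_count_map, pn_counts

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunResult",
    "TileSamplingResult",
    "run_quantify",
    "aggregate",
    "tile_sampling_experiment",
]

SCHEMA_VERSION = 1


def _check_keys(table: dict, allowed: set[str], context: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one quantification run."""

    image: str
    out_dir: str
    pixel_size_um: float | None = None
    hu_channel: str = "hu"
    species: str | None = "mouse"
    target_um_per_px: float | None = None
    rescale: bool = True
    seg_source: str = "baseline"  # or "import"
    labels_path: str | None = None
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    ganglia_mode: str = "expand"  # expand | prob | import
    expand_um: float | None = None
    prob_threshold: float = 0.8
    ganglia_path: str | None = None
    markers: tuple[MarkerRule, ...] = ()
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seg_source not in ("baseline", "import"):
            raise ValueError("seg_source must be 'baseline' or 'import'")
        if self.seg_source == "import" and not self.labels_path:
            raise ValueError("seg_source 'import' requires labels_path")
        if self.ganglia_mode not in ("expand", "prob", "import"):
            raise ValueError("ganglia_mode must be 'expand', 'prob' or 'import'")
        if self.ganglia_mode in ("prob", "import") and not self.ganglia_path:
            raise ValueError(f"ganglia_mode {self.ganglia_mode!r} requires ganglia_path")
        for rule in self.markers:
            if rule.mode == "intensity" and not rule.channel:
                raise ValueError(f"marker {rule.marker_name!r}: intensity mode needs a channel")
            if rule.mode == "label_overlap" and not rule.labels_path:
                raise ValueError(f"marker {rule.marker_name!r}: label_overlap mode needs labels_path")

    def validate_paths(self) -> None:
        """Check that every referenced input file exists."""
        paths = [self.image, self.labels_path, self.ganglia_path]
        paths += [r.labels_path for r in self.markers if r.labels_path]
        for p in paths:
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls.from_dict(doc, base_dir=path.parent)

    @classmethod
    def from_dict(cls, doc: dict, base_dir: str | Path = ".") -> "RunConfig":
        base = Path(base_dir)
        _check_keys(
            doc,
            {"schema_version", "seed", "input", "rescale", "segmentation", "ganglia", "markers", "spatial", "output"},
            "config root",
        )
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"config schema_version must be {SCHEMA_VERSION}, got {doc.get('schema_version')!r}")

        def resolve(p):
            return str(base / p) if p is not None else None

        inp = doc.get("input", {})
        _check_keys(inp, {"image", "pixel_size_um", "hu_channel"}, "[input]")
        res = doc.get("rescale", {})
        _check_keys(res, {"species", "target_um_per_px", "enabled"}, "[rescale]")
        seg = doc.get("segmentation", {})
        _check_keys(seg, {"source", "labels", "params"}, "[segmentation]")
        seg_param_fields = {f.name for f in dataclasses.fields(SegmentationParams)}
        _check_keys(seg.get("params", {}), seg_param_fields, "[segmentation.params]")
        gan = doc.get("ganglia", {})
        _check_keys(gan, {"mode", "expand_um", "prob_threshold", "path"}, "[ganglia]")
        spa = doc.get("spatial", {})
        _check_keys(spa, {"threshold_um", "search_radius_um"}, "[spatial]")
        out = doc.get("output", {})
        _check_keys(out, {"dir"}, "[output]")
        rules = []
        for m in doc.get("markers", []):
            _check_keys(
                m,
                {"name", "mode", "channel", "labels", "overlap_fraction", "intensity_k"},
                "[[markers]]",
            )
            rules.append(
                MarkerRule(
                    marker_name=m["name"],
                    mode=m.get("mode", "label_overlap"),
                    overlap_fraction=m.get("overlap_fraction", 0.5),
                    intensity_k=m.get("intensity_k", 3.0),
                    channel=m.get("channel"),
                    labels_path=resolve(m.get("labels")),
                )
            )
        if "image" not in inp:
            raise ValueError("[input] image is required")
        if "dir" not in out:
            raise ValueError("[output] dir is required")
        return cls(
            image=resolve(inp["image"]),
            out_dir=resolve(out["dir"]),
            pixel_size_um=inp.get("pixel_size_um"),
            hu_channel=inp.get("hu_channel", "hu"),
            species=res.get("species", "mouse"),
            target_um_per_px=res.get("target_um_per_px"),
            rescale=res.get("enabled", True),
            seg_source=seg.get("source", "baseline"),
            labels_path=resolve(seg.get("labels")),
            seg_params=SegmentationParams(**seg.get("params", {})),
            ganglia_mode=gan.get("mode", "expand"),
            expand_um=gan.get("expand_um"),
            prob_threshold=gan.get("prob_threshold", 0.8),
            ganglia_path=resolve(gan.get("path")),
            markers=tuple(rules),
            spatial=SpatialConfig(
                threshold_um=spa.get("threshold_um", SpatialConfig().threshold_um),
                search_radius_um=spa.get("search_radius_um"),
            ),
            seed=doc.get("seed", 0),
        )


@dataclass
class RunResult:
    """Bundle of one quantification run: tables, stats and written artifacts."""

    image_name: str
    out_dir: str
    cells: pd.DataFrame
    cell_labels: LabelMap
    ganglia: GangliaMask
    stats: GanglionStats
    pn: PnResult
    paths: dict[str, str]
    timings_s: dict[str, float]

    def summary_row(self) -> dict:
        return _summary_row(self.image_name, self.cells, self.stats, self.pn)


def _summary_row(image_name: str, cells: pd.DataFrame, stats: GanglionStats, pn: PnResult) -> dict:
    row: dict = {
        "image": image_name,
        "n_cells_hu": len(cells),
        "n_ganglia": stats.n_ganglia,
        "mean_cells_per_ganglion": stats.mean_cells_per_ganglion,
        "median_cells_per_ganglion": stats.median_cells_per_ganglion,
        "ganglionic_area_um2": stats.total_area_um2,
        "neurons_per_mm2": stats.neurons_per_mm2,
    }
    n = len(cells)
    for col in cells.columns:
        if col.startswith("marker_"):
            count = int(cells[col].sum())
            row[f"count_{col[7:]}"] = count
            row[f"percent_{col[7:]}"] = 100.0 * count / n if n else 0.0
    for k, v in pn.histogram.items():
        row[f"pn_{k}_raw"] = v
    for k, v in pn.normalized.items():
        row[f"pn_{k}_norm"] = v
    return row


class _StageTimer:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}
        self._stage: str | None = None
        self._t0 = 0.0

    def stage(self, name: str):
        self._stage = name
        return self

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self._stage] = time.perf_counter() - self._t0
        if exc is not None and not isinstance(exc, _StageFailure):
            raise _StageFailure(self._stage, exc) from exc
        return False


class _StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _package_version() -> str:
    try:
        return metadata.version("enteroquant")
    except metadata.PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


def run_quantify(config: RunConfig) -> RunResult:
    """Execute the full quantification pipeline described by ``config``.

    Stage failures abort with the stage name; partially written outputs are
    removed.  Reruns with the same config produce byte-identical tables.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timer = _StageTimer()
    try:
        with timer.stage("load"):
            image = read_calibrated_image(config.image, pixel_size_um=config.pixel_size_um)

        with timer.stage("rescale"):
            factor = 1.0
            if config.rescale:
                policy = RescalePolicy(custom_target=config.target_um_per_px)
                factor = rescale_factor(image.pixel_size_um, policy, config.species)
                image = resample_intensity(image, factor)

        with timer.stage("segment"):
            if config.seg_source == "import":
                labels = read_label_map(config.labels_path, pixel_size_um=None)
                if labels.pixel_size_um == 1.0:
                    labels = LabelMap(labels.labels, image.pixel_size_um * factor)
                labels = resample_labels(labels, factor)
            else:
                labels = segment_cells_baseline(
                    image.channel(config.hu_channel), image.pixel_size_um, config.seg_params
                )
            if labels.shape != image.shape:
                raise ValueError(
                    f"label grid {labels.shape} does not match the working image grid {image.shape}"
                )

        with timer.stage("cells"):
            cells = build_cell_table(labels, image)

        with timer.stage("ganglia"):
            if config.ganglia_mode == "expand":
                ganglia = ganglia_by_expansion(labels, config.expand_um)
            elif config.ganglia_mode == "prob":
                prob = read_calibrated_image(config.ganglia_path, pixel_size_um=labels.pixel_size_um)
                ganglia = ganglia_from_probability(
                    prob.pixels[0], config.prob_threshold, pixel_size_um=labels.pixel_size_um
                )
            else:
                glab = read_label_map(config.ganglia_path, pixel_size_um=labels.pixel_size_um)
                glab = resample_labels(glab, factor)
                ganglia = GangliaMask(glab, "imported")
            if ganglia.labels.shape != labels.shape:
                raise ValueError("ganglia mask grid does not match the cell label grid")
            cells = assign_cells(cells, labels, ganglia)
            stats = ganglia_stats(cells, ganglia)

        with timer.stage("markers"):
            for rule in config.markers:
                if rule.mode == "label_overlap":
                    sub = read_label_map(rule.labels_path)
                    sub = resample_labels(LabelMap(sub.labels, labels.pixel_size_um * factor), factor)
                    flags = positive_by_overlap(cells, labels, sub, rule.overlap_fraction)
                else:
                    flags = positive_by_intensity(
                        cells, labels, image.channel(rule.channel), rule.intensity_k
                    )
                cells[f"marker_{rule.marker_name}"] = flags

        with timer.stage("spatial"):
            graph = edge_distance_graph(labels, config.spatial)
            pn = pn_counts(graph, config.spatial)
            order = {int(i): n for n, i in enumerate(pn.ids)}
            cells["pn_count"] = [pn.counts[order[int(i)]] for i in cells["id"]]
            count_map = neighbor_count_map(labels, pn)

        with timer.stage("write"):
            paths: dict[str, str] = {}

            def emit(name: str, writer) -> None:
                p = out_dir / name
                writer(p)
                written.append(p)
                paths[name] = str(p)

            emit("cells.csv", lambda p: write_cell_table(cells, p))
            emit("labels.tif", lambda p: write_label_map(labels, p))
            emit("ganglia.tif", lambda p: write_label_map(ganglia.labels, p))
            rois = [outline_to_roi(row.polygon, f"cell-{row.id:04d}") for row in cells.itertuples()]
            if rois:
                emit("rois.zip", lambda p: write_roi_archive(rois, p))
            hist = pd.DataFrame(
                {
                    "k": sorted(pn.histogram),
                    "count": [pn.histogram[k] for k in sorted(pn.histogram)],
                    "fraction": [pn.normalized[k] for k in sorted(pn.histogram)],
                }
            )
            emit("pn_histogram.csv", lambda p: hist.to_csv(p, index=False))
            # map is stored as k+1 so that 0 stays the TIFF background value
            emit(
                "neighbor_count_map.tif",
                lambda p: write_label_map(LabelMap(count_map + 1, labels.pixel_size_um), p),
            )
            summary = _summary_row(Path(config.image).stem, cells, stats, pn)
            emit("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2)))
            log = {
                "schema_version": SCHEMA_VERSION,
                "package_version": _package_version(),
                "seed": config.seed,
                "config": {
                    k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                    for k, v in dataclasses.asdict(config).items()
                },
                "stage_timings_s": timer.timings,
                "n_cells": len(cells),
                "n_ganglia": stats.n_ganglia,
            }
            emit("run_log.json", lambda p: p.write_text(json.dumps(log, indent=2, default=str)))
    except _StageFailure:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return RunResult(
        image_name=Path(config.image).stem,
        out_dir=str(out_dir),
        cells=cells,
        cell_labels=labels,
        ganglia=ganglia,
        stats=stats,
        pn=pn,
        paths=paths,
        timings_s=timer.timings,
    )


def aggregate(bundles: list[RunResult]) -> pd.DataFrame:
    """One summary row per image, sorted by image name.

    Bundles with differing marker sets are merged on the union of columns
    (missing markers become nulls) with a warning.
    """
    if not bundles:
        raise ValueError("aggregate needs at least one result bundle")
    marker_sets = [
        frozenset(c for c in b.cells.columns if c.startswith("marker_")) for b in bundles
    ]
    if len(set(marker_sets)) > 1:
        logger.warning("bundles have differing marker sets; aggregating on their union with nulls")
    rows = [b.summary_row() for b in bundles]
    table = pd.DataFrame(rows).sort_values("image", kind="stable").reset_index(drop=True)
    return table


@dataclass(frozen=True)
class TileSamplingResult:
    """Monte-Carlo tile-sampling estimates of neuron density."""

    estimates_per_mm2: np.ndarray  # one density estimate per repeat
    full_density_per_mm2: float
    tile_area_um2: float  # realised tile area after partitioning
    n_tiles_available: int
    n_tiles: int
    n_repeats: int

    @property
    def mean_density_per_mm2(self) -> float:
        return float(np.mean(self.estimates_per_mm2))

    @property
    def sd_density_per_mm2(self) -> float:
        return float(np.std(self.estimates_per_mm2, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def relative_error(self) -> float:
        if self.full_density_per_mm2 == 0:
            return float("nan")
        return abs(self.mean_density_per_mm2 - self.full_density_per_mm2) / self.full_density_per_mm2

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tile_area_um2": self.tile_area_um2,
                    "n_tiles_available": self.n_tiles_available,
                    "n_tiles": self.n_tiles,
                    "n_repeats": self.n_repeats,
                    "mean_density_per_mm2": self.mean_density_per_mm2,
                    "sd_density_per_mm2": self.sd_density_per_mm2,
                    "full_density_per_mm2": self.full_density_per_mm2,
                    "relative_error": self.relative_error,
                }
            ]
        )


def tile_sampling_experiment(
    cells: pd.DataFrame,
    image_area_um2: float,
    tile_area_um2: float,
    n_tiles: int,
    seed: int,
    min_tile_area_um2: float = 60000.0,
    n_repeats: int = 100,
    bounds_um: tuple[float, float] | None = None,
) -> TileSamplingResult:
    """Estimate neuron density from randomly sampled tiles.

    The field (``bounds_um`` = (width, height), default a square of
    ``image_area_um2``) is partitioned into equal square-ish tiles of
    approximately ``tile_area_um2``; partitions whose tile falls below
    ``min_tile_area_um2`` are rejected.  Each of ``n_repeats`` seeded repeats
    draws ``n_tiles`` tiles without replacement and estimates density as cells
    in the drawn tiles divided by their total area.
    """
    if bounds_um is None:
        side = math.sqrt(image_area_um2)
        bounds_um = (side, side)
    width, height = bounds_um
    if tile_area_um2 <= 0 or n_tiles < 1 or n_repeats < 1:
        raise ValueError("tile_area_um2, n_tiles and n_repeats must be positive")
    side = math.sqrt(tile_area_um2)
    nx = max(1, int(round(width / side)))
    ny = max(1, int(round(height / side)))
    tile_w, tile_h = width / nx, height / ny
    actual_area = tile_w * tile_h
    if actual_area < min_tile_area_um2:
        raise ValueError(
            f"tiles of {actual_area:.0f} um^2 fall below the minimum of {min_tile_area_um2:.0f} um^2"
        )
    n_avail = nx * ny
    if n_tiles > n_avail:
        raise ValueError(f"n_tiles={n_tiles} exceeds the {n_avail} available tiles")

    x = cells["centroid_x_um"].to_numpy()
    y = cells["centroid_y_um"].to_numpy()
    ix = np.clip((x / tile_w).astype(int), 0, nx - 1)
    iy = np.clip((y / tile_h).astype(int), 0, ny - 1)
    tile_counts = np.bincount(iy * nx + ix, minlength=n_avail)

    rng = np.random.default_rng(seed)
    estimates = np.empty(n_repeats)
    for r in range(n_repeats):
        draw = rng.choice(n_avail, size=n_tiles, replace=False)
        estimates[r] = tile_counts[draw].sum() / (n_tiles * actual_area) * 1e6

    full_density = tile_counts.sum() / (n_avail * actual_area) * 1e6
    return TileSamplingResult(
        estimates_per_mm2=estimates,
        full_density_per_mm2=float(full_density),
        tile_area_um2=float(actual_area),
        n_tiles_available=n_avail,
        n_tiles=n_tiles,
        n_repeats=n_repeats,
    )
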