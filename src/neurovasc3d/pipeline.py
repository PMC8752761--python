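"""Batch orchestration: segment → morphometry → microglia → stats.

A run is configured by a YAML manifest listing images (one row per
acquisition: channel file paths, region, animal metadata) plus parameter
overrides.  Each image yields vessel and pericyte masks, the classified
medial axis, vascular metrics, microglia detections with interaction
metrics and the planar distribution; results aggregate into tidy tables and
the statistics stage runs per metric × region.  Per-image seeds derive
deterministically from the master seed and the image id so batch order
never changes results.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as nvio
from .geometry import BinaryVolume, IntensityVolume
from .microglia import DetectionParams, detect_somata, planar_distribution, vessel_interaction
from .morphometry import compute_vascular_metrics, thin_to_medial_axis
from .segmentation import SegmentationParams, segment_channel, segment_pericytes
from .stats import analyze_metric_table

logger = logging.getLogger("neurovasc3d")

REGIONS = ("anterior cortex", "parietal cortex", "occipital cortex", "hippocampus")
CORTICAL_REGIONS = ("anterior cortex", "parietal cortex", "occipital cortex")


@dataclass
class ImageEntry:
    image_id: str
    endothelium: str
    region: str
    microglia: str | None = None
    pericyte: str | None = None
    animal_id: str = ""
    litter_id: str = ""
    diet: str = ""
    sex: str = ""
    spacing_zyx: tuple[float, float, float] | None = None


@dataclass
class RunConfig:
    images: list[ImageEntry]
    out_dir: str
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    tortuosity_radius_um: float = 20.0
    regions: tuple[str, ...] = REGIONS
    run_stats: bool = True

    def __post_init__(self) -> None:
        vocab = set(self.regions)
        for entry in self.images:
            if entry.region not in vocab:
                raise ValueError(f"image {entry.image_id}: unknown region "
                                 f"'{entry.region}' (vocabulary: {sorted(vocab)})")


def load_run_config(path: str) -> RunConfig:
    """Parse a YAML run configuration (manifest + parameter overrides)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        return p if p is None or os.path.isabs(p) else os.path.join(base, p)

    images = []
    for row in raw.get("images", []):
        row = dict(row)
        for key in ("endothelium", "pericyte", "microglia"):
            if key in row:
                row[key] = resolve(row[key])
        if "spacing_zyx" in row and row["spacing_zyx"] is not None:
            row["spacing_zyx"] = tuple(row["spacing_zyx"])
        images.append(ImageEntry(**row))
    seg = SegmentationParams(**raw.get("segmentation", {}))
    det = DetectionParams(**raw.get("detection", {}))
    return RunConfig(
        images=images,
        out_dir=resolve(raw.get("out_dir", "nvu_out")),
        seed=int(raw.get("seed", 0)),
        segmentation=seg,
        detection=det,
        tortuosity_radius_um=float(raw.get("tortuosity_radius_um", 20.0)),
        regions=tuple(raw.get("regions", REGIONS)),
        run_stats=bool(raw.get("run_stats", True)),
    )


def derive_seed(master_seed: int, image_id: str) -> int:
    """Stable per-image seed below 2^31, independent of batch order."""
    return (int(master_seed) * 1000003 + zlib.crc32(image_id.encode())) % (2 ** 31)


def analyze_image(entry: ImageEntry, config: RunConfig) -> tuple[list[dict], list[dict]]:
    """Run every stage on one image; returns (metric rows, cell rows)."""
    endo = nvio.read_stack(entry.endothelium, spacing_override=entry.spacing_zyx,
                           channel="endothelium")
    vessel_mask = segment_channel(endo, config.segmentation)
    peri_mask = None
    if entry.pericyte:
        peri = nvio.read_stack(entry.pericyte, spacing_override=entry.spacing_zyx,
                               channel="pericyte")
        peri_mask = segment_pericytes(peri, config.segmentation)
    axis = thin_to_medial_axis(vessel_mask)
    vasc = compute_vascular_metrics(axis, peri_mask, config.tortuosity_radius_um)

    meta = {"image_id": entry.image_id, "animal_id": entry.animal_id,
            "litter_id": entry.litter_id, "diet": entry.diet, "sex": entry.sex,
            "region": entry.region}
    metrics = [
        dict(meta, metric="length_density_mm_per_mm3", value=vasc.length_density),
        dict(meta, metric="branch_density_per_mm3", value=vasc.branch_density),
        dict(meta, metric="mean_tortuosity_um", value=vasc.mean_tortuosity),
    ]
    if vasc.pericyte_coverage is not None:
        metrics.append(dict(meta, metric="pericyte_coverage", value=vasc.pericyte_coverage))

    cells: list[dict] = []
    if entry.microglia:
        micro = nvio.read_stack(entry.microglia, spacing_override=entry.spacing_zyx,
                                channel="microglia")
        det_params = DetectionParams(
            log_sigma=config.detection.log_sigma,
            peak_threshold=config.detection.peak_threshold,
            sphere_radius=config.detection.sphere_radius,
            max_overlap=config.detection.max_overlap,
            contact_distance=config.detection.contact_distance,
            rng_seed=derive_seed(config.seed, entry.image_id),
        )
        detections = detect_somata(micro, det_params)
        if vessel_mask.values.any() and detections:
            inter = vessel_interaction(detections, vessel_mask, det_params)
            metrics += [
                dict(meta, metric="microglia_density_per_mm3", value=inter.density_3d),
                dict(meta, metric="microglia_mean_distance_um", value=inter.mean_distance),
                dict(meta, metric="microglia_contact_ratio", value=inter.contact_ratio),
            ]
            for i, (d, c) in enumerate(zip(inter.distances, inter.contacts)):
                z, y, x = detections[i].center
                cells.append(dict(meta, cell_id=i, z_um=z, y_um=y, x_um=x,
                                  response=detections[i].response,
                                  dist_to_vessel_um=float(d), contact=bool(c)))
        # planar branch on projected detections
        centers = np.array([d.center for d in detections]).reshape(-1, 3)
        geom = micro.geometry
        area_mm2 = (geom.shape_zyx[1] * geom.spacing_zyx[1] *
                    geom.shape_zyx[2] * geom.spacing_zyx[2]) * 1e-6
        planar = planar_distribution(centers[:, 1:], area_mm2)
        metrics.append(dict(meta, metric="microglia_density_2d_per_mm2",
                            value=planar.density_2d))
        if planar.cell_count >= 2:
            metrics += [
                dict(meta, metric="microglia_mean_nnd_um", value=planar.mean_nnd),
                dict(meta, metric="microglia_spacing_index", value=planar.spacing_index),
            ]
    return metrics, cells


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the batch; writes metrics.csv, cells.csv, stats.csv and a JSONL log.

    A stage failure on one image is logged and reported without aborting the
    rest of the batch.  Fixed seed → byte-identical output tables.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run_log.jsonl")
    metric_rows: list[dict] = []
    cell_rows: list[dict] = []
    failures: list[dict] = []
    with open(log_path, "w") as log:
        log.write(json.dumps({"event": "start", "seed": config.seed,
                              "n_images": len(config.images),
                              "segmentation": vars(config.segmentation).copy(),
                              "detection": {k: float(v) if isinstance(v, float) else v
                                            for k, v in vars(config.detection).items()},
                              "tortuosity_radius_um": config.tortuosity_radius_um},
                             sort_keys=True) + "\n")
        for entry in sorted(config.images, key=lambda e: e.image_id):
            try:
                m, c = analyze_image(entry, config)
                metric_rows += m
                cell_rows += c
                log.write(json.dumps({"event": "image_done", "image_id": entry.image_id,
                                      "n_metrics": len(m), "n_cells": len(c)},
                                     sort_keys=True) + "\n")
            except Exception as exc:  # keep the batch alive
                failures.append({"image_id": entry.image_id, "error": str(exc)})
                logger.warning("image %s failed: %s", entry.image_id, exc)
                log.write(json.dumps({"event": "image_failed",
                                      "image_id": entry.image_id,
                                      "error": str(exc)}, sort_keys=True) + "\n")
        metrics = pd.DataFrame(metric_rows)
        cells = pd.DataFrame(cell_rows)
        metrics_path = os.path.join(config.out_dir, "metrics.csv")
        cells_path = os.path.join(config.out_dir, "cells.csv")
        metrics.to_csv(metrics_path, index=False)
        cells.to_csv(cells_path, index=False)

        stats_df = outliers = None
        if config.run_stats and len(metrics) and metrics["diet"].nunique() > 1:
            stats_df, outliers = analyze_metric_table(metrics)
            stats_df.to_csv(os.path.join(config.out_dir, "stats.csv"), index=False)
            outliers.to_csv(os.path.join(config.out_dir, "outliers.csv"), index=False)
            log.write(json.dumps({"event": "stats_done",
                                  "n_tests": len(stats_df)}, sort_keys=True) + "\n")
        log.write(json.dumps({"event": "end", "n_failures": len(failures)},
                             sort_keys=True) + "\n")
    return {"metrics": metrics, "cells": cells, "stats": stats_df,
            "outliers": outliers, "failures": failures, "log_path": log_path}
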