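"""End-to-end validation suite on phantoms with analytic ground truth.

Each function builds a scene from the continuous specification, runs the
relevant pipeline stages on the rendered channels, and returns the measured
quantities next to their analytic references.  The suite backs both the
acceptance tests and the reproduction script; ground truth always derives
from the scene specification, never from the rendered voxels.

Default scene conditions mirror the target acquisition (≈1 µm sampling,
structure amplitude 150 over background 10, 1 µm optical blur, additive
noise σ = 15); segmentation of these noisy scenes uses a threshold factor
of 2.0 over the 40 µm local mean with 1 µm denoising (≈ background + 4
effective-noise SD, see the methods note).
"""

from __future__ import annotations

import hashlib
import os
import tempfile

import numpy as np
import pandas as pd

from .geometry import BinaryVolume
from .io import write_stack
from .microglia import DetectionParams, detect_somata, detection_f1, planar_distribution, \
    sphere_overlap_fraction, vessel_interaction
from .morphometry import junction_count, pericyte_coverage, thin_to_medial_axis, tortuosity
from .phantoms import SceneConfig, Sleeve, Tube, arc_curve, cells_at_wall_distances, \
    generate_scene, helix_curve, line_curve, rasterise_tube_mask, reference_tortuosity
from .pipeline import ImageEntry, RunConfig, run_pipeline
from .segmentation import SegmentationParams, segment_channel, segment_pericytes
from .stats import grubbs_filter, two_way_anova

PHANTOM_SEG = SegmentationParams(threshold_factor=2.0, smoothing_sigma_um=1.0)


def tree_scene(seed: int) -> SceneConfig:
    """Three-junction vessel tree in a 64×256×256 µm³ volume (1 µm iso)."""
    j1, j2, j3 = (32.0, 128.0, 60.0), (32.0, 70.0, 150.0), (32.0, 186.0, 150.0)
    tubes = [Tube(line_curve((32, 128, 8), j1), 3.0),
             Tube(line_curve(j1, j2), 3.0), Tube(line_curve(j1, j3), 3.0),
             Tube(line_curve(j2, (32, 40, 248)), 3.0),
             Tube(line_curve(j2, (20, 110, 248)), 3.0),
             Tube(line_curve(j3, (32, 216, 248)), 3.0),
             Tube(line_curve(j3, (44, 150, 248)), 3.0)]
    return SceneConfig(shape_zyx=(64, 256, 256), tubes=tubes,
                       branch_points_um=[j1, j2, j3], rng_seed=seed)


def validate_tree_recovery(seed: int) -> dict:
    """Length density and branch count of the noisy tree vs analytic truth."""
    cfg = tree_scene(seed)
    channels, truth = generate_scene(cfg)
    mask = segment_channel(channels["endothelium"], PHANTOM_SEG)
    axis = thin_to_medial_axis(mask)
    vol_mm3 = cfg.geometry.volume_mm3
    recovered = axis.path_length_um() / 1000.0 / vol_mm3
    true_density = truth.true_total_length_um / 1000.0 / vol_mm3
    return {
        "length_density_recovered_mm_per_mm3": recovered,
        "length_density_true_mm_per_mm3": true_density,
        "length_error_pct": 100.0 * abs(recovered - true_density) / true_density,
        "branch_count_recovered": junction_count(axis),
        "branch_count_true": truth.true_branch_count,
        "n_axis_voxels": axis.n_voxels,
    }


def validate_tortuosity(seed: int) -> dict:
    """Straight / arc / helix tube tortuosity vs the continuous oracle."""
    def measure(curve, shape, noise=None):
        cfg = SceneConfig(shape_zyx=shape, tubes=[Tube(curve, 3.0)], rng_seed=seed)
        if noise is not None:
            from dataclasses import replace
            cfg = replace(cfg, noise_sigma=noise)
        channels, _ = generate_scene(cfg)
        mask = segment_channel(channels["endothelium"], PHANTOM_SEG)
        return tortuosity(thin_to_medial_axis(mask)).mean

    # the zero-tortuosity null is a property of the estimator; sensor noise
    # adds a skeleton wiggle floor of ~0.1 µm that would mask it
    straight = measure(line_curve((27, 40, 5), (27, 40, 195)), (54, 80, 200),
                       noise=0.0)
    arc = arc_curve((27, 20, 100), radius=70.0, angle_span=0.45 * np.pi,
                    plane="yx", phase=0.28 * np.pi)
    helix = helix_curve((27, 60, 10), radius=12.0, pitch=60.0, turns=3.0, axis="x")
    arc_m, arc_o = measure(arc, (54, 120, 200)), reference_tortuosity(arc)
    hel_m, hel_o = measure(helix, (54, 120, 200)), reference_tortuosity(helix)
    return {
        "straight_tube_mean_tortuosity_um": straight,
        "arc_tortuosity_um": arc_m, "arc_tortuosity_oracle_um": arc_o,
        "arc_tortuosity_error_pct": 100.0 * abs(arc_m - arc_o) / arc_o,
        "helix_tortuosity_um": hel_m, "helix_tortuosity_oracle_um": hel_o,
        "helix_tortuosity_error_pct": 100.0 * abs(hel_m - hel_o) / hel_o,
    }


def validate_component_filter() -> dict:
    """Bright cubes of 400 and 800 µm³: the 500 µm³ cutoff keeps one."""
    from scipy import ndimage

    from .geometry import IntensityVolume, VoxelGeometry

    data = np.full((40, 40, 60), 0.0)
    data[10:14, 10:20, 5:15] = 200.0    # 400 µm³
    data[20:28, 25:35, 40:50] = 200.0   # 800 µm³
    vol = IntensityVolume(data, VoxelGeometry((1, 1, 1), data.shape))
    mask = segment_channel(vol, SegmentationParams())
    n = ndimage.label(mask.values, structure=np.ones((3, 3, 3)))[1]
    return {"surviving_components": n,
            "large_cube_retained": bool(mask.values[24, 30, 45]),
            "small_cube_removed": bool(~mask.values[12, 15, 10])}


def validate_pericyte_coverage(seed: int) -> dict:
    """Half / full / empty pericyte sleeves around a straight tube."""
    tube = Tube(line_curve((27, 64, 5), (27, 64, 195)), 3.0)
    out = {}
    for name, (lo, hi) in {"half": (0.0, 0.5), "full": (0.0, 1.0),
                           "empty": (0.0, 0.0)}.items():
        cfg = SceneConfig(shape_zyx=(54, 128, 200), tubes=[tube],
                          sleeves=[Sleeve(0, lo, hi)], rng_seed=seed)
        channels, truth = generate_scene(cfg)
        vmask = segment_channel(channels["endothelium"], PHANTOM_SEG)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty sleeve warns by design
            pmask = segment_pericytes(channels["pericyte"], PHANTOM_SEG)
        axis = thin_to_medial_axis(vmask)
        out[f"coverage_{name}_sleeve"] = pericyte_coverage(axis, pmask)
        out[f"coverage_{name}_true"] = truth.true_pericyte_coverage
    return out


def detection_scene(seed: int, n_cells: int = 20) -> SceneConfig:
    """Planted somata with pairwise separations ≥ 30 µm at soma SNR 10."""
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float, float]] = []
    while len(centers) < n_cells:
        c = rng.uniform([12, 15, 15], [42, 225, 225])
        if all(np.linalg.norm(c - np.array(o)) >= 30 for o in centers):
            centers.append(tuple(c))
    return SceneConfig(shape_zyx=(54, 240, 240), cell_centers_um=centers,
                       rng_seed=seed)


def validate_detection(seed: int) -> dict:
    cfg = detection_scene(seed)
    channels, truth = generate_scene(cfg)
    params = DetectionParams(rng_seed=seed)
    det = detect_somata(channels["microglia"], params)
    det2 = detect_somata(channels["microglia"], params)
    identical = [d.center for d in det] == [d.center for d in det2]
    precision, recall, _ = detection_f1(det, truth.cell_centers_um, match_radius=5.0)
    centers = np.array([d.center for d in det]).reshape(-1, 3)
    if len(centers):
        from scipy.spatial import cKDTree
        loc_err = float(cKDTree(centers).query(truth.cell_centers_um)[0].max())
    else:
        loc_err = float("inf")
    max_overlap = 0.0
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            max_overlap = max(max_overlap, sphere_overlap_fraction(
                np.linalg.norm(centers[i] - centers[j]), params.sphere_radius))
    return {"detection_recall": recall, "detection_precision": precision,
            "max_localisation_error_um": loc_err,
            "seed_repeat_identical": identical,
            "max_surviving_overlap_fraction": max_overlap,
            "n_planted": len(truth.cell_centers_um), "n_detected": len(det)}


def validate_contact_metrics(seed: int) -> dict:
    """Cells at 1..10 µm from a tube wall: the < 5 µm rule gives ratio 4/10."""
    tube = Tube(line_curve((27, 64, 5), (27, 64, 195)), 3.0)
    cells = cells_at_wall_distances(tube, np.arange(1, 11))
    cfg = SceneConfig(shape_zyx=(54, 128, 200), tubes=[tube],
                      cell_centers_um=cells, rng_seed=seed)
    channels, truth = generate_scene(cfg)
    vmask = BinaryVolume(rasterise_tube_mask(cfg), cfg.geometry)
    det = detect_somata(channels["microglia"], DetectionParams(rng_seed=seed))
    inter = vessel_interaction(det, vmask, DetectionParams())
    # exhaustive brute-force minimum per detection
    fg = np.argwhere(vmask.values).astype(float)
    brute_dev = 0.0
    for d, detn in zip(inter.distances, det):
        brute = np.linalg.norm(fg - np.array(detn.center), axis=1).min()
        brute_dev = max(brute_dev, abs(d - brute))
    return {"contact_ratio": inter.contact_ratio,
            "contact_ratio_true": float(truth.cell_contacts.mean()),
            "n_cells": inter.cell_count,
            "max_distance_deviation_from_brute_force_um": brute_dev,
            "mean_distance_um": inter.mean_distance}


def validate_planar_distribution(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 800, size=(200, 2))
    out = planar_distribution(pts, 0.64)
    dev = 0.0
    for i in range(len(pts)):
        d = np.linalg.norm(pts - pts[i], axis=1)
        d[i] = np.inf
        dev = max(dev, abs(out.nnd_per_cell[i] - d.min()))
    pitch = 25.0
    grid = np.array([(y * pitch, x * pitch) for y in range(6) for x in range(6)])
    gout = planar_distribution(grid, (5 * pitch) ** 2 * 1e-6)
    return {"nnd_brute_force_max_deviation_um": dev,
            "grid_mean_nnd_um": gout.mean_nnd, "grid_pitch_um": pitch,
            "spacing_index_identity_residual":
                abs(gout.spacing_index - gout.density_2d * gout.mean_nnd ** 2)}


def validate_group_stats(seed: int, n_null: int = 2000) -> dict:
    rng = np.random.default_rng(seed)

    def table(diet_effect=0.0):
        rows = []
        for diet in ("CD", "mHFD"):
            for sex in ("F", "M"):
                for v in rng.normal(diet_effect * (diet == "mHFD"), 1.0, 6):
                    rows.append({"diet": diet, "sex": sex, "value": v})
        return pd.DataFrame(rows)

    # fixture ANOVA vs from-scratch balanced sums of squares
    fix = pd.DataFrame({
        "diet": ["CD"] * 6 + ["mHFD"] * 6,
        "sex": (["F"] * 3 + ["M"] * 3) * 2,
        "value": [4.1, 3.8, 4.4, 5.0, 5.3, 4.9, 6.2, 5.9, 6.4, 8.1, 7.7, 8.3]})
    res = two_way_anova(fix)
    y = fix["value"].to_numpy()
    cells = {k: g["value"].to_numpy() for k, g in fix.groupby(["diet", "sex"])}
    grand, nc = y.mean(), 3
    ss_a = 2 * nc * sum((g["value"].mean() - grand) ** 2
                        for _, g in fix.groupby("diet"))
    ss_b = 2 * nc * sum((g["value"].mean() - grand) ** 2
                        for _, g in fix.groupby("sex"))
    ss_cells = nc * sum((v.mean() - grand) ** 2 for v in cells.values())
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    mse = ss_err / (len(y) - 4)
    oracle = {"Diet": ss_a / mse, "Sex": ss_b / mse,
              "Diet:Sex": (ss_cells - ss_a - ss_b) / mse}
    f_dev = max(abs(res.effects[k][0] - oracle[k]) for k in oracle)

    rejections = sum(two_way_anova(table()).effects["Diet"][3] < 0.05
                     for _ in range(n_null))
    grubbs_fixture = grubbs_filter([1.0, 1.1, 0.9, 1.05, 8.0])
    false_removals = sum(bool(grubbs_filter(rng.normal(0, 1, 20)).removed)
                         for _ in range(n_null))
    return {"anova_f_max_deviation_from_oracle": f_dev,
            "null_diet_rejection_rate": rejections / n_null,
            "grubbs_fixture_removed": grubbs_fixture.removed,
            "grubbs_false_removal_rate": false_removals / n_null,
            "n_simulations": n_null}


def validate_pipeline_determinism(seed: int, workdir: str | None = None) -> dict:
    """Run the batch pipeline twice with one master seed; compare bytes."""
    from .phantoms import sinusoid_curve

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = workdir if workdir is not None else ctx.name
    try:
        entries = []
        for i in range(4):
            tubes = [Tube(line_curve((27, 30, 5), (27, 30, 91)), 3.0),
                     Tube(sinusoid_curve((27, 65, 5), 86, 5.0 + i, 50), 3.0)]
            cfg = SceneConfig(shape_zyx=(54, 96, 96), tubes=tubes,
                              sleeves=[Sleeve(0, 0.0, 0.5)],
                              cell_centers_um=[(27.0, 15.0, 30.0), (40.0, 80.0, 60.0)],
                              rng_seed=seed + i)
            channels, _ = generate_scene(cfg)
            d = os.path.join(base, f"img{i}")
            os.makedirs(d, exist_ok=True)
            paths = {}
            for name, vol in channels.items():
                p = os.path.join(d, f"{name}.tif")
                write_stack(vol, p)
                paths[name] = p
            entries.append(ImageEntry(
                image_id=f"img{i}", endothelium=paths["endothelium"],
                pericyte=paths["pericyte"], microglia=paths["microglia"],
                region="parietal cortex", animal_id=f"a{i}",
                diet="CD" if i % 2 else "mHFD", sex="F" if i < 2 else "M"))
        digests = []
        for run in ("a", "b"):
            out = os.path.join(base, f"out_{run}")
            config = RunConfig(images=entries, out_dir=out, seed=seed,
                               segmentation=PHANTOM_SEG, run_stats=False)
            result = run_pipeline(config)
            assert not result["failures"], result["failures"]
            digests.append(tuple(
                hashlib.sha256(open(os.path.join(out, f), "rb").read()).hexdigest()
                for f in ("metrics.csv", "cells.csv")))
        return {"runs_byte_identical": digests[0] == digests[1],
                "n_images": len(entries)}
    finally:
        if ctx is not None:
            ctx.cleanup()
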