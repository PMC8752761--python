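"""Microglial soma detection and microglia–vessel interaction metrics.

Somata are detected as peaks of a scale-normalised Laplacian-of-Gaussian
response (σ = 5 µm by default) exceeding a fixed threshold; each peak
defines a sphere of radius 5√3 µm, and overlapping spheres (pairwise
intersection above 0.2 of a sphere volume) are resolved by removing one
member of each offending pair, chosen by a seeded generator so a run is
reproducible.  Interaction metrics: per-cell Euclidean distance to the
nearest vessel-mask voxel centre, the < 5 µm contact rule, mean distance,
contact ratio and 3D density.  The planar branch computes cell density,
nearest-neighbour distance (NND) and the spacing index density × NND² on a
2D field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .geometry import BinaryVolume, IntensityVolume

__all__ = [
    "DetectionParams", "MicrogliaDetection", "InteractionMetrics", "PlanarDistribution",
    "log_response", "detect_somata", "detection_f1", "vessel_interaction",
    "planar_distribution", "sphere_overlap_fraction",
]


@dataclass(frozen=True)
class DetectionParams:
    """Constants of the blob-detection and interaction analysis.

    log_sigma : µm, scale of the Laplacian-of-Gaussian kernel.
    peak_threshold : minimum response at a candidate peak.
    sphere_radius : µm, radius of the sphere representing a soma (5√3 by default).
    max_overlap : maximal tolerated pairwise sphere-overlap fraction.
    contact_distance : µm, a cell closer than this to a vessel is a contact.
    rng_seed : seed of the generator resolving overlap removals.
    """

    log_sigma: float = 5.0
    peak_threshold: float = 15.0
    sphere_radius: float = 5.0 * np.sqrt(3.0)
    max_overlap: float = 0.2
    contact_distance: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.log_sigma <= 0 or self.sphere_radius <= 0 or self.contact_distance <= 0:
            raise ValueError("sigma, sphere radius and contact distance must be > 0")
        if not (0 <= self.max_overlap < 1):
            raise ValueError("max_overlap must lie in [0, 1)")


@dataclass(frozen=True)
class MicrogliaDetection:
    """A detected soma: sphere centre (µm, z/y/x), radius (µm), peak response."""

    center: tuple[float, float, float]
    radius: float
    response: float


@dataclass
class InteractionMetrics:
    """Microglia–vessel interaction readouts for one image."""

    distances: np.ndarray          # µm, one per detection
    contacts: np.ndarray           # bool, distance < contact_distance
    mean_distance: float           # µm (NaN when no detections)
    contact_ratio: float           # fraction (NaN when no detections)
    density_3d: float              # cells per mm³
    cell_count: int


@dataclass
class PlanarDistribution:
    """2D microglial distribution readouts.

    Units follow the source convention: density in cells/mm², NND in µm;
    the spacing index is density_2d × mean_nnd² in those mixed units.
    """

    cell_count: int
    density_2d: float
    mean_nnd: float                # NaN for < 2 cells
    spacing_index: float           # NaN for < 2 cells
    nnd_per_cell: np.ndarray = field(default_factory=lambda: np.zeros(0))


def log_response(volume: IntensityVolume, sigma: float) -> IntensityVolume:
    """Negated, σ²-normalised Laplacian-of-Gaussian response in physical units.

    The Gaussian scale and the Laplacian are both expressed in µm so
    anisotropic voxel spacing is honoured; bright blobs of scale σ produce
    positive local maxima at their centres.
    """
    spacing = volume.geometry.spacing
    if sigma <= spacing.max() / 2:
        raise ValueError(
            f"sigma {sigma} µm must exceed half the largest voxel spacing "
            f"({spacing.max()} µm) for a resolvable kernel")
    sig_vox = sigma / spacing
    values = volume.values.astype(np.float64)
    lap = np.zeros_like(values)
    ones = np.ones_like(values)
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 2
        deriv = ndimage.gaussian_filter(values, sigma=sig_vox, order=order)
        # truncated derivative kernels do not sum exactly to zero; subtract
        # the per-voxel DC leak so a constant image maps to exactly zero
        leak = ndimage.gaussian_filter(ones, sigma=sig_vox, order=order)
        lap += (deriv - values * leak) / spacing[ax] ** 2
    resp = -(sigma ** 2) * lap
    return IntensityVolume(np.maximum(resp, 0.0), volume.geometry, channel=volume.channel)


def sphere_overlap_fraction(distance: float, radius: float) -> float:
    """Intersection volume of two equal spheres over one sphere's volume."""
    d = float(distance)
    if d >= 2 * radius:
        return 0.0
    return min(1.0, ((2 * radius - d) ** 2 * (4 * radius + d)) / (16 * radius ** 3))


def _overlap_critical_distance(radius: float, max_overlap: float) -> float:
    """Centre distance at which the overlap fraction equals max_overlap."""
    if max_overlap <= 0:
        return 2 * radius
    return brentq(lambda d: sphere_overlap_fraction(d, radius) - max_overlap,
                  0.0, 2 * radius)


def detect_somata(volume: IntensityVolume,
                  params: DetectionParams = DetectionParams()) -> list[MicrogliaDetection]:
    """Detect somata as supra-threshold LoG peaks with overlap suppression.

    Candidates are 26-neighbourhood local maxima of the LoG response with
    response strictly above ``peak_threshold``.  Offending sphere pairs
    (overlap fraction > ``max_overlap``) are processed in ascending order
    of centre distance; one member of each still-alive pair is removed,
    chosen uniformly by the seeded generator.  Identical seed and input
    give identical output.
    """
    resp = log_response(volume, params.log_sigma)
    r = resp.values
    maxf = ndimage.maximum_filter(r, size=3, mode="constant", cval=-np.inf)
    peaks = np.argwhere((r >= maxf) & (r > params.peak_threshold)).astype(np.int64)
    if len(peaks) == 0:
        return []
    centers = resp.geometry.physical_coords(peaks)
    responses = r[tuple(peaks.T)]
    # deterministic candidate order: by (z, y, x)
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0]))
    centers, responses = centers[order], responses[order]

    d_crit = _overlap_critical_distance(params.sphere_radius, params.max_overlap)
    tree = cKDTree(centers)
    pairs = tree.query_pairs(r=d_crit * (1 - 1e-12), output_type="ndarray")
    alive = np.ones(len(centers), dtype=bool)
    if len(pairs):
        dists = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
        rng = np.random.default_rng(params.rng_seed)
        for k in np.lexsort((pairs[:, 1], pairs[:, 0], dists)):
            a, b = pairs[k]
            if alive[a] and alive[b]:
                alive[b if rng.integers(2) else a] = False
    return [MicrogliaDetection(tuple(c), params.sphere_radius, float(s))
            for c, s in zip(centers[alive], responses[alive])]


def detection_f1(detections: list[MicrogliaDetection] | np.ndarray,
                 truth_centers: np.ndarray,
                 match_radius: float) -> tuple[float, float, float]:
    """Precision, recall and f1 of detections against ground-truth centres.

    Greedy one-to-one matching by ascending centre distance, restricted to
    pairs closer than ``match_radius`` µm.  Empty truth and empty detections
    count as vacuous perfect agreement (f1 = 1).
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    det = _centers_array(detections)
    truth = np.asarray(truth_centers, dtype=float).reshape(-1, 3)
    if len(det) == 0 and len(truth) == 0:
        return 1.0, 1.0, 1.0
    if len(det) == 0 or len(truth) == 0:
        return 0.0, 0.0, 0.0
    diff = det[:, None, :] - truth[None, :, :]
    dmat = np.linalg.norm(diff, axis=2)
    pairs = np.argwhere(dmat <= match_radius)
    order = np.argsort(dmat[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_d = np.zeros(len(det), dtype=bool)
    used_t = np.zeros(len(truth), dtype=bool)
    matched = 0
    for i, j in pairs[order]:
        if not used_d[i] and not used_t[j]:
            used_d[i] = used_t[j] = True
            matched += 1
    precision = matched / len(det)
    recall = matched / len(truth)
    f1 = 0.0 if matched == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _centers_array(detections) -> np.ndarray:
    if isinstance(detections, np.ndarray):
        return detections.reshape(-1, 3).astype(float)
    return np.array([d.center for d in detections], dtype=float).reshape(-1, 3)


def vessel_interaction(detections: list[MicrogliaDetection],
                       vessel_mask: BinaryVolume,
                       params: DetectionParams = DetectionParams()) -> InteractionMetrics:
    """Distance-to-vessel, contact and density metrics for detected cells.

    Per-cell distance: exact Euclidean distance (µm) from the detection
    centre to the nearest vessel-foreground voxel centre.  Contact: distance
    strictly below ``contact_distance``.  With no detections the mean and
    ratio are reported as NaN (missing), never as 0.
    """
    if not vessel_mask.values.any():
        raise ValueError("vessel mask is empty; interaction metrics undefined")
    vol_mm3 = vessel_mask.geometry.volume_mm3
    centers = _centers_array(detections)
    n = len(centers)
    if n == 0:
        return InteractionMetrics(np.zeros(0), np.zeros(0, dtype=bool),
                                  float("nan"), float("nan"), 0.0, 0)
    fg = np.argwhere(vessel_mask.values)
    tree = cKDTree(vessel_mask.geometry.physical_coords(fg))
    dists, _ = tree.query(centers)
    contacts = dists < params.contact_distance
    return InteractionMetrics(
        distances=dists,
        contacts=contacts,
        mean_distance=float(dists.mean()),
        contact_ratio=float(contacts.mean()),
        density_3d=n / vol_mm3,
        cell_count=n,
    )


def planar_distribution(cell_centers: np.ndarray, field_area_mm2: float) -> PlanarDistribution:
    """Density, nearest-neighbour distance and spacing index on a 2D field.

    ``cell_centers`` are (n, 2) physical coordinates in µm; ``field_area_mm2``
    the imaged area.  NND per cell is the distance to the nearest other
    cell; the spacing index is density_2d × mean_nnd².  With fewer than two
    cells NND and spacing index are reported missing (NaN).
    """
    if field_area_mm2 <= 0:
        raise ValueError("field area must be > 0")
    pts = np.asarray(cell_centers, dtype=float).reshape(-1, 2)
    n = len(pts)
    density = n / field_area_mm2
    if n < 2:
        return PlanarDistribution(n, density, float("nan"), float("nan"))
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    nnd = d[:, 1]
    mean_nnd = float(nnd.mean())
    return PlanarDistribution(n, density, mean_nnd, density * mean_nnd ** 2, nnd)
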