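import numpy as np
import pytest

from neurovasc3d import (
    BinaryVolume,
    DetectionParams,
    SceneConfig,
    Tube,
    VoxelGeometry,
    detect_somata,
    detection_f1,
    generate_scene,
    line_curve,
    log_response,
    planar_distribution,
    vessel_interaction,
)
from neurovasc3d.microglia import MicrogliaDetection, sphere_overlap_fraction
from neurovasc3d.phantoms import cells_at_wall_distances, rasterise_tube_mask

from conftest import volume_from


def gaussian_blob_volume(shape, centers, sigma=5.0, amplitude=150.0, background=0.0):
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    img = np.full(shape, background, dtype=float)
    for c in centers:
        r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        img += amplitude * np.exp(-r2 / (2 * sigma ** 2))
    return volume_from(img, channel="microglia")


def test_log_response_of_constant_is_zero():
    vol = volume_from(np.full((12, 12, 12), 40.0), channel="microglia")
    assert np.allclose(log_response(vol, 5.0).values, 0.0, atol=1e-6)


def test_log_response_peaks_at_matched_blob_center():
    vol = gaussian_blob_volume((40, 40, 40), [(20.0, 20.0, 20.0)])
    resp = log_response(vol, 5.0).values
    peak = np.unravel_index(np.argmax(resp), resp.shape)
    assert np.linalg.norm(np.array(peak) - [20, 20, 20]) <= 1.0 + 1e-9
    # σ²-normalised response at a matched Gaussian blob: 3·A/2^{5/2}
    assert resp[peak] == pytest.approx(3 * 150.0 / 2 ** 2.5, rel=0.02)


def test_log_response_local_maxima_match_brute_force_scan():
    centers = [(15.0, 14.0, 14.0), (15.0, 40.0, 44.0)]
    vol = gaussian_blob_volume((30, 54, 58), centers)
    resp = log_response(vol, 5.0).values
    # brute-force 26-neighbour local-maximum scan above half the blob response
    maxima = []
    thr = resp.max() / 2
    for z in range(1, 29):
        for y in range(1, 53):
            for x in range(1, 57):
                v = resp[z, y, x]
                if v > thr and v >= resp[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2].max():
                    maxima.append((z, y, x))
    assert len(maxima) == 2
    for m, c in zip(sorted(maxima, key=lambda t: t[1]), centers):
        assert np.linalg.norm(np.array(m) - c) <= 1.5


def test_blank_image_yields_no_detections():
    vol = volume_from(np.full((20, 20, 20), 5.0), channel="microglia")
    assert detect_somata(vol, DetectionParams()) == []


def test_detection_recovers_well_separated_planted_blobs():
    rng = np.random.default_rng(0)
    centers = []
    while len(centers) < 8:
        c = rng.uniform([12, 15, 15], [42, 105, 105])
        if all(np.linalg.norm(c - np.array(o)) >= 30 for o in centers):
            centers.append(tuple(c))
    cfg = SceneConfig(shape_zyx=(54, 120, 120), cell_centers_um=centers, rng_seed=3)
    channels, _ = generate_scene(cfg)
    det = detect_somata(channels["microglia"], DetectionParams(rng_seed=5))
    precision, recall, f1 = detection_f1(det, np.array(centers), match_radius=5.0)
    assert (precision, recall, f1) == (1.0, 1.0, 1.0)
    for d in det:
        assert min(np.linalg.norm(np.array(d.center) - c) for c in centers) < 2.0


def test_close_pair_suppression_is_seeded_and_complete():
    """Two candidates 5 µm apart overlap > 0.2 at radius 5√3: exactly one
    survives, and which one depends only on the seed."""
    vol = gaussian_blob_volume((40, 40, 60), [(20.0, 20.0, 26.0), (20.0, 20.0, 31.0)],
                               amplitude=200.0)
    survivors = {}
    for seed in range(6):
        det = detect_somata(vol, DetectionParams(rng_seed=seed))
        assert len(det) == 1
        survivors[seed] = det[0].center
        again = detect_somata(vol, DetectionParams(rng_seed=seed))
        assert [d.center for d in again] == [d.center for d in det]
    assert len(set(survivors.values())) == 2  # both outcomes reachable


def test_no_surviving_pair_overlaps_beyond_limit():
    rng = np.random.default_rng(1)
    centers = [tuple(rng.uniform(14, 76, 3)) for _ in range(25)]
    cfg = SceneConfig(shape_zyx=(90, 90, 90), cell_centers_um=centers,
                      noise_sigma=5.0, rng_seed=2)
    channels, _ = generate_scene(cfg)
    params = DetectionParams(rng_seed=11)
    det = detect_somata(channels["microglia"], params)
    assert det
    pts = np.array([d.center for d in det])
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            frac = sphere_overlap_fraction(np.linalg.norm(pts[i] - pts[j]),
                                           params.sphere_radius)
            assert frac <= params.max_overlap + 1e-12


def test_sphere_overlap_fraction_endpoints():
    assert sphere_overlap_fraction(0.0, 3.0) == pytest.approx(1.0)
    assert sphere_overlap_fraction(6.0, 3.0) == 0.0
    assert sphere_overlap_fraction(7.0, 3.0) == 0.0


@pytest.mark.parametrize("det,truth,expected", [
    # identical sets → perfect
    ([(5, 5, 5), (10, 10, 10)], [(5, 5, 5), (10, 10, 10)], (1.0, 1.0, 1.0)),
    # nothing detected → recall and f1 zero
    ([], [(5, 5, 5)], (0.0, 0.0, 0.0)),
    # vacuous agreement
    ([], [], (1.0, 1.0, 1.0)),
])
def test_detection_f1_basic_cases(det, truth, expected):
    dets = [MicrogliaDetection(tuple(map(float, c)), 8.66, 20.0) for c in det]
    out = detection_f1(dets, np.array(truth, dtype=float).reshape(-1, 3), 3.0)
    assert out == expected


def test_detection_f1_partial_match_harmonic_mean():
    """3 detections vs 4 truths with 2 matchable pairs → P=2/3, R=1/2, f1=4/7."""
    dets = [MicrogliaDetection(c, 8.66, 20.0)
            for c in [(0.0, 0.0, 0.0), (0.0, 0.0, 10.0), (0.0, 0.0, 50.0)]]
    truth = np.array([[0, 0, 1], [0, 0, 11], [0, 0, 30], [0, 0, 90]], dtype=float)
    p, r, f1 = detection_f1(dets, truth, match_radius=3.0)
    assert p == pytest.approx(2 / 3)
    assert r == pytest.approx(1 / 2)
    assert f1 == pytest.approx(4 / 7)


def _tube_mask(shape=(54, 128, 200)):
    nz, ny, nx = shape
    tube = Tube(line_curve((nz / 2, ny / 2, 5), (nz / 2, ny / 2, nx - 5)), 3.0)
    cfg = SceneConfig(shape_zyx=shape, tubes=[tube])
    return tube, cfg, BinaryVolume(rasterise_tube_mask(cfg), cfg.geometry)


def test_interaction_distance_and_contact_rules():
    tube, cfg, mask = _tube_mask()
    on_vessel = MicrogliaDetection((27.0, 64.0, 100.0), 8.66, 20.0)
    near = MicrogliaDetection((27.0, 64.0 + 3.0 + 3.0, 100.0), 8.66, 20.0)   # 3 µm off wall
    far = MicrogliaDetection((27.0, 64.0 + 3.0 + 7.0, 100.0), 8.66, 20.0)    # 7 µm off wall
    inter = vessel_interaction([on_vessel, near, far], mask, DetectionParams())
    assert inter.distances[0] == 0.0
    assert inter.contacts.tolist() == [True, True, False]
    assert inter.contact_ratio == pytest.approx(2 / 3)


def test_interaction_distances_match_exhaustive_minimum():
    rng = np.random.default_rng(3)
    _, cfg, mask = _tube_mask(shape=(40, 60, 80))
    dets = [MicrogliaDetection(tuple(rng.uniform([5, 5, 5], [35, 55, 75])), 8.66, 20.0)
            for _ in range(12)]
    inter = vessel_interaction(dets, mask, DetectionParams())
    fg = np.argwhere(mask.values).astype(float)
    for d, det in zip(inter.distances, dets):
        brute = np.linalg.norm(fg - np.array(det.center), axis=1).min()
        assert d == pytest.approx(brute, abs=1e-6)


def test_interaction_edge_cases():
    _, cfg, mask = _tube_mask(shape=(40, 60, 80))
    empty = vessel_interaction([], mask, DetectionParams())
    assert empty.cell_count == 0
    assert np.isnan(empty.mean_distance) and np.isnan(empty.contact_ratio)
    with pytest.raises(ValueError, match="empty"):
        vessel_interaction([], BinaryVolume(np.zeros((4, 4, 4), bool),
                                            VoxelGeometry((1, 1, 1), (4, 4, 4))),
                           DetectionParams())


def test_contact_ratio_monotone_in_contact_distance():
    tube, cfg, mask = _tube_mask()
    cells = cells_at_wall_distances(tube, np.arange(1, 11))
    dets = [MicrogliaDetection(c, 8.66, 20.0) for c in cells]
    prev = 0.0
    for cd in (1.0, 3.0, 5.0, 8.0, 12.0):
        ratio = vessel_interaction(dets, mask,
                                   DetectionParams(contact_distance=cd)).contact_ratio
        assert ratio >= prev
        prev = ratio


def test_planar_grid_nnd_equals_pitch_and_spacing_identity():
    d = 25.0
    pts = np.array([(y * d, x * d) for y in range(5) for x in range(5)])
    area = (4 * d * 4 * d) * 1e-6  # mm²
    out = planar_distribution(pts, area)
    assert np.allclose(out.nnd_per_cell, d)
    assert out.mean_nnd == pytest.approx(d)
    assert out.spacing_index == pytest.approx(out.density_2d * out.mean_nnd ** 2)


def test_planar_nnd_matches_brute_force():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 500, size=(50, 2))
    out = planar_distribution(pts, 0.25)
    for i in range(50):
        d = np.linalg.norm(pts - pts[i], axis=1)
        d[i] = np.inf
        assert out.nnd_per_cell[i] == d.min()


def test_planar_undersized_input_reports_missing():
    out = planar_distribution(np.array([[1.0, 2.0]]), 0.1)
    assert out.cell_count == 1
    assert np.isnan(out.mean_nnd) and np.isnan(out.spacing_index)
    with pytest.raises(ValueError):
        planar_distribution(np.zeros((3, 2)), 0.0)
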