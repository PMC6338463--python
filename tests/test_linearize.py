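"""Peak detection, spiral fitting and straightening."""

import numpy as np
import pytest

from cochleamap.geometry import REDUCED, generate_geometry
from cochleamap.linearize import (
    LinearizationError,
    PeakSet,
    build_spiral,
    cluster_peaks,
    find_peaks,
    fit_segment,
    resample_linearized,
    stitch_arcs,
)
from cochleamap.phantom import VoxelVolume


def _gauss_volume(centers, shape_zyx=(40, 60, 200), amp=10000, sigma=2.5):
    zz, yy, xx = np.indices(shape_zyx, dtype=np.float32)
    data = np.zeros(shape_zyx, dtype=np.float32)
    for cx, cy, cz in centers:
        data += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
            - (zz - cz) ** 2 / (2 * 3.5**2)
        )
    return VoxelVolume(data.astype(np.uint16), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def test_single_blob_gives_one_peak():
    vol = _gauss_volume([(100, 30, 20)])
    peaks = find_peaks(vol, min_intensity=1000)
    assert len(peaks) == 1
    np.testing.assert_allclose(peaks.points[0], [100, 30, 20], atol=0.5)


def test_two_blobs_20um_apart_give_two_peaks():
    vol = _gauss_volume([(80, 30, 20), (100, 30, 20)])
    peaks = find_peaks(vol, min_intensity=1000)
    assert len(peaks) == 2


def test_chain_at_24um_links_one_cluster():
    pts = np.array([[i * 24.0, 0, 0] for i in range(6)])
    ps = PeakSet(points=pts, intensities=np.ones(6))
    ps = cluster_peaks(ps, max_link_distance=25.0, min_cluster_size=2)
    assert len(np.unique(ps.cluster_id)) == 1


def test_groups_separated_by_30um_split():
    pts = np.vstack(
        [[[i * 5.0, 0, 0] for i in range(5)], [[100 + i * 5.0, 0, 0] for i in range(5)]]
    )
    ps = cluster_peaks(PeakSet(pts, np.ones(10)), max_link_distance=25.0, min_cluster_size=2)
    assert len(np.unique(ps.cluster_id)) == 2


def test_single_linkage_matches_bruteforce_oracle():
    # oracle: union-find over all pairwise distances
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 200, (120, 3))
    ps = cluster_peaks(PeakSet(pts, np.ones(len(pts))), 25.0, min_cluster_size=1)

    parent = list(range(len(pts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.linalg.norm(pts[i] - pts[j]) <= 25.0:
                parent[find(i)] = find(j)
    oracle = np.array([find(i) for i in range(len(pts))])
    # same partition: cluster ids must be a relabeling of oracle roots
    for lab in np.unique(ps.cluster_id):
        members = oracle[ps.cluster_id == lab]
        assert len(np.unique(members)) == 1
    for root in np.unique(oracle):
        members = ps.cluster_id[oracle == root]
        assert len(np.unique(members)) == 1


def test_no_large_cluster_raises():
    pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    with pytest.raises(LinearizationError):
        cluster_peaks(PeakSet(pts, np.ones(2)), 25.0, min_cluster_size=5)


@pytest.fixture(scope="module")
def tilted_circle():
    rng = np.random.default_rng(3)
    th = np.linspace(0.2, 1.1, 60)
    pts = np.stack([300 * np.cos(th), 300 * np.sin(th), np.zeros_like(th)], axis=1)
    c, s = np.cos(0.3), np.sin(0.3)
    R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    return pts @ R.T + np.array([10.0, -20.0, 5.0]), R @ np.array([0, 0, 1.0])


def test_exact_circle_fit_recovers_radius_and_normal(tilted_circle):
    pts, normal = tilted_circle
    seg = fit_segment(pts)
    assert seg.radius == pytest.approx(300.0, abs=0.1)
    ang = np.degrees(np.arccos(abs(seg.plane_normal @ normal)))
    assert ang < 0.1


def _gridsearch_circle_oracle(pts):
    """Brute-force circle fit: grid over center, pick min radial-residual RMS."""
    centroid = pts.mean(axis=0)
    q = pts - centroid
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    u, v = q @ vt[0], q @ vt[1]
    best = None
    for a in np.linspace(-400, 400, 161):
        for b in np.linspace(-400, 400, 161):
            d = np.hypot(u - a, v - b)
            r = d.mean()
            rms = np.sqrt(((d - r) ** 2).mean())
            if best is None or rms < best[0]:
                best = (rms, r)
    return best[1]


def test_noisy_circle_fit_agrees_with_gridsearch_oracle(tilted_circle):
    pts, _ = tilted_circle
    diffs = []
    for seed in range(20):
        noisy = pts + np.random.default_rng(seed).normal(0, 1.0, pts.shape)
        seg = fit_segment(noisy)
        oracle_r = _gridsearch_circle_oracle(noisy)
        diffs.append(abs(seg.radius - oracle_r) / oracle_r)
    assert max(diffs) < 0.02


def test_collinear_points_fall_back_to_line():
    pts = np.stack([np.linspace(0, 100, 8), np.zeros(8), np.zeros(8)], axis=1)
    seg = fit_segment(pts)
    assert seg.is_line and np.isinf(seg.radius)


def test_too_few_or_too_short_segment_rejected():
    with pytest.raises(ValueError):
        fit_segment(np.zeros((4, 3)))
    with pytest.raises(ValueError):
        fit_segment(np.random.default_rng(0).normal(0, 1, (10, 3)))


def test_single_segment_curve_equals_arc(tilted_circle):
    pts, _ = tilted_circle
    seg = fit_segment(pts)
    spiral = stitch_arcs([seg])
    # every original arc sample lies on the stitched curve
    from scipy.spatial import cKDTree

    d, _ = cKDTree(spiral.curve).query(seg.arc_points)
    assert d.max() < 1.0


def test_spiral_length_matches_ground_truth_polyline():
    geom = generate_geometry(REDUCED, seed=4)
    spiral = build_spiral(geom.ihc_positions)
    truth = geom.ihc_polyline_length()
    assert abs(spiral.length - truth) / truth < 0.02


def test_reversed_input_gives_same_curve():
    geom = generate_geometry(REDUCED, seed=5)
    a = build_spiral(geom.ihc_positions)
    b = build_spiral(geom.ihc_positions[::-1])
    # same geometry up to parameter reversal; both orient base -> apex
    assert abs(a.length - b.length) / a.length < 0.01
    np.testing.assert_allclose(a.curve[0], b.curve[0], atol=3.0)


def test_frames_are_orthonormal_and_smooth():
    geom = generate_geometry(REDUCED, seed=6)
    sp = build_spiral(geom.ihc_positions)
    for arr in (sp.tangent, sp.radial, sp.vertical):
        np.testing.assert_allclose(np.linalg.norm(arr, axis=1), 1.0, atol=1e-6)
    # right-handed
    np.testing.assert_allclose(
        np.cross(sp.tangent, sp.radial), sp.vertical, atol=1e-6
    )
    # consecutive frame rotation < 10 degrees
    for arr in (sp.tangent, sp.radial, sp.vertical):
        dots = np.clip(np.einsum("ij,ij->i", arr[:-1], arr[1:]), -1, 1)
        assert np.degrees(np.arccos(dots)).max() < 10.0


def test_straight_row_linearization_is_identity():
    # degenerate "spiral": cells along the x axis; the straightened image
    # must equal an axis-aligned crop up to interpolation error
    centers = [(20 + i * 8.0, 30.0, 20.0) for i in range(23)]
    vol = _gauss_volume(centers)
    band = np.array(centers)
    spiral = build_spiral(band, target_chord=80.0)
    linv = resample_linearized(vol, spiral, r_range=(-10, 10), v_range=(-10, 10))
    # compare along the cell row: intensity at (s of cell, r=0, v=0)
    srv = spiral.linear_from_world(band)
    si = np.round(srv[:, 0] - spiral.s[0]).astype(int)
    vals = linv.data[si, 10, 10]
    direct = vol.data[20, 30, np.round(band[:, 0]).astype(int)]
    np.testing.assert_allclose(vals, direct, rtol=0.02, atol=200)


def test_linearized_roundtrip_mapping_within_one_voxel():
    geom = generate_geometry(REDUCED, seed=7)
    spiral = build_spiral(geom.ihc_positions)
    vol = VoxelVolume(np.zeros((4, 4, 4), dtype=np.uint16))  # mapping needs no data
    linv = resample_linearized(vol, spiral, r_range=(-20, 40), v_range=(-15, 15))
    idx = np.array([[100.0, 25.0, 10.0], [600.0, 50.0, 20.0], [900.0, 5.0, 3.0]])
    world = linv.linear_idx_to_world(idx)
    back = linv.world_to_linear_idx(world)
    assert np.abs(back - idx).max() < 1.0


def test_ihc_band_near_r_zero_after_refit():
    geom = generate_geometry(REDUCED, seed=8)
    spiral = build_spiral(geom.ihc_positions)
    srv = spiral.linear_from_world(geom.ihc_positions)
    assert abs(srv[:, 1].mean()) < 2.0
    srv_ohc = spiral.linear_from_world(geom.ohc_positions)
    assert srv_ohc[:, 1].mean() > 10.0  # OHC rows lie outward (distal)
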