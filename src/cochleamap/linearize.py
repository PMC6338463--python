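"""Spiral fitting and epithelium straightening.

The hair-cell band is found as a chain of local intensity maxima,
divided into 200-300 um segments, and each segment is fitted with a
best-fit plane (principal axes) plus a best-fit arc within that plane.
The stitched arcs form a continuous arc-length-parameterized curve with
orthonormal frames (tangent; in-plane radial, pointing away from the
modiolus; plane normal), and the volume is resampled onto a
straightened (s, r, v) grid at 1 um spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .phantom import VoxelVolume

__all__ = [
    "PeakSet",
    "SegmentFit",
    "SpiralModel",
    "LinearizedVolume",
    "LinearizationError",
    "find_peaks",
    "cluster_peaks",
    "fit_segment",
    "stitch_arcs",
    "build_spiral",
    "resample_linearized",
]


class LinearizationError(RuntimeError):
    pass


@dataclass
class PeakSet:
    """Local intensity maxima with physical coordinates (um)."""

    points: np.ndarray                      # (n, 3) x, y, z um
    intensities: np.ndarray
    cluster_id: np.ndarray | None = None    # filled by cluster_peaks

    def __len__(self) -> int:
        return len(self.points)


def find_peaks(volume: VoxelVolume, min_intensity: float | None = None) -> PeakSet:
    """Regional intensity maxima (26-connectivity) above a threshold.

    ``min_intensity`` defaults to background + 6 robust standard
    deviations (median + 6 * 1.4826 MAD): hair-cell somata occupy only
    ~1% of the volume, so a histogram-split threshold (e.g. Otsu) lands
    inside the background noise, while the robust statistic excludes
    essentially every noise maximum.
    """
    data = volume.data
    if data.size == 0:
        raise ValueError("empty volume")
    if min_intensity is None:
        sample = data[::2, ::4, ::4].astype(np.float64)
        med = np.median(sample)
        mad = np.median(np.abs(sample - med))
        # noise floor guard: on a noise-free volume MAD collapses to 0 and
        # the constant background would count as one huge regional plateau
        floor = max(1.4826 * mad, 1e-3 * (float(sample.max()) - med), 0.5)
        min_intensity = float(med + 6.0 * floor)
    footprint = np.ones((3, 3, 3), dtype=bool)
    maxima = (data == ndimage.maximum_filter(data, footprint=footprint)) & (
        data >= min_intensity
    )
    zz, yy, xx = np.nonzero(maxima)
    idx = np.stack([xx, yy, zz], axis=1).astype(float)
    pts = volume.voxel_to_world(idx)
    return PeakSet(points=pts, intensities=data[zz, yy, xx].astype(float))


def cluster_peaks(
    peaks: PeakSet,
    max_link_distance: float = 25.0,
    min_cluster_size: int = 10,
) -> PeakSet:
    """Single-linkage clustering with a maximal connection distance.

    Two peaks share a cluster iff they are connected by a chain of links
    each at most ``max_link_distance`` um.  Cluster ids are assigned by
    decreasing cluster size (0 = principal band); clusters smaller than
    ``min_cluster_size`` are marked -1 (discarded noise).
    """
    if len(peaks) == 0:
        raise ValueError("no peaks to cluster")
    tree = cKDTree(peaks.points)
    pairs = tree.query_pairs(max_link_distance, output_type="ndarray")
    n = len(peaks)
    if len(pairs):
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        g = coo_matrix((n, n))
    _, labels = connected_components(g, directed=False)
    sizes = np.bincount(labels)
    order = np.argsort(sizes)[::-1]
    remap = -np.ones(len(sizes), dtype=int)
    next_id = 0
    for lab in order:
        if sizes[lab] >= min_cluster_size:
            remap[lab] = next_id
            next_id += 1
    if next_id == 0:
        raise LinearizationError(
            f"no peak cluster of size >= {min_cluster_size}; cannot locate the cell band"
        )
    peaks.cluster_id = remap[labels]
    return peaks


@dataclass
class SegmentFit:
    """Best-fit plane and in-plane arc of one band segment."""

    plane_point: np.ndarray
    plane_normal: np.ndarray
    center: np.ndarray | None       # 3D arc centre; None for the line fallback
    radius: float                   # inf for collinear points
    arc_points: np.ndarray          # ordered samples (~1 um) along the fitted arc
    rms_residual: float
    is_line: bool = False


def fit_segment(points: np.ndarray) -> SegmentFit:
    """Fit a plane (principal axes) and an arc to one segment of band points.

    The plane minimizes orthogonal least squares; the arc minimizes
    in-plane radial residuals (algebraic fit refined by Gauss-Newton).
    Collinear/degenerate input falls back to a line with radius = inf.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 points")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    span = np.linalg.norm(q, axis=1).max() * 2
    if span < 50.0:
        raise ValueError(f"segment spans only {span:.0f} um (< 50)")
    _, sv, vt = np.linalg.svd(q, full_matrices=False)
    e1, e2, normal = vt[0], vt[1], vt[2]
    u = q @ e1
    v = q @ e2
    # algebraic (Kasa) circle fit: u^2+v^2 = 2a u + 2b v + c
    A = np.stack([2 * u, 2 * v, np.ones_like(u)], axis=1)
    rhs = u**2 + v**2
    sol, res, rank, svals = np.linalg.lstsq(A, rhs, rcond=None)
    degenerate = rank < 3 or svals[-1] < 1e-9 * svals[0] or sv[1] < 1e-6 * sv[0]
    if not degenerate:
        a, b, c = sol
        r = np.sqrt(max(c + a**2 + b**2, 0.0))
        # Gauss-Newton refinement of (a, b, r) on radial residuals
        for _ in range(10):
            du, dv = u - a, v - b
            d = np.hypot(du, dv)
            d = np.where(d < 1e-12, 1e-12, d)
            J = np.stack([-du / d, -dv / d, -np.ones_like(d)], axis=1)
            f = d - r
            try:
                step, *_ = np.linalg.lstsq(J, -f, rcond=None)
            except np.linalg.LinAlgError:
                break
            a, b, r = a + step[0], b + step[1], r + step[2]
            if np.linalg.norm(step) < 1e-10:
                break
        curvature_span = np.ptp(np.arctan2(v - b, u - a))
        degenerate = r > 50 * span
    if degenerate:
        order = np.argsort(u)
        t = np.arange(np.floor(u.min()), np.ceil(u.max()) + 1)
        arc = centroid + t[:, None] * e1
        resid = np.abs(v)
        return SegmentFit(centroid, normal, None, np.inf, arc, float(np.sqrt(np.mean(resid**2))), True)
    ang = np.arctan2(v - b, u - a)
    # unwrap angles around their circular mean so the span is contiguous
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    ang_rel = (ang - mean_ang + np.pi) % (2 * np.pi) - np.pi
    a0, a1 = ang_rel.min(), ang_rel.max()
    n_samp = max(int(np.ceil((a1 - a0) * r)), 2)
    th = mean_ang + np.linspace(a0, a1, n_samp)
    arc = centroid + (a + r * np.cos(th))[:, None] * e1 + (b + r * np.sin(th))[:, None] * e2
    center3d = centroid + a * e1 + b * e2
    du, dv = u - a, v - b
    resid = np.hypot(du, dv) - r
    return SegmentFit(centroid, normal, center3d, float(r), arc, float(np.sqrt(np.mean(resid**2))), False)


@dataclass
class SpiralModel:
    """Continuous arc-length-parameterized curve of the hair-cell band."""

    curve: np.ndarray       # (n, 3) samples at ~1 um spacing
    s: np.ndarray           # (n,) arc length, 0 at the basal end
    tangent: np.ndarray     # (n, 3) unit, d(curve)/ds
    radial: np.ndarray      # (n, 3) unit, in-plane, away from the modiolus
    vertical: np.ndarray    # (n, 3) unit plane normal; (t, r, v) right-handed
    segments: list[SegmentFit] = field(default_factory=list)
    end_extension: int = 0  # um of tangential extrapolation at each end
    _tree: cKDTree | None = field(default=None, repr=False)

    @property
    def length(self) -> float:
        """Arc length of the fitted band (excluding the end extrapolation)."""
        return float(self.s[-1] - self.s[0]) - 2.0 * self.end_extension

    def world_from_linear(self, s, r, v) -> np.ndarray:
        """(s, r, v) um -> world coordinates (interpolated along the curve)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = np.clip(np.searchsorted(self.s, s), 1, len(self.s) - 1)
        f = (s - self.s[idx - 1]) / np.maximum(self.s[idx] - self.s[idx - 1], 1e-12)
        f = np.clip(f, 0.0, 1.0)[:, None]
        c = self.curve[idx - 1] * (1 - f) + self.curve[idx] * f
        rv = self.radial[idx - 1] * (1 - f) + self.radial[idx] * f
        vv = self.vertical[idx - 1] * (1 - f) + self.vertical[idx] * f
        rv /= np.linalg.norm(rv, axis=1, keepdims=True)
        vv /= np.linalg.norm(vv, axis=1, keepdims=True)
        return c + np.atleast_1d(r)[:, None] * rv + np.atleast_1d(v)[:, None] * vv

    def linear_from_world(self, points: np.ndarray) -> np.ndarray:
        """World points -> (s, r, v) by projection onto the curve."""
        pts = np.atleast_2d(points)
        if self._tree is None:
            self._tree = cKDTree(self.curve)
        _, idx = self._tree.query(pts)
        d = pts - self.curve[idx]
        s = self.s[idx] + np.einsum("ij,ij->i", d, self.tangent[idx])
        r = np.einsum("ij,ij->i", d, self.radial[idx])
        v = np.einsum("ij,ij->i", d, self.vertical[idx])
        return np.stack([s, r, v], axis=1)


def _order_band(
    points: np.ndarray, max_link: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Order band points along the ribbon by graph-geodesic distance.

    Builds the link graph (edges <= max_link) on the largest connected
    component (isolated outliers are dropped), finds an approximate
    diameter endpoint pair by double sweep, and returns (geodesic
    distance from the chosen end, membership mask).
    """
    tree = cKDTree(points)
    pairs = tree.query_pairs(max_link, output_type="ndarray")
    n = len(points)
    w = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
    g = coo_matrix((w, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, comp = connected_components(g, directed=False)
    main = np.bincount(comp).argmax()
    mask = comp == main
    if mask.sum() < max(10, 0.5 * n):
        raise LinearizationError(
            f"band point graph is fragmented (largest component {mask.sum()}/{n})"
        )
    start = int(np.flatnonzero(mask)[0])
    d0 = dijkstra(g, directed=False, indices=start)
    a = int(np.nanargmax(np.where(mask, d0, -np.inf)))
    da = dijkstra(g, directed=False, indices=a)
    return da[mask], mask


def stitch_arcs(segments: list[SegmentFit], join_tolerance: float = 5.0) -> SpiralModel:
    """Stitch per-segment arcs into one continuous framed curve.

    Segments must be ordered along the band; each arc's sample order is
    flipped if needed so that endpoints chain head-to-tail.  Joins are
    smoothed with a short moving average, the curve is re-parameterized
    by arc length, and frames are built from the smoothed tangents and
    (sign-aligned, interpolated) segment plane normals.
    """
    if not segments:
        raise ValueError("no segments")
    arcs = [seg.arc_points.copy() for seg in segments]
    normals = [seg.plane_normal.copy() for seg in segments]
    for i in range(1, len(arcs)):
        prev_end = arcs[i - 1][-1]
        if np.linalg.norm(arcs[i][0] - prev_end) > np.linalg.norm(arcs[i][-1] - prev_end):
            arcs[i] = arcs[i][::-1]
    if len(arcs) > 1:
        gaps = [float(np.linalg.norm(arcs[i][0] - arcs[i - 1][-1])) for i in range(1, len(arcs))]
        if max(gaps) > 10 * join_tolerance:
            raise LinearizationError(f"segment order ambiguous: join gap {max(gaps):.0f} um")
    # orient the first arc consistently with the second
    if len(arcs) > 1 and np.linalg.norm(arcs[0][-1] - arcs[1][0]) > np.linalg.norm(
        arcs[0][0] - arcs[1][0]
    ):
        arcs[0] = arcs[0][::-1]
    per_point_normals = []
    ref = normals[0]
    for i, (arc, nrm) in enumerate(zip(arcs, normals)):
        if np.dot(nrm, ref) < 0:
            nrm = -nrm
        normals[i] = nrm
        ref = nrm
        per_point_normals.append(np.tile(nrm, (len(arc), 1)))
    curve = np.vstack(arcs)
    nrms = np.vstack(per_point_normals)
    win = min(31, max(3, len(curve) // 4 * 2 + 1))
    curve_s = np.stack(
        [ndimage.uniform_filter1d(curve[:, k], win, mode="nearest") for k in range(3)], axis=1
    )
    nrms = np.stack(
        [ndimage.uniform_filter1d(nrms[:, k], win, mode="nearest") for k in range(3)], axis=1
    )
    nrms /= np.linalg.norm(nrms, axis=1, keepdims=True)
    # re-parameterize by arc length at 1 um
    seg_len = np.linalg.norm(np.diff(curve_s, axis=0), axis=1)
    s_raw = np.concatenate([[0.0], np.cumsum(seg_len)])
    keep = np.concatenate([[True], seg_len > 1e-9])
    curve_s, nrms, s_raw = curve_s[keep], nrms[keep], s_raw[keep]
    s_grid = np.arange(0.0, s_raw[-1] + 0.5, 1.0)
    curve_g = np.stack([np.interp(s_grid, s_raw, curve_s[:, k]) for k in range(3)], axis=1)
    nrm_g = np.stack([np.interp(s_grid, s_raw, nrms[:, k]) for k in range(3)], axis=1)
    nrm_g /= np.linalg.norm(nrm_g, axis=1, keepdims=True)
    # extrapolate tangentially at both ends so cells at the very ends of
    # the band are not cut off the straightened grid
    ext = 15
    t0 = curve_g[1] - curve_g[0]
    t1 = curve_g[-1] - curve_g[-2]
    t0 /= np.linalg.norm(t0)
    t1 /= np.linalg.norm(t1)
    pre = curve_g[0] + np.arange(-ext, 0)[:, None] * t0
    post = curve_g[-1] + np.arange(1, ext + 1)[:, None] * t1
    curve_g = np.vstack([pre, curve_g, post])
    nrm_g = np.vstack([np.tile(nrm_g[0], (ext, 1)), nrm_g, np.tile(nrm_g[-1], (ext, 1))])
    s_grid = np.arange(len(curve_g), dtype=float)
    tang = np.gradient(curve_g, s_grid, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    radial = np.cross(nrm_g, tang)
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    vert = np.cross(tang, radial)
    return SpiralModel(
        curve=curve_g, s=s_grid, tangent=tang, radial=radial, vertical=vert,
        segments=segments, end_extension=ext,
    )


def build_spiral(band_points: np.ndarray, target_chord: float = 250.0) -> SpiralModel:
    """Fit the full spiral model from band points (peaks or cells).

    Points are ordered by graph geodesic, divided into ~``target_chord``
    um segments (the 200-300 um range midpoint), fitted and stitched.
    The radial axis is oriented away from the arc centres (i.e. away
    from the modiolus), and s = 0 is placed at the end with the larger
    fitted arc radius (cochlear base).
    """
    pts = np.asarray(band_points, dtype=float)
    dist, mask = _order_band(pts)
    pts = pts[mask]
    order = np.argsort(dist)
    pts_o = pts[order]
    d_o = dist[order]
    total = d_o[-1]
    n_seg = max(1, int(round(total / target_chord)))
    edges = np.linspace(0.0, total, n_seg + 1)
    segments = []
    for i in range(n_seg):
        m = (d_o >= edges[i]) & (d_o <= edges[i + 1])
        if m.sum() < 5:
            continue
        segments.append(fit_segment(pts_o[m]))
    if not segments:
        raise LinearizationError("no fittable segments")
    spiral = stitch_arcs(segments)
    # orient s base -> apex: base has the larger arc radius
    radii = [seg.radius for seg in spiral.segments if np.isfinite(seg.radius)]
    if len(radii) >= 2 and radii[0] < radii[-1]:
        spiral = SpiralModel(
            curve=spiral.curve[::-1].copy(),
            s=(spiral.s[-1] - spiral.s[::-1]).copy(),
            tangent=-spiral.tangent[::-1].copy(),
            radial=spiral.radial[::-1].copy(),
            vertical=-spiral.vertical[::-1].copy(),
            segments=spiral.segments[::-1],
            end_extension=spiral.end_extension,
        )
    # orient r outward: the radial axis must point away from the arc centres
    votes = []
    for seg in spiral.segments:
        if seg.center is None or not np.isfinite(seg.radius):
            continue
        i = int(np.argmin(np.linalg.norm(spiral.curve - seg.plane_point, axis=1)))
        votes.append(np.dot(spiral.radial[i], spiral.curve[i] - seg.center))
    if votes and np.mean(votes) < 0:
        spiral.radial = -spiral.radial
        spiral.vertical = -spiral.vertical
        spiral._tree = None
    return spiral


@dataclass
class LinearizedVolume:
    """Straightened voxel image with axes (s, r, v) at 1 um spacing.

    ``data[si, ri, vi]`` samples the source volume at
    ``curve(s0 + si) + (r0 + ri) * radial + (v0 + vi) * vertical``; the
    mapping is invertible through the stored spiral model.
    """

    data: np.ndarray
    spiral: SpiralModel
    r_range: tuple[float, float]
    v_range: tuple[float, float]
    oob_mask: np.ndarray | None = None       # True where sampling left the source

    def linear_idx_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.spiral.world_from_linear(
            idx[:, 0], idx[:, 1] + self.r_range[0], idx[:, 2] + self.v_range[0]
        )

    def world_to_linear_idx(self, points: np.ndarray) -> np.ndarray:
        srv = self.spiral.linear_from_world(points)
        return srv - np.array([0.0, self.r_range[0], self.v_range[0]])


def resample_linearized(
    volume: VoxelVolume,
    spiral: SpiralModel,
    r_range: tuple[float, float] = (-40.0, 60.0),
    v_range: tuple[float, float] = (-30.0, 30.0),
) -> LinearizedVolume:
    """Trilinear resampling of the volume onto the straightened grid.

    Samples outside the source bounds are zero-filled and flagged in the
    out-of-bounds mask.
    """
    ns = len(spiral.s)
    r_axis = np.arange(r_range[0], r_range[1] + 0.5, 1.0)
    v_axis = np.arange(v_range[0], v_range[1] + 0.5, 1.0)
    nr, nv = len(r_axis), len(v_axis)
    # world coords of every output voxel: c(s) + r*e_r + v*e_v
    world = (
        spiral.curve.astype(np.float32)[:, None, None, :]
        + r_axis.astype(np.float32)[None, :, None, None]
        * spiral.radial.astype(np.float32)[:, None, None, :]
        + v_axis.astype(np.float32)[None, None, :, None]
        * spiral.vertical.astype(np.float32)[:, None, None, :]
    )
    vs = np.asarray(volume.voxel_size, dtype=np.float32)
    org = np.asarray(volume.origin, dtype=np.float32)
    idx = (world - org) / vs  # (ns, nr, nv, 3) in (x, y, z)
    del world
    coords = np.stack([idx[..., 2], idx[..., 1], idx[..., 0]])  # (z, y, x) for map_coordinates
    del idx
    out = ndimage.map_coordinates(
        volume.data.astype(np.float32), coords.reshape(3, -1), order=1, mode="constant", cval=0.0
    ).reshape(ns, nr, nv)
    shp = np.array(volume.data.shape)  # (z, y, x)
    oob = (
        (coords[0] < 0) | (coords[0] > shp[0] - 1)
        | (coords[1] < 0) | (coords[1] > shp[1] - 1)
        | (coords[2] < 0) | (coords[2] > shp[2] - 1)
    )
    return LinearizedVolume(out, spiral, tuple(r_range), tuple(v_range), oob)
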