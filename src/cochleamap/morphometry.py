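"""Three-dimensional structural summaries of the cochlea.

The IHC row is the structural reference: its total length and cell
count summarize longitudinal size; distances of IHCs from the modiolar
axis give the radial profile; and projections onto the axis, averaged
over consecutive 25-cell blocks, give the axial (pitch) profile.  The
modiolar axis itself is estimated as the direction that makes the
turn-wise circle centres of the projected spiral coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ModiolarAxis",
    "MorphometrySummary",
    "estimate_modiolar_axis",
    "radial_profile",
    "axial_profile",
    "summarize",
]


@dataclass
class ModiolarAxis:
    point: np.ndarray       # a point on the axis
    direction: np.ndarray   # unit vector
    low_confidence: bool = False


def _chunk_centers_var(points: np.ndarray, direction: np.ndarray, n_chunks: int) -> tuple:
    """Variance of per-chunk circle centres in the plane normal to ``direction``."""
    d = direction / np.linalg.norm(direction)
    # in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    u = points @ e1
    v = points @ e2
    # chunks of consecutive cells along the row
    edges = np.linspace(0, len(points), n_chunks + 1).astype(int)
    centers = []
    for i in range(n_chunks):
        uu, vv = u[edges[i]:edges[i + 1]], v[edges[i]:edges[i + 1]]
        if len(uu) < 5:
            continue
        A = np.stack([2 * uu, 2 * vv, np.ones_like(uu)], axis=1)
        rhs = uu**2 + vv**2
        try:
            (ca, cb, _), *_ = np.linalg.lstsq(A, rhs, rcond=None)
        except np.linalg.LinAlgError:
            continue
        centers.append((ca, cb))
    centers = np.asarray(centers)
    if len(centers) < 2:
        return np.inf, centers, (e1, e2)
    return float(centers.var(axis=0).sum()), centers, (e1, e2)


def estimate_modiolar_axis(ihc_positions: np.ndarray, n_chunks: int = 4) -> ModiolarAxis:
    """Helix-axis fit: minimize the scatter of turn-wise circle centres.

    IHC positions must be ordered along the row.  A coarse direction
    grid is refined by Nelder-Mead on spherical angles.  Fewer than 50
    cells or less than about one turn of spiral gives a low-confidence
    flag (and a warning).
    """
    pts = np.asarray(ihc_positions, dtype=float)
    centroid = pts.mean(axis=0)
    q = pts - centroid

    def objective(angles):
        th, ph = angles
        d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        return _chunk_centers_var(q, d, n_chunks)[0]

    best = None
    for th in np.linspace(0, np.pi, 8):
        for ph in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            val = objective((th, ph))
            if best is None or val < best[0]:
                best = (val, (th, ph))
    res = minimize(objective, best[1], method="Nelder-Mead", options={"xatol": 1e-4})
    th, ph = res.x
    d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    if d[2] < 0:
        d = -d
    _, centers, (e1, e2) = _chunk_centers_var(q, d, n_chunks)
    center_world = centroid + centers.mean(axis=0) @ np.stack([e1, e2])
    # angular span around the fitted axis
    u = q @ e1
    v = q @ e2
    ang = np.unwrap(np.arctan2(v - centers.mean(axis=0)[1], u - centers.mean(axis=0)[0]))
    span_turns = abs(ang[-1] - ang[0]) / (2 * np.pi)
    low = len(pts) < 50 or span_turns < 1.0
    if low:
        warnings.warn(
            f"modiolar-axis fit on {len(pts)} cells spanning {span_turns:.2f} turns; "
            "low confidence"
        )
    # place the axis point at the cells' centroid height along the axis
    axis_point = center_world + ((centroid - center_world) @ d) * d
    return ModiolarAxis(point=axis_point, direction=d, low_confidence=low)


def radial_profile(ihc_positions: np.ndarray, axis: ModiolarAxis) -> np.ndarray:
    """Distance of every IHC from the modiolar axis, in input (base ->
    apex) order."""
    q = np.asarray(ihc_positions, dtype=float) - axis.point
    proj = np.outer(q @ axis.direction, axis.direction)
    return np.linalg.norm(q - proj, axis=1)


def axial_profile(
    ihc_positions: np.ndarray, axis: ModiolarAxis, block: int = 25
) -> np.ndarray:
    """Relative axial position of every consecutive ``block`` IHCs.

    Projections onto the axis are averaged per complete block (an
    incomplete final block is dropped) and min-max normalized to [0, 1].
    """
    pts = np.asarray(ihc_positions, dtype=float)
    n_blocks = len(pts) // block
    if n_blocks < 2:
        raise ValueError("need at least 2 complete blocks")
    h = (pts - axis.point) @ axis.direction
    means = np.array([h[i * block:(i + 1) * block].mean() for i in range(n_blocks)])
    lo, hi = means.min(), means.max()
    return (means - lo) / max(hi - lo, 1e-12)


@dataclass
class MorphometrySummary:
    total_longitudinal_length: float
    ihc_count: int
    radial_distances: np.ndarray
    axial_blocks: np.ndarray
    axis: ModiolarAxis


def summarize(
    ihc_positions: np.ndarray, spiral_length: float, block: int = 25
) -> MorphometrySummary:
    axis = estimate_modiolar_axis(ihc_positions)
    return MorphometrySummary(
        total_longitudinal_length=float(spiral_length),
        ihc_count=len(ihc_positions),
        radial_distances=radial_profile(ihc_positions, axis),
        axial_blocks=axial_profile(ihc_positions, axis, block),
        axis=axis,
    )
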