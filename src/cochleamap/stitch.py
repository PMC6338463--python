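"""Tile registration and fusion.

Overlapping stacks are registered pairwise by exhaustive normalized
cross-correlation over a translational search window, pairwise shifts
are reconciled globally by linear least squares over the adjacency
graph, and tiles are fused with linear distance-ramp blending so that
blending weights sum to one at every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .phantom import VoxelVolume

__all__ = ["RegistrationError", "StitchError", "TileLayout", "register_pair", "stitch"]


class RegistrationError(RuntimeError):
    pass


class StitchError(RuntimeError):
    pass


@dataclass
class TileLayout:
    """Tiles plus nominal and (after refinement) registered offsets (um)."""

    tiles: list[VoxelVolume]
    nominal_offsets: np.ndarray                  # (n, 3) um, (x, y, z)
    refined_offsets: np.ndarray | None = None
    pair_scores: dict = field(default_factory=dict)

    @classmethod
    def from_tiles(cls, tiles: list[VoxelVolume]) -> "TileLayout":
        return cls(tiles=tiles, nominal_offsets=np.array([t.origin for t in tiles]))


def register_pair(
    tile_a: VoxelVolume,
    tile_b: VoxelVolume,
    nominal_offset: np.ndarray,
    search_radius: float | None = None,
) -> tuple[np.ndarray, float]:
    """Refine the offset of ``tile_b`` relative to ``tile_a``.

    ``nominal_offset`` is b's origin minus a's origin in um.  The offset
    maximizing normalized cross-correlation over the overlap is searched
    exhaustively within ``search_radius`` um of nominal (default 20% of
    the tile extent).  Returns (refined_offset_um, ncc_score).
    """
    vs = np.asarray(tile_a.voxel_size)
    a = tile_a.data.astype(np.float32)
    b = tile_b.data.astype(np.float32)
    shape_a = np.array(a.shape[::-1])  # (x, y, z)
    shape_b = np.array(b.shape[::-1])
    if search_radius is None:
        search_radius = 0.2 * float(np.max(shape_a * vs))
    rel = np.round(np.asarray(nominal_offset, dtype=float) / vs).astype(int)
    srch = np.maximum(np.round(search_radius / vs).astype(int), 1)

    a_lo = np.maximum(0, rel)
    a_hi = np.minimum(shape_a, rel + shape_b)
    if np.any(a_hi - a_lo < 3):
        raise RegistrationError(
            f"no usable overlap at nominal offset {nominal_offset} (extent {a_hi - a_lo})"
        )
    # template: interior of b's overlap part, leaving room for the search
    b_lo = a_lo - rel
    b_hi = a_hi - rel
    shrink = np.minimum(srch, ((b_hi - b_lo) // 3))
    bt_lo = b_lo + shrink
    bt_hi = b_hi - shrink
    if np.any(bt_hi - bt_lo < 2):
        raise RegistrationError("overlap too small for the requested search radius")
    # crop the template to a compact high-signal chunk: the NCC peak is
    # determined by local structure, and small templates keep the FFTs cheap
    max_templ = np.array([32, 64, 32])  # (x, y, z) voxels
    if np.any(bt_hi - bt_lo > max_templ):
        region = b[bt_lo[2]:bt_hi[2], bt_lo[1]:bt_hi[1], bt_lo[0]:bt_hi[0]]
        peak = np.array(np.unravel_index(np.argmax(region), region.shape))[::-1]
        half = np.minimum(max_templ, bt_hi - bt_lo) // 2
        center = np.clip(bt_lo + peak, bt_lo + half, bt_hi - half)
        bt_lo = center - half
        bt_hi = np.minimum(center + half, bt_hi)
    templ = b[bt_lo[2]:bt_hi[2], bt_lo[1]:bt_hi[1], bt_lo[0]:bt_hi[0]]
    if templ.std() == 0:
        raise RegistrationError("flat overlap region; cannot register")
    as_lo = np.maximum(0, rel + bt_lo - srch)
    as_hi = np.minimum(shape_a, rel + bt_hi + srch)
    search_img = a[as_lo[2]:as_hi[2], as_lo[1]:as_hi[1], as_lo[0]:as_hi[0]]
    ncc = match_template(search_img, templ)
    pos = np.array(np.unravel_index(np.argmax(ncc), ncc.shape))[::-1]  # (x, y, z)
    score = float(ncc.max())
    refined_rel = as_lo + pos - bt_lo
    # clamp to the declared search radius around nominal
    refined_rel = np.clip(refined_rel, rel - srch, rel + srch)
    return refined_rel * vs, score


def _adjacent_pairs(layout: TileLayout) -> list[tuple[int, int]]:
    """Pairs of tiles whose nominal bounding boxes overlap."""
    n = len(layout.tiles)
    pairs = []
    exts = [np.array(t.shape_xyz) * np.asarray(t.voxel_size) for t in layout.tiles]
    for i in range(n):
        for j in range(i + 1, n):
            lo = np.maximum(layout.nominal_offsets[i], layout.nominal_offsets[j])
            hi = np.minimum(
                layout.nominal_offsets[i] + exts[i], layout.nominal_offsets[j] + exts[j]
            )
            if np.all(hi - lo > 3):
                # skip corner-only overlaps: they add little constraint and
                # the edge pairs already connect the graph
                xy_frac = (hi[0] - lo[0]) * (hi[1] - lo[1]) / (exts[i][0] * exts[i][1])
                if xy_frac >= 0.10:
                    pairs.append((i, j))
    return pairs


def refine_layout(
    layout: TileLayout,
    search_radius: float | None = None,
    min_score: float = 0.2,
) -> TileLayout:
    """Register every adjacent pair and reconcile offsets globally.

    Pairwise shifts are combined by least squares over the adjacency
    graph (tile 0 anchored at its nominal offset); pairs scoring below
    ``min_score`` are dropped, and an unregistrable (disconnected) graph
    raises :class:`RegistrationError`.
    """
    pairs = _adjacent_pairs(layout)
    n = len(layout.tiles)
    if n == 1:
        layout.refined_offsets = layout.nominal_offsets.copy()
        return layout
    rows, rhs = [], []
    for i, j in pairs:
        nominal = layout.nominal_offsets[j] - layout.nominal_offsets[i]
        try:
            d, score = register_pair(
                layout.tiles[i], layout.tiles[j], nominal, search_radius
            )
        except RegistrationError:
            continue
        layout.pair_scores[(i, j)] = score
        if score < min_score:
            continue
        row = np.zeros(n)
        row[i], row[j] = -1.0, 1.0
        rows.append(row)
        rhs.append(d)
    # anchor tile 0
    anchor = np.zeros(n)
    anchor[0] = 1.0
    rows.append(anchor)
    rhs.append(layout.nominal_offsets[0])
    A = np.asarray(rows)
    if np.linalg.matrix_rank(A) < n:
        raise RegistrationError("tile adjacency graph is disconnected; cannot reconcile")
    sol, *_ = np.linalg.lstsq(A, np.asarray(rhs), rcond=None)
    layout.refined_offsets = sol
    return layout


def _ramp(n: int) -> np.ndarray:
    return np.minimum(np.arange(1, n + 1), np.arange(n, 0, -1)).astype(np.float32)


def stitch(layout: TileLayout) -> VoxelVolume:
    """Fuse registered tiles into a single volume.

    Within overlaps, intensity is a convex combination of contributing
    tiles with linear distance-ramp weights (each tile's weight rises
    linearly from its x/y borders); elsewhere it equals the sole
    contributing tile.
    """
    if layout.refined_offsets is None:
        layout = refine_layout(layout)
    offs = layout.refined_offsets
    vs = np.asarray(layout.tiles[0].voxel_size)
    lo = offs.min(axis=0)
    idx = [np.round((o - lo) / vs).astype(int) for o in offs]
    shapes = [np.array(t.shape_xyz) for t in layout.tiles]
    hi_idx = np.max([i + s for i, s in zip(idx, shapes)], axis=0)
    nx, ny, nz = hi_idx
    acc = np.zeros((nz, ny, nx), dtype=np.float32)
    wacc = np.zeros((nz, ny, nx), dtype=np.float32)
    for t, i0 in zip(layout.tiles, idx):
        tx, ty, tz = t.shape_xyz
        w = _ramp(ty)[:, None] * _ramp(tx)[None, :]
        sl = (
            slice(i0[2], i0[2] + tz),
            slice(i0[1], i0[1] + ty),
            slice(i0[0], i0[0] + tx),
        )
        acc[sl] += t.data.astype(np.float32) * w[None, :, :]
        wacc[sl] += w[None, :, :]
    out = np.zeros_like(acc)
    nz_mask = wacc > 0
    out[nz_mask] = acc[nz_mask] / wacc[nz_mask]
    dtype = layout.tiles[0].data.dtype
    if np.issubdtype(dtype, np.integer):
        out = np.round(out).astype(dtype)
    else:
        out = out.astype(dtype)
    return VoxelVolume(out, tuple(vs), tuple(lo))
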