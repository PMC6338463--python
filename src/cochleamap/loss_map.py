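"""Void-space detection and lost-cell estimation on the normalized grid.

Detected cells are transformed to a standardized template: coordinates
are locally rescaled so the mean intercellular distance is one unit
along (u) and across (w) the epithelium.  Unit squares placed on every
detected OHC then leave connected empty pixel groups — void spaces —
wherever cells are missing; dividing each void's area by the area of a
single cell estimates the number of lost cells.  Longitudinal (50 um),
radial (per-row) and 13 x 15 segment loss profiles summarize the
spatial pattern, and a centered SVD across samples gives the principal
components of loss frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "StandardGrid",
    "VoidSpace",
    "normalize_coordinates",
    "find_void_spaces",
    "estimate_lost_cells",
    "loss_profiles",
    "pca_loss_frequency",
]

RASTER_RES = 10           # pixels per normalized unit
BAND_W = (0.5, 3.5)       # OHC band extent in w (rows at w = 1, 2, 3)


@dataclass
class StandardGrid:
    """Cells in normalized template coordinates (unit mean spacing)."""

    cells: pd.DataFrame           # columns: kind, row, u, w, s
    s_knots: np.ndarray           # monotone mapping between s (um) and u
    u_knots: np.ndarray
    mean_spacing_um: float        # mean within-row OHC spacing before scaling

    def u_to_s(self, u: np.ndarray) -> np.ndarray:
        return np.interp(u, self.u_knots, self.s_knots)

    def s_to_u(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.s_knots, self.u_knots)


@dataclass
class VoidSpace:
    """A connected cell-free pixel group in the occupancy raster."""

    area_px: int
    area_units: float
    centroid_u: float
    centroid_w: float
    est_lost: int
    pixels: np.ndarray = field(repr=False)   # (n, 2) raster indices (wi, ui)


def normalize_coordinates(cells: pd.DataFrame, window_um: float = 60.0) -> StandardGrid:
    """Rescale cell coordinates to the standardized template.

    ``u`` integrates 1 / (local median within-row OHC spacing) along s,
    so one unit equals one intercellular distance everywhere along the
    organ; ``w`` places the three OHC rows at 1, 2, 3 (and IHCs at 0) by
    a linear map of the radial coordinate per row band.  The mapping is
    monotone in s (order preserving).
    """
    if len(cells) < 10:
        raise ValueError("need at least 10 detected cells to normalize")
    ohc = cells[cells.kind == "OHC"]
    if ohc.row.nunique() < 3:
        raise ValueError("need OHCs in all three rows")
    # local spacing estimate from same-row consecutive pairs
    mids, gaps = [], []
    for row in (1, 2, 3):
        s_row = np.sort(ohc[ohc.row == row].s.to_numpy())
        d = np.diff(s_row)
        ok = d < 3.0 * np.median(d)  # exclude gaps from lost cells
        mids.append((s_row[:-1] + s_row[1:])[ok] / 2)
        gaps.append(d[ok])
    mids = np.concatenate(mids)
    gaps = np.concatenate(gaps)
    order = np.argsort(mids)
    mids, gaps = mids[order], gaps[order]
    s_lo, s_hi = cells.s.min() - 5, cells.s.max() + 5
    knots = np.arange(s_lo, s_hi + 1, 10.0)
    local = np.empty(len(knots))
    for i, k in enumerate(knots):
        m = np.abs(mids - k) <= window_um
        local[i] = np.median(gaps[m]) if m.any() else np.nan
    if np.isnan(local).any():
        valid = ~np.isnan(local)
        local = np.interp(knots, knots[valid], local[valid])
    # u(s) = integral ds / spacing(s)
    du = 10.0 / local
    u_knots = np.concatenate([[0.0], np.cumsum(0.5 * (du[:-1] + du[1:]))])
    grid = StandardGrid(
        cells=pd.DataFrame(), s_knots=knots, u_knots=u_knots,
        mean_spacing_um=float(np.mean(gaps)),
    )
    out = cells.copy()
    out["u"] = grid.s_to_u(out.s.to_numpy())
    # w: per-row linear map of r so row centers sit at 1, 2, 3
    row_r = ohc.groupby("row").r.mean()
    coef = np.polyfit(row_r.loc[[1, 2, 3]].to_numpy(), [1.0, 2.0, 3.0], 1)
    out["w"] = np.where(
        out.kind == "OHC", np.polyval(coef, out.r.to_numpy()), 0.0
    )
    grid.cells = out[["kind", "row", "u", "w", "s"]].reset_index(drop=True)
    return grid


def find_void_spaces(
    grid: StandardGrid,
    square_size: float = 1.0,
    resolution: int = RASTER_RES,
    min_area_units: float = 0.5,
) -> list[VoidSpace]:
    """Rasterize occupancy of the OHC band and label empty regions.

    A ``square_size`` x ``square_size`` unit square is placed on every
    detected OHC; remaining in-band pixels form 8-connected voids;
    voids smaller than ``min_area_units`` cell areas are discarded.
    """
    ohc = grid.cells[grid.cells.kind == "OHC"]
    u = ohc.u.to_numpy()
    w = ohc.w.to_numpy()
    u_lo, u_hi = u.min() - 0.5, u.max() + 0.5
    nw = int(round((BAND_W[1] - BAND_W[0]) * resolution))
    nu = int(np.ceil((u_hi - u_lo) * resolution))
    occupied = np.zeros((nw, nu), dtype=bool)
    h = square_size / 2.0
    for ui, wi in zip(u, w):
        c0 = int(np.floor((ui - h - u_lo) * resolution))
        c1 = int(np.ceil((ui + h - u_lo) * resolution))
        r0 = int(np.floor((wi - h - BAND_W[0]) * resolution))
        r1 = int(np.ceil((wi + h - BAND_W[0]) * resolution))
        occupied[max(r0, 0):max(r1, 0), max(c0, 0):max(c1, 0)] = True
    empty = ~occupied
    labels, n = ndimage.label(empty, structure=np.ones((3, 3), dtype=bool))
    voids = []
    cell_px = resolution * resolution
    for lab in range(1, n + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area < min_area_units * cell_px:
            continue
        wi_idx, ui_idx = np.nonzero(mask)
        voids.append(
            VoidSpace(
                area_px=area,
                area_units=area / cell_px,
                centroid_u=float(ui_idx.mean() / resolution + u_lo),
                centroid_w=float(wi_idx.mean() / resolution + BAND_W[0]),
                est_lost=max(1, round(area / cell_px)),
                pixels=np.stack([wi_idx, ui_idx], axis=1),
            )
        )
    return voids


def estimate_lost_cells(
    voids: list[VoidSpace],
    grid: StandardGrid,
    resolution: int = RASTER_RES,
) -> pd.DataFrame:
    """Total lost-cell count and imputed template positions.

    Each void contributes round(area / cell area) lost cells placed at
    template lattice nodes (integer u offsets, rows w = 1, 2, 3) inside
    the void; surplus counts fall back to the void centroid.
    """
    ohc = grid.cells[grid.cells.kind == "OHC"]
    u_lo = ohc.u.min() - 0.5
    rows = []
    for vid, void in enumerate(voids):
        # lattice nodes covered by this void
        node_votes = {}
        for wi, ui in void.pixels:
            nu = round(ui / resolution + u_lo)
            nw = round(wi / resolution + BAND_W[0])
            if 1 <= nw <= 3:
                node_votes[(nu, nw)] = node_votes.get((nu, nw), 0) + 1
        nodes = sorted(node_votes, key=node_votes.get, reverse=True)[: void.est_lost]
        for k in range(void.est_lost):
            if k < len(nodes):
                nu, nw = nodes[k]
            else:
                nu, nw = void.centroid_u, round(np.clip(void.centroid_w, 1, 3))
            rows.append(
                {"void_id": vid, "u": float(nu), "w": float(nw), "row": int(nw),
                 "s": float(grid.u_to_s(np.atleast_1d(nu))[0])}
            )
    return pd.DataFrame(rows, columns=["void_id", "u", "w", "row", "s"])


def loss_profiles(
    lost: pd.DataFrame,
    grid: StandardGrid,
    bin_um: float = 50.0,
    n_long: int = 13,
    n_rad: int = 15,
) -> dict:
    """Longitudinal (50 um bins), radial (per row) and segment profiles.

    The segment frequency matrix divides the normalized band area into
    ``n_long`` longitudinal x ``n_rad`` radial equal segments.
    """
    s_max = float(grid.s_knots[-1])
    edges = np.arange(0.0, s_max + bin_um, bin_um)
    s_vals = lost.s.to_numpy() if len(lost) else np.zeros(0)
    hist, _ = np.histogram(np.clip(s_vals, 0, edges[-1] - 1e-9), bins=edges)
    radial = {row: int((lost.row == row).sum()) for row in (1, 2, 3)} if len(lost) else {
        1: 0, 2: 0, 3: 0
    }
    ohc = grid.cells[grid.cells.kind == "OHC"]
    u_lo, u_hi = ohc.u.min() - 0.5, ohc.u.max() + 0.5
    seg = np.zeros((n_long, n_rad))
    if len(lost):
        iu = np.clip(
            ((lost.u - u_lo) / (u_hi - u_lo) * n_long).astype(int), 0, n_long - 1
        )
        iw = np.clip(
            ((lost.w - BAND_W[0]) / (BAND_W[1] - BAND_W[0]) * n_rad).astype(int),
            0, n_rad - 1,
        )
        np.add.at(seg, (iu, iw), 1)
    return {
        "longitudinal_edges_um": edges,
        "longitudinal_counts": hist,
        "radial_counts": radial,
        "segment_matrix": seg,
        "total_lost": int(len(lost)),
    }


def pca_loss_frequency(matrices: list[np.ndarray]) -> dict:
    """Principal components of per-sample loss-frequency matrices.

    Flattened matrices are centered across samples and decomposed by
    SVD; returns unit-norm coefficient vectors for the first two
    components and per-sample scores.
    """
    if len(matrices) < 3:
        raise ValueError("need at least 3 samples")
    X = np.stack([np.asarray(m, dtype=float).ravel() for m in matrices])
    mu = X.mean(axis=0)
    Xc = X - mu
    if np.allclose(Xc, 0):
        import warnings

        warnings.warn("all samples identical: zero variance, components undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    return {
        "components": Vt[:2],
        "scores": scores[:, :2],
        "singular_values": S,
        "explained_variance_ratio": (S**2 / max((S**2).sum(), 1e-30))[:2],
        "mean": mu,
    }
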