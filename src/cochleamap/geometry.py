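"""Ground-truth cochlear geometry.

The organ of Corti is modelled as a conical spiral (the modiolus is the
z axis): a single row of inner hair cells (IHCs) runs along the spiral,
and three parallel rows of outer hair cells (OHCs) lie on the same
epithelial surface at increasing radial offsets.  All coordinates are in
micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeometryConfig", "CochleaGeometry", "generate_geometry", "REDUCED", "FULL"]


@dataclass
class GeometryConfig:
    """Parameters of the spiral and the cell lattice.

    Defaults describe a full-size mouse cochlea (~2 turns, organ span
    about 1200 x 1200 x 800 um, 550-650 IHCs).
    """

    turns: float = 2.0
    base_radius: float = 500.0
    apex_radius: float = 250.0
    vertical_drop: float = 450.0          # total descent along the modiolar axis
    ihc_spacing_mean: float = 8.0
    ihc_spacing_sd: float = 0.35
    ihc_spacing_min: float = 6.5          # consecutive-IHC linking constraint is > 6
    ohc_spacing_mean: float = 7.0
    ohc_spacing_sd: float = 0.3
    ohc_spacing_min: float = 6.2
    ohc_row_offsets: tuple[float, float, float] = (18.0, 26.0, 34.0)  # radial, from IHC row
    ohc_row_v_offsets: tuple[float, float, float] = (-2.0, -3.0, -4.0)  # surface tilt
    position_jitter: float = 0.5          # isotropic placement jitter (um, 1 sd)
    ihc_count_range: tuple[int, int] = (550, 650)

    def spiral_length(self) -> float:
        """Approximate arc length of the IHC spiral (planar component)."""
        mean_r = 0.5 * (self.base_radius + self.apex_radius)
        return 2.0 * np.pi * mean_r * self.turns


#: Desk-scale preset: ~0.94 turn, ~150 IHCs, ~500 OHCs.
REDUCED = GeometryConfig(
    turns=0.94,
    base_radius=230.0,
    apex_radius=170.0,
    vertical_drop=40.0,
    ihc_count_range=(130, 170),
)

#: Full-size preset (alias of the defaults).
FULL = GeometryConfig()


@dataclass
class CochleaGeometry:
    """Cell positions plus the generating spiral parameters.

    ``ihc_positions``: (n_ihc, 3) array, ordered base -> apex.
    ``ohc_positions``: (n_ohc, 3) array; ``ohc_rows`` gives the row label
    (1 = closest to the IHC row) and ``ohc_rank`` the order along the row.
    """

    ihc_positions: np.ndarray
    ohc_positions: np.ndarray
    ohc_rows: np.ndarray
    ohc_rank: np.ndarray
    config: GeometryConfig
    spacing_stats: dict = field(default_factory=dict)

    @property
    def n_ihc(self) -> int:
        return len(self.ihc_positions)

    @property
    def n_ohc(self) -> int:
        return len(self.ohc_positions)

    def all_cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (positions, kinds, rows) for every cell; kind 'IHC'/'OHC'."""
        pos = np.vstack([self.ihc_positions, self.ohc_positions])
        kinds = np.array(["IHC"] * self.n_ihc + ["OHC"] * self.n_ohc)
        rows = np.concatenate([np.zeros(self.n_ihc, dtype=int), self.ohc_rows])
        return pos, kinds, rows

    def ihc_polyline_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.ihc_positions, axis=0), axis=1)))


def _spiral_point(theta: np.ndarray, cfg: GeometryConfig, theta_total: float):
    """Spiral centre line and local frame at unwrapped angle ``theta``.

    Returns (point, e_r, e_v): the point on the IHC row, the outward
    radial unit vector (away from the modiolus) and the surface normal.
    """
    frac = theta / theta_total
    r = cfg.base_radius + (cfg.apex_radius - cfg.base_radius) * frac
    z = -cfg.vertical_drop * frac
    p = np.stack([r * np.cos(theta), r * np.sin(theta), z * np.ones_like(theta)], axis=-1)
    e_r = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    e_v = np.broadcast_to(np.array([0.0, 0.0, 1.0]), p.shape)
    return p, e_r, e_v


def _arc_to_theta(cfg: GeometryConfig, theta_total: float, n_samples: int = 4000):
    """Lookup table arc length -> theta along the IHC spiral."""
    thetas = np.linspace(0.0, theta_total, n_samples)
    pts, _, _ = _spiral_point(thetas, cfg, theta_total)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s, thetas


def generate_geometry(config: GeometryConfig | None = None, seed: int = 0) -> CochleaGeometry:
    """Generate a ground-truth cochlea.

    Cells are placed by walking along the spiral with per-step spacing
    drawn around the configured mean (clipped below at the spacing
    minimum so no two same-row cells are closer than 6 um), then
    jittered isotropically.  Deterministic for a given (config, seed).

    Raises
    ------
    ValueError
        If the configuration is infeasible (non-positive turn count, or
        the spiral is too short to hold at least 10 IHCs).
    """
    cfg = config or GeometryConfig()
    if cfg.turns <= 0:
        raise ValueError("turn count must be positive")
    total_len = cfg.spiral_length()
    if total_len < 10 * cfg.ihc_spacing_mean:
        raise ValueError(
            f"spiral length {total_len:.0f} um cannot hold 10 IHCs at "
            f"{cfg.ihc_spacing_mean} um spacing"
        )
    rng = np.random.default_rng(seed)
    theta_total = 2.0 * np.pi * cfg.turns
    s_tab, th_tab = _arc_to_theta(cfg, theta_total)
    total_s = s_tab[-1]

    def place_row(spacing_mean, spacing_sd, spacing_min, r_off, v_off, sub):
        rr = np.random.default_rng([seed, sub])
        spacings = []
        s = spacing_mean * 0.5
        while s < total_s - spacing_mean * 0.25:
            spacings.append(s)
            s += max(spacing_min, rr.normal(spacing_mean, spacing_sd))
        svals = np.asarray(spacings)
        theta = np.interp(svals, s_tab, th_tab)
        p, e_r, e_v = _spiral_point(theta, cfg, theta_total)
        pos = p + r_off * e_r + v_off * e_v
        # jitter only across the row (radial/vertical) so along-row spacing,
        # and with it the > 6 um linking constraint, is preserved exactly
        jit = rr.normal(0.0, cfg.position_jitter, (len(pos), 2))
        pos = pos + jit[:, :1] * e_r + jit[:, 1:] * e_v
        return pos

    ihc = place_row(cfg.ihc_spacing_mean, cfg.ihc_spacing_sd, cfg.ihc_spacing_min, 0.0, 0.0, 0)
    ohc_pos, ohc_rows, ohc_rank = [], [], []
    for j in range(3):
        row = place_row(
            cfg.ohc_spacing_mean, cfg.ohc_spacing_sd, cfg.ohc_spacing_min,
            cfg.ohc_row_offsets[j], cfg.ohc_row_v_offsets[j], j + 1,
        )
        ohc_pos.append(row)
        ohc_rows.append(np.full(len(row), j + 1, dtype=int))
        ohc_rank.append(np.arange(len(row)))
    geom = CochleaGeometry(
        ihc_positions=ihc,
        ohc_positions=np.vstack(ohc_pos),
        ohc_rows=np.concatenate(ohc_rows),
        ohc_rank=np.concatenate(ohc_rank),
        config=cfg,
        spacing_stats={
            "ihc_spacing_mean": float(np.mean(np.linalg.norm(np.diff(ihc, axis=0), axis=1))),
            "spiral_length": float(total_s),
        },
    )
    lo, hi = cfg.ihc_count_range
    if not (lo <= geom.n_ihc <= hi):
        raise ValueError(
            f"generated {geom.n_ihc} IHCs, outside configured range [{lo}, {hi}]; "
            "adjust spiral length or spacing"
        )
    return geom
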