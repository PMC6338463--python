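"""End-to-end orchestration: phantom, stitching, linearization, detection.

The detection geometry is established in two passes.  An initial spiral
is fitted through the whole hair-cell band, shifted radially onto the
innermost (IHC) row, and a narrow slab around that row is straightened
to detect the IHC chain.  The spiral is then refitted through the IHC
positions (the fine readjustment of image linearization), the full slab
is straightened with the IHC row at r = 0, and the staged detectors are
run for both cell kinds.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import detect as det
from .geometry import REDUCED, CochleaGeometry, GeometryConfig, generate_geometry
from .linearize import (
    LinearizedVolume,
    SpiralModel,
    build_spiral,
    cluster_peaks,
    find_peaks,
    resample_linearized,
)
from .phantom import LossGroundTruth, PhantomSpec, VoxelVolume, inject_loss, render_tiles
from .stitch import TileLayout, refine_layout, stitch

__all__ = [
    "PhantomRun",
    "simulate_phantom",
    "assemble_tiles",
    "initial_ihc_spiral",
    "shift_spiral",
    "linearize_sample",
    "detect_pass1_ihc",
    "process_phantom",
    "train_detector",
]

IHC_SLAB_R = (-14.0, 14.0)
IHC_SLAB_V = (-20.0, 20.0)
FULL_SLAB_R = (-30.0, 60.0)
FULL_SLAB_V = (-25.0, 25.0)


@dataclass
class PhantomRun:
    """All artifacts of one phantom processed end to end."""

    seed: int
    geometry: CochleaGeometry
    loss: LossGroundTruth
    truth: pd.DataFrame
    volume: VoxelVolume
    spiral: SpiralModel
    linv: LinearizedVolume
    cells: pd.DataFrame | None = None
    timings: dict = field(default_factory=dict)


def simulate_phantom(
    seed: int,
    geometry_config: GeometryConfig = REDUCED,
    n_lost: int = 15,
    loss_generator: str = "neighborhood",
    spec: PhantomSpec | None = None,
):
    """Generate geometry, inject loss, render tiles.  Returns
    (tiles, truth table, geometry, loss)."""
    geom = generate_geometry(geometry_config, seed=seed)
    loss = inject_loss(geom, loss_generator, n_lost, seed=seed)
    spec = spec or PhantomSpec(seed=seed)
    tiles, table = render_tiles(geom, loss, spec)
    return tiles, table, geom, loss


def assemble_tiles(tiles: list[VoxelVolume], search_radius: float = 5.0) -> VoxelVolume:
    layout = TileLayout.from_tiles(tiles)
    layout = refine_layout(layout, search_radius=search_radius)
    return stitch(layout)


def shift_spiral(spiral: SpiralModel, dr: float) -> SpiralModel:
    """Translate the curve radially by ``dr`` um and re-parameterize."""
    curve = spiral.curve + dr * spiral.radial
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s_raw = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.arange(0.0, s_raw[-1] + 0.5, 1.0)
    c = np.stack([np.interp(grid, s_raw, curve[:, k]) for k in range(3)], axis=1)
    vert = np.stack([np.interp(grid, s_raw, spiral.vertical[:, k]) for k in range(3)], axis=1)
    vert /= np.linalg.norm(vert, axis=1, keepdims=True)
    tang = np.gradient(c, grid, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    radial = np.cross(vert, tang)
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    vert = np.cross(tang, radial)
    return SpiralModel(
        curve=c, s=grid, tangent=tang, radial=radial, vertical=vert,
        segments=spiral.segments, end_extension=spiral.end_extension,
    )


def _innermost_row_offset(spiral: SpiralModel, band_points: np.ndarray) -> float:
    """Radial offset of the innermost (IHC) row from the band curve.

    The r histogram of band peaks has four modes (IHC + three OHC rows);
    the smallest-r mode is the IHC row.
    """
    srv = spiral.linear_from_world(band_points)
    r = srv[:, 1]
    edges = np.arange(-40, 40.5, 0.5)
    hist, _ = np.histogram(r, bins=edges)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), 3.0)
    is_max = (smooth >= np.roll(smooth, 1)) & (smooth >= np.roll(smooth, -1))
    is_max &= smooth > 0.2 * smooth.max()
    centers = 0.5 * (edges[:-1] + edges[1:])
    modes = centers[is_max]
    if len(modes) == 0:
        return float(np.median(r))
    return float(modes.min())


def initial_ihc_spiral(volume: VoxelVolume) -> SpiralModel:
    """Band spiral from intensity peaks, shifted onto the IHC row."""
    peaks = find_peaks(volume)
    peaks = cluster_peaks(peaks)
    band = peaks.points[peaks.cluster_id == 0]
    spiral = build_spiral(band)
    dr = _innermost_row_offset(spiral, band)
    return shift_spiral(spiral, dr)


def linearize_sample(
    volume: VoxelVolume,
    spiral: SpiralModel,
    r_range=FULL_SLAB_R,
    v_range=FULL_SLAB_V,
) -> LinearizedVolume:
    return resample_linearized(volume, spiral, r_range, v_range)


def detect_pass1_ihc(
    linv: LinearizedVolume,
    models: det.DetectorModels,
    stage1_thresh: float = 0.1,
) -> pd.DataFrame:
    """Quick IHC localization on the narrow slab: template matching,
    stage-1 scoring and chain linking (no stage 2; the chain only seeds
    the spiral refit)."""
    template = det.build_template(linv)
    corr, peaks = det.match_template_volume(linv, template)
    cands = det.form_candidates(corr, peaks, linv)
    if len(cands) == 0:
        raise RuntimeError("no candidates in the IHC slab")
    s1 = models.stage1_ihc.predict_proba(cands.df[det.STAGE1_FEATURES].to_numpy())[:, 1]
    df = cands.df.copy()
    df["score"] = s1
    chain = det._chain_ihc(df[df.score >= stage1_thresh])
    world = linv.spiral.world_from_linear(
        chain.s.to_numpy(), chain.r.to_numpy(), chain.v.to_numpy()
    )
    chain = chain.copy()
    chain[["x", "y", "z"]] = world
    return chain


def process_phantom(
    seed: int,
    models: det.DetectorModels | None = None,
    geometry_config: GeometryConfig = REDUCED,
    n_lost: int = 15,
    loss_generator: str = "neighborhood",
    spec: PhantomSpec | None = None,
    refit_with_truth: bool = False,
) -> PhantomRun:
    """Run one phantom end to end.

    With ``refit_with_truth`` the spiral readjustment uses the true
    surviving IHC positions instead of a pass-1 detection (used when
    harvesting training candidates, where models do not exist yet).
    """
    timings = {}
    t0 = time.time()
    tiles, truth, geom, loss = simulate_phantom(
        seed, geometry_config, n_lost, loss_generator, spec
    )
    timings["render"] = time.time() - t0
    t0 = time.time()
    volume = assemble_tiles(tiles)
    timings["stitch"] = time.time() - t0
    t0 = time.time()
    spiral0 = initial_ihc_spiral(volume)
    if refit_with_truth:
        ihc_world = truth[(truth.kind == "IHC") & (~truth.lost)][["x", "y", "z"]].to_numpy()
    else:
        if models is None:
            raise ValueError("models required unless refit_with_truth=True")
        linv1 = linearize_sample(volume, spiral0, IHC_SLAB_R, IHC_SLAB_V)
        chain1 = detect_pass1_ihc(linv1, models)
        ihc_world = chain1[["x", "y", "z"]].to_numpy()
    spiral = build_spiral(ihc_world)
    timings["linearize_fit"] = time.time() - t0
    t0 = time.time()
    linv = linearize_sample(volume, spiral)
    timings["resample"] = time.time() - t0
    cells = None
    if models is not None:
        t0 = time.time()
        cells = det.detect_cells(linv, models)
        timings["detect"] = time.time() - t0
    return PhantomRun(seed, geom, loss, truth, volume, spiral, linv, cells, timings)


def _truth_srv(run: PhantomRun):
    surv = run.truth[~run.truth.lost]
    srv = run.linv.spiral.linear_from_world(surv[["x", "y", "z"]].to_numpy())
    return surv, srv


def train_detector(
    train_seeds: list[int],
    seed: int = 0,
    geometry_config: GeometryConfig = REDUCED,
    n_lost: int = 15,
    loss_generator: str = "neighborhood",
) -> det.DetectorModels:
    """Harvest candidates from training phantoms and train the stack.

    Training phantoms are processed with the truth-based spiral refit
    (teacher forcing); candidate labels are positives within 4 um of a
    surviving ground-truth cell.
    """
    rng = np.random.default_rng(seed)
    cand_sets, label_frames, slab_sets = [], [], []
    gap_crop_list, gap_label_list = [], []
    for ps in train_seeds:
        run = process_phantom(
            ps, geometry_config=geometry_config, n_lost=n_lost,
            loss_generator=loss_generator, refit_with_truth=True,
        )
        template = det.build_template(run.linv)
        corr, peaks = det.match_template_volume(run.linv, template)
        cands = det.form_candidates(corr, peaks, run.linv)
        cands.corr = None          # free the correlation volume
        run.linv.oob_mask = None
        surv, srv = _truth_srv(run)
        labels = det.label_candidates(
            cands, srv, surv.kind.to_numpy(), surv.row.to_numpy()
        )
        cand_sets.append(cands)
        label_frames.append(labels)
        # candidates of the narrow pass-1 IHC slab (different neighbor
        # context); stage-1 IHC training must cover this regime too
        spiral0 = initial_ihc_spiral(run.volume)
        linv1 = linearize_sample(run.volume, spiral0, IHC_SLAB_R, IHC_SLAB_V)
        t1 = det.build_template(linv1)
        corr1, peaks1 = det.match_template_volume(linv1, t1)
        cands1 = det.form_candidates(corr1, peaks1, linv1)
        srv1 = linv1.spiral.linear_from_world(surv[["x", "y", "z"]].to_numpy())
        labels1 = det.label_candidates(
            cands1, srv1, surv.kind.to_numpy(), surv.row.to_numpy()
        )
        slab_sets.append(
            (cands1.df[det.STAGE1_FEATURES].to_numpy(), labels1.is_ihc.to_numpy())
        )
        lost = run.truth[run.truth.lost]
        lost_srv = (
            run.linv.spiral.linear_from_world(lost[["x", "y", "z"]].to_numpy())
            if len(lost)
            else np.zeros((0, 3))
        )
        gc, gl = det.build_gap_training_crops(
            run.linv, srv, surv.kind.to_numpy(), lost_srv, rng
        )
        gap_crop_list.append(gc)
        gap_label_list.append(gl)
    return det.train_models(
        cand_sets,
        label_frames,
        np.concatenate(gap_crop_list),
        np.concatenate(gap_label_list),
        seed=seed,
        ihc_slab_sets=slab_sets,
    )
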