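"""Shared fixtures.

The trained detector stack and the 10-phantom benchmark are expensive
(minutes); they are built once per session and shared by the detection
and acceptance tests.  Benchmark results keep only lightweight metrics,
not the volumes.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
import pytest

from cochleamap import detect as det
from cochleamap import pipeline as pl

TRAIN_SEEDS = [11, 12, 13, 14, 15]
BENCH_SEEDS = list(range(1, 11))


@pytest.fixture(scope="session")
def trained_models():
    """Detector stack trained on 5 phantoms disjoint from the benchmark."""
    return pl.train_detector(TRAIN_SEEDS, seed=0)


@pytest.fixture(scope="session")
def benchmark_results(trained_models):
    """Full pipeline on 10 benchmark phantoms; per-phantom metrics only."""
    results = []
    for seed in BENCH_SEEDS:
        t0 = time.time()
        run = pl.process_phantom(seed, models=trained_models)
        elapsed = time.time() - t0
        surv = run.truth[~run.truth.lost]
        metrics = {}
        for kind in ("IHC", "OHC"):
            metrics[kind] = det.evaluate_detection(
                run.cells[run.cells.kind == kind][["x", "y", "z"]].to_numpy(),
                surv[surv.kind == kind][["x", "y", "z"]].to_numpy(),
            )
        ws = det.watershed_baseline(run.linv)
        ws_metrics = det.evaluate_detection(
            ws[["x", "y", "z"]].to_numpy(),
            surv[["x", "y", "z"]].to_numpy(),
        )
        staged_all = det.evaluate_detection(
            run.cells[["x", "y", "z"]].to_numpy(),
            surv[["x", "y", "z"]].to_numpy(),
        )
        results.append(
            {
                "seed": seed,
                "metrics": metrics,
                "watershed": ws_metrics,
                "staged_all": staged_all,
                "runtime_s": elapsed,
                "spiral_length": run.spiral.length,
                "ihc_polyline_length": run.geometry.ihc_polyline_length(),
                "cells": run.cells,
                "truth": run.truth,
            }
        )
    return results


def make_lattice_cells(
    n_cols: int = 60,
    spacing_u: float = 8.0,
    spacing_w: float = 7.0,
    removed: list[tuple[int, int]] | None = None,
    gradient: float = 0.0,
) -> pd.DataFrame:
    """Synthetic straight lattice cell map: 1 IHC row + 3 OHC rows.

    ``removed`` lists (row, col) OHC lattice nodes left out;
    ``gradient`` linearly scales the u spacing along the lattice.
    """
    removed = set(removed or [])
    rows = []
    s_vals = np.cumsum(spacing_u * (1 + gradient * np.arange(n_cols) / n_cols))
    for c, s in enumerate(s_vals):
        rows.append({"kind": "IHC", "row": 0, "s": s, "r": 0.0})
    for row in (1, 2, 3):
        for c, s in enumerate(s_vals):
            if (row, c) in removed:
                continue
            rows.append({"kind": "OHC", "row": row, "s": s, "r": 18.0 + spacing_w * (row - 1)})
    return pd.DataFrame(rows)
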