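"""Coordinate normalization, void spaces and loss profiles."""

import numpy as np

import pytest

from cochleamap import loss_map as lmap
from conftest import make_lattice_cells


def test_perfect_lattice_normalizes_to_unit_spacing():
    cells = make_lattice_cells(spacing_u=8.0, spacing_w=7.0)
    grid = lmap.normalize_coordinates(cells)
    ohc = grid.cells[grid.cells.kind == "OHC"]
    for row in (1, 2, 3):
        u = np.sort(ohc[ohc.row == row].u.to_numpy())
        np.testing.assert_allclose(np.diff(u), 1.0, atol=0.02)
    # rows sit one unit apart in w
    means = ohc.groupby("row").w.mean()
    np.testing.assert_allclose(means.to_numpy(), [1.0, 2.0, 3.0], atol=0.01)


def test_gradient_lattice_spacing_uniform_after_normalization():
    cells = make_lattice_cells(n_cols=80, gradient=0.5)
    grid = lmap.normalize_coordinates(cells)
    ohc = grid.cells[(grid.cells.kind == "OHC") & (grid.cells.row == 2)]
    du = np.diff(np.sort(ohc.u.to_numpy()))
    assert du.max() / du.min() < 1.05  # uniform within 5%


def test_normalization_preserves_order_along_s():
    cells = make_lattice_cells()
    grid = lmap.normalize_coordinates(cells)
    ohc = grid.cells[(grid.cells.kind == "OHC") & (grid.cells.row == 1)].sort_values("s")
    assert np.all(np.diff(ohc.u.to_numpy()) > 0)


def test_too_few_cells_raise():
    cells = make_lattice_cells(n_cols=2)
    with pytest.raises(ValueError):
        lmap.normalize_coordinates(cells.head(5))


def test_complete_lattice_has_no_voids():
    grid = lmap.normalize_coordinates(make_lattice_cells())
    assert lmap.find_void_spaces(grid) == []


def test_single_removed_cell_gives_one_void_count_one():
    grid = lmap.normalize_coordinates(make_lattice_cells(removed=[(2, 30)]))
    voids = lmap.find_void_spaces(grid)
    assert len(voids) == 1
    assert voids[0].est_lost == 1
    lost = lmap.estimate_lost_cells(voids, grid)
    assert len(lost) == 1
    assert lost.iloc[0].row == 2


def test_L_shaped_triple_removal_is_one_void_count_three():
    grid = lmap.normalize_coordinates(
        make_lattice_cells(removed=[(1, 30), (1, 31), (2, 30)])
    )
    voids = lmap.find_void_spaces(grid)
    assert len(voids) == 1
    assert voids[0].est_lost == 3
    lost = lmap.estimate_lost_cells(voids, grid)
    assert len(lost) == 3


def test_double_area_void_counts_two():
    grid = lmap.normalize_coordinates(make_lattice_cells(removed=[(3, 20), (3, 21)]))
    voids = lmap.find_void_spaces(grid)
    assert len(voids) == 1
    assert voids[0].est_lost == 2


def _bruteforce_void_raster(grid, resolution=10):
    """Independent raster oracle: explicit per-pixel-centre loop."""
    ohc = grid.cells[grid.cells.kind == "OHC"]
    u, w = ohc.u.to_numpy(), ohc.w.to_numpy()
    u_lo = u.min() - 0.5
    nu = int(np.ceil((u.max() + 0.5 - u_lo) * resolution))
    nw = int(round(3.0 * resolution))
    occ = np.zeros((nw, nu), dtype=bool)
    for wi in range(nw):
        for ui in range(nu):
            wc = 0.5 + (wi + 0.5) / resolution
            uc = u_lo + (ui + 0.5) / resolution
            for cu, cw in zip(u, w):
                if abs(uc - cu) <= 0.5 and abs(wc - cw) <= 0.5:
                    occ[wi, ui] = True
                    break
    return occ


def test_void_partition_matches_bruteforce_oracle():
    # same void partition (count, counts per void and locations) as an
    # explicit pixel-centre oracle; pixel areas may differ by the
    # one-pixel boundary convention of the fast rasterizer
    from scipy import ndimage

    grid = lmap.normalize_coordinates(
        make_lattice_cells(n_cols=24, removed=[(1, 5), (2, 5), (2, 12), (3, 20)])
    )
    voids = lmap.find_void_spaces(grid)
    occ = _bruteforce_void_raster(grid)
    labels, n_oracle = ndimage.label(~occ, structure=np.ones((3, 3), bool))
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= 50)  # same half-cell-area filter
    assert len(voids) == len(keep)
    oracle = []
    for lab in keep:
        wi, ui = np.nonzero(labels == lab + 1)
        oracle.append(
            (round(sizes[lab] / 100), ui.mean() / 10 + grid.cells.u.min(), wi.mean())
        )
    # est_lost per void must agree exactly; centroids within one pixel
    assert sorted(v.est_lost for v in voids) == sorted(o[0] for o in oracle)
    for v, o in zip(
        sorted(voids, key=lambda v: v.centroid_u), sorted(oracle, key=lambda o: o[1])
    ):
        assert abs(v.centroid_w - (0.5 + (o[2] + 0.5) / 10)) < 0.3


def test_estimator_unbiased_over_random_removals():
    rng = np.random.default_rng(0)
    errors = []
    for trial in range(60):
        k = int(rng.integers(3, 25))
        removed = set()
        while len(removed) < k:
            removed.add((int(rng.integers(1, 4)), int(rng.integers(0, 60))))
        grid = lmap.normalize_coordinates(make_lattice_cells(removed=sorted(removed)))
        lost = lmap.estimate_lost_cells(lmap.find_void_spaces(grid), grid)
        errors.append(len(lost) - k)
    assert abs(np.mean(errors)) < 0.05 * 14  # mean estimate within 5% of mean k


def test_profiles_conserve_totals():
    grid = lmap.normalize_coordinates(
        make_lattice_cells(removed=[(1, 5), (2, 30), (3, 31), (3, 32)])
    )
    lost = lmap.estimate_lost_cells(lmap.find_void_spaces(grid), grid)
    prof = lmap.loss_profiles(lost, grid)
    assert prof["longitudinal_counts"].sum() == prof["total_lost"] == len(lost)
    assert prof["segment_matrix"].sum() == len(lost)
    assert sum(prof["radial_counts"].values()) == len(lost)
    assert prof["segment_matrix"].shape == (13, 15)


def test_all_losses_in_one_bin():
    grid = lmap.normalize_coordinates(make_lattice_cells(removed=[(1, 3), (2, 3), (3, 3)]))
    lost = lmap.estimate_lost_cells(lmap.find_void_spaces(grid), grid)
    prof = lmap.loss_profiles(lost, grid)
    counts = prof["longitudinal_counts"]
    assert (counts > 0).sum() == 1 and counts.max() == 3


def test_uniform_losses_pass_chi_square():
    from scipy.stats import chisquare

    rng = np.random.default_rng(42)
    # pool losses across seeds; uniform removal must not reject uniformity
    all_bins = np.zeros(12)
    for _ in range(40):
        cols = rng.choice(60, 5, replace=False)
        rows = rng.integers(1, 4, 5)
        grid = lmap.normalize_coordinates(
            make_lattice_cells(removed=sorted(zip(rows.tolist(), cols.tolist())))
        )
        lost = lmap.estimate_lost_cells(lmap.find_void_spaces(grid), grid)
        ohc = grid.cells[grid.cells.kind == "OHC"]
        h = np.histogram(
            lost.u, bins=12, range=(ohc.u.min() - 0.5, ohc.u.max() + 0.5)
        )[0]
        all_bins += h
    _, p = chisquare(all_bins)
    assert p > 0.01


def test_pca_separates_orthogonal_patterns():
    rng = np.random.default_rng(0)
    base_a = np.zeros((13, 15))
    base_a[:3] = 5
    base_b = np.zeros((13, 15))
    base_b[-3:] = 5
    mats = []
    labels = []
    for i in range(6):
        noise = rng.poisson(0.2, (13, 15))
        mats.append((base_a if i % 2 == 0 else base_b) + noise)
        labels.append(i % 2)
    out = lmap.pca_loss_frequency(mats)
    s1 = out["scores"][:, 0]
    group0, group1 = s1[::2], s1[1::2]
    assert (group0.max() < group1.min()) or (group1.max() < group0.min())


def test_pca_duplicates_get_identical_scores_and_unit_components():
    m = np.random.default_rng(1).poisson(2, (13, 15))
    out = lmap.pca_loss_frequency([m, m + 1, m, m + 1])
    np.testing.assert_allclose(out["scores"][0], out["scores"][2], atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(out["components"], axis=1), 1.0)


def test_pca_needs_three_samples():
    with pytest.raises(ValueError):
        lmap.pca_loss_frequency([np.zeros((13, 15))] * 2)
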