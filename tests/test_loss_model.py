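"""Clustered-loss simulation, null model and error score."""

import numpy as np
import pytest

from cochleamap import loss_model as lm


def test_to_loss_matrix_trivial_cases():
    assert lm.to_loss_matrix(np.array([]), np.array([])).sum() == 0
    mat = lm.to_loss_matrix(np.array([1, 2, 3]), np.array([0.0, 500.0, 1000.0]))
    assert mat.shape == (3, 600)
    assert mat.sum() == 3


def test_adjacent_losses_land_in_adjacent_columns():
    # two losses one intercell spacing apart over a 600-cell row
    rows = np.array([1, 1])
    pos = np.array([100.0, 102.0])
    mat = lm.to_loss_matrix(rows, pos, total_extent=1200.0)
    cols = np.flatnonzero(mat[0])
    assert abs(cols[1] - cols[0]) == 1


def test_single_cell_is_one_cluster_of_size_one():
    mat = np.zeros((3, 600), bool)
    mat[1, 100] = True
    sizes = lm.cluster_sizes(mat)
    np.testing.assert_array_equal(sizes, [1])


def test_2x2_block_is_one_cluster_of_four():
    mat = np.zeros((3, 600), bool)
    mat[0:2, 10:12] = True
    np.testing.assert_array_equal(lm.cluster_sizes(mat), [4])


def test_clustering_matches_floodfill_oracle():
    def flood(mat):
        seen = np.zeros_like(mat, bool)
        sizes = []
        for r0 in range(mat.shape[0]):
            for c0 in range(mat.shape[1]):
                if mat[r0, c0] and not seen[r0, c0]:
                    stack, size = [(r0, c0)], 0
                    seen[r0, c0] = True
                    while stack:
                        r, c = stack.pop()
                        size += 1
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                rr, cc = r + dr, c + dc
                                if (
                                    0 <= rr < mat.shape[0]
                                    and 0 <= cc < mat.shape[1]
                                    and mat[rr, cc]
                                    and not seen[rr, cc]
                                ):
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
                    sizes.append(size)
        return np.sort(sizes)[::-1]

    for seed in range(100):
        rng = np.random.default_rng(seed)
        mat = np.zeros(3 * 60, bool)
        mat[rng.choice(3 * 60, 30, replace=False)] = True
        mat = mat.reshape(3, 60)
        np.testing.assert_array_equal(lm.cluster_sizes(mat), flood(mat))


def test_cluster_sizes_sum_to_losses():
    cfg = lm.LossSimConfig(n_lost=40, w_neigh=5.0, p=3.0)
    mat = lm.simulate_loss(cfg, seed=3)
    assert mat.sum() == 40
    assert lm.cluster_sizes(mat).sum() == 40


def test_null_single_loss_band_degenerate():
    band = lm.random_null(1, reps=50, seed=0)
    assert band["mean_cluster_size"] == (1.0, 1.0)


def test_null_saturated_grid_single_cluster():
    band = lm.random_null(1800, reps=5, seed=0)
    assert band["n_clusters"] == (1.0, 1.0)
    assert band["mean_cluster_size"] == (1800.0, 1800.0)


def test_null_cluster_count_matches_pairwise_expectation():
    # E[#clusters] ~ k - E[#adjacent lost pairs] for sparse uniform loss
    k, n_rows, n_cols = 30, 3, 600
    n = n_rows * n_cols
    m_edges = (
        n_rows * (n_cols - 1)          # horizontal
        + (n_rows - 1) * n_cols        # vertical
        + 2 * (n_rows - 1) * (n_cols - 1)  # diagonals
    )
    expected_pairs = m_edges * k * (k - 1) / (n * (n - 1))
    band = lm.random_null(k, reps=2000, seed=1)
    mc_mean = band["n_clusters_samples"].mean()
    assert mc_mean == pytest.approx(k - expected_pairs, abs=0.2)


def test_uniform_simulation_is_uniform_per_cell():
    from scipy.stats import chisquare

    cfg = lm.LossSimConfig(n_lost=30, w_neigh=0.0, p=0.0)
    counts = np.zeros((3, 600))
    rng = np.random.default_rng(5)
    reps = 2000
    for _ in range(reps):
        counts += lm.simulate_loss(cfg, seed=int(rng.integers(2**31)))
    _, p = chisquare(counts.ravel())
    assert p > 0.01


def test_neighborhood_weight_increases_cluster_size():
    rng = np.random.default_rng(7)
    means = {}
    for w in (0.0, 10.0):
        cfg = lm.LossSimConfig(n_lost=30, w_neigh=w, p=0.0)
        sizes = [
            lm.cluster_sizes(lm.simulate_loss(cfg, seed=int(rng.integers(2**31)))).mean()
            for _ in range(300)
        ]
        means[w] = np.mean(sizes)
    assert means[10.0] > means[0.0] * 1.3


def test_position_effect_requires_positive_p():
    flat = lm.position_effect_values(100, 0.0, np.random.default_rng(0))
    np.testing.assert_array_equal(flat, np.ones(100))
    vals = lm.position_effect_values(1000, 6.0, np.random.default_rng(0))
    assert vals.std() > 0


def test_error_score_identity_and_arithmetic():
    h = np.array([3.0, 1.0, 0.0, 2.0])
    assert lm.error_score(h, h[None, :]) == 0.0
    assert lm.error_score(np.array([3.0]), np.array([[1.0]])) == 4.0
    # mean over simulated histograms
    assert lm.error_score(np.array([2.0]), np.array([[1.0], [3.0]])) == 0.0


def test_error_score_matches_bruteforce_on_random_fixtures():
    rng = np.random.default_rng(2)
    for _ in range(20):
        meas = rng.integers(0, 5, 6).astype(float)
        sims = rng.integers(0, 5, (10, 9)).astype(float)
        m = max(len(meas), sims.shape[1])
        meas_p = np.pad(meas, (0, m - len(meas)))
        sims_p = np.pad(sims, ((0, 0), (0, m - sims.shape[1])))
        brute = sum((meas_p[i] - sims_p[:, i].mean()) ** 2 for i in range(m))
        assert lm.error_score(meas, sims) == pytest.approx(brute)


def test_fit_with_single_grid_point_returns_that_point():
    cfg = lm.LossSimConfig(n_lost=25, w_neigh=8.0, p=0.0)
    mat = lm.simulate_loss(cfg, seed=11)
    fit = lm.fit_two_component(
        mat, w_grid=np.array([8.0]), p_grid=np.array([0.0]), reps=20, seed=0
    )
    assert fit.top3 == [(8.0, 0.0, fit.top3[0][2])]
    assert fit.contribution_neighborhood == 1.0


def test_fit_rejects_empty_matrix():
    with pytest.raises(ValueError):
        lm.fit_two_component(np.zeros((3, 600), bool))


def test_simulation_determinism():
    cfg = lm.LossSimConfig(n_lost=20, w_neigh=3.0, p=3.0)
    a = lm.simulate_loss(cfg, seed=9)
    b = lm.simulate_loss(cfg, seed=9)
    np.testing.assert_array_equal(a, b)
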