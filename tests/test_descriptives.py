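"""Polychoric estimation and the MDS network layout."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from qolclasses.descriptives import (
    PolychoricMatrix,
    bvn_cdf,
    cell_probabilities,
    estimate_thresholds,
    mds_layout,
    polychoric_matrix,
    polychoric_pair,
)
from qolclasses.errors import DegenerateItemError

from conftest import make_items


def discretise(z, n_categories):
    qs = np.quantile(z, np.linspace(0, 1, n_categories + 1)[1:-1])
    return np.digitize(z, qs)


def grid_search_oracle(x, y, step=0.001):
    """Brute-force rho by scanning the discretised-normal likelihood.

    Independent of the package's optimiser and of its Owen's-T rectangle
    probabilities (uses scipy's multivariate normal CDF directly).
    """
    thr_x = estimate_thresholds(x)
    thr_y = estimate_thresholds(y)
    Cx, Cy = len(thr_x) + 1, len(thr_y) + 1
    table = np.zeros((Cx, Cy))
    np.add.at(table, (x, y), 1.0)
    tx = np.concatenate([[-30.0], thr_x, [30.0]])
    ty = np.concatenate([[-30.0], thr_y, [30.0]])
    corners = np.array([[a, b] for a in tx for b in ty])
    best, best_ll = None, -np.inf
    for rho in np.arange(-0.99, 0.99 + step / 2, step):
        mvn = multivariate_normal(cov=[[1.0, rho], [rho, 1.0]])
        grid = mvn.cdf(corners).reshape(len(tx), len(ty))
        cells = np.clip(np.diff(np.diff(grid, axis=0), axis=1), 1e-12, 1.0)
        ll = float(np.sum(table * np.log(cells)))
        if ll > best_ll:
            best, best_ll = rho, ll
    return best


class TestThresholds:
    def test_median_split_threshold_is_zero(self):
        x = np.array([0] * 50 + [1] * 50)
        assert estimate_thresholds(x) == pytest.approx([0.0])

    def test_normal_quantiles_of_cumulative_proportions(self):
        # cumulative proportions [0.5, 0.8413] -> thresholds [0, 1]
        n = 10_000
        c1 = int(0.5 * n)
        c2 = int(round(norm.cdf(1.0) * n)) - c1
        x = np.array([0] * c1 + [1] * c2 + [2] * (n - c1 - c2))
        thr = estimate_thresholds(x)
        assert thr == pytest.approx([0.0, 1.0], abs=1e-3)

    def test_single_observed_category_is_degenerate(self):
        with pytest.raises(DegenerateItemError):
            estimate_thresholds(np.zeros(10, dtype=int))

    def test_zero_margin_collapses_adjacent_thresholds(self):
        x = np.array([0] * 40 + [2] * 60)  # category 1 empty
        thr = estimate_thresholds(x, n_categories=3)
        assert thr[0] == pytest.approx(thr[1])


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.85, -0.3, 0.0, 0.4, 0.95])
    def test_matches_scipy_reference(self, rho):
        rng = np.random.default_rng(2)
        for _ in range(20):
            h, k = rng.normal(size=2) * 1.5
            ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-9)

    def test_cells_sum_to_one(self):
        cells = cell_probabilities(np.array([-0.5, 0.7]), np.array([0.1]), 0.6)
        assert cells.sum() == pytest.approx(1.0, abs=1e-12)
        assert (cells >= 0).all()


class TestPolychoricPair:
    def test_same_discretisation_gives_near_one(self):
        rng = np.random.default_rng(3)
        x = discretise(rng.normal(size=3000), 5)
        assert polychoric_pair(x, x) >= 0.99

    def test_independent_ordinals_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 4, size=20_000)
        y = rng.integers(0, 5, size=20_000)
        assert abs(polychoric_pair(x, y)) < 0.03

    @pytest.mark.parametrize("rho", [-0.5, 0.5])
    def test_recovers_latent_correlation_at_tertiles(self, rho):
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=20_000)
        x, y = discretise(z[:, 0], 3), discretise(z[:, 1], 3)
        assert polychoric_pair(x, y) == pytest.approx(rho, abs=0.03)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=4000)
        x, y = discretise(z[:, 0], 3), discretise(z[:, 1], 3)
        assert polychoric_pair(x, y) == pytest.approx(
            grid_search_oracle(x, y, step=0.002), abs=0.002
        )


class TestPolychoricMatrix:
    def test_symmetric_with_unit_diagonal_and_duplicate_item(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=2000)
        values = 1 + np.column_stack(
            [discretise(z + rng.normal(size=2000), 5) for _ in range(3)]
            + [discretise(z, 5)] * 2  # duplicated column
        )
        pm = polychoric_matrix(make_items(values))
        assert np.allclose(pm.r, pm.r.T)
        assert np.allclose(np.diag(pm.r), 1.0)
        assert pm.r[3, 4] >= 0.99

    def test_independent_items_have_small_correlations(self):
        rng = np.random.default_rng(8)
        values = rng.integers(1, 6, size=(5000, 6))
        pm = polychoric_matrix(make_items(values))
        off = pm.r[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.07


class TestMdsLayout:
    def test_blocks_cluster_closer_than_cross_block(self):
        rng = np.random.default_rng(9)
        n = 4000
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        noise = lambda: 0.35 * rng.normal(size=n)
        cols = [f1 + noise() for _ in range(3)] + [f2 + noise() for _ in range(3)]
        values = 1 + np.column_stack([discretise(c, 5) for c in cols])
        pm = polychoric_matrix(make_items(values))
        layout = mds_layout(pm)
        d = np.linalg.norm(
            layout.coordinates[:, None] - layout.coordinates[None, :], axis=2
        )
        within = np.r_[d[:3, :3][np.triu_indices(3, 1)], d[3:, 3:][np.triu_indices(3, 1)]]
        between = d[:3, 3:].ravel()
        assert within.mean() < between.mean()

    def test_perfect_correlation_collapses_all_points(self):
        pm = PolychoricMatrix(np.ones((4, 4)), [], [f"Q{i}" for i in range(4)])
        layout = mds_layout(pm)
        assert np.allclose(layout.coordinates, layout.coordinates[0], atol=1e-8)

    def test_three_items_embed_exactly_and_preserve_distance_order(self):
        r = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.4], [0.1, 0.4, 1.0]])
        pm = PolychoricMatrix(r, [], ["a", "b", "c"])
        layout = mds_layout(pm)
        d = np.linalg.norm(
            layout.coordinates[:, None] - layout.coordinates[None, :], axis=2
        )
        target = np.sqrt(2 * (1 - r))
        assert np.allclose(d, target, atol=1e-8)

    def test_edge_list_respects_threshold(self):
        r = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.35], [0.1, 0.35, 1.0]])
        pm = PolychoricMatrix(r, [], ["a", "b", "c"])
        layout = mds_layout(pm, edge_threshold=0.3)
        pairs = set(map(tuple, layout.edges[["item_i", "item_j"]].to_numpy()))
        assert pairs == {("a", "b"), ("b", "c")}
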