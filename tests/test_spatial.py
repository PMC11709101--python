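import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from senmap.spatial import (
    SampleExcludedError,
    cluster_test,
    hex_embed,
    neighbor_table,
    null_distribution,
    positive_spots,
    run_spatial_test,
    spots_in_clusters,
)
from senmap.synthetic import SpatialSimConfig, simulate_spatial
from tests.conftest import make_grid


def brute_force_in_clusters(positions, positive, radius=1.0, tol=1e-6):
    """O(n^2) oracle: positive spots with another positive within radius."""
    pos = np.flatnonzero(positive)
    if pos.size < 2:
        return 0
    d = cdist(positions[pos], positions[pos])
    np.fill_diagonal(d, np.inf)
    return int((d.min(axis=1) <= radius + tol).sum())


def random_hex_grid(rng, max_rows=20, max_cols=20, max_spots=200):
    rows = rng.integers(3, max_rows)
    cols = rng.integers(3, max_cols)
    coords = [(r, c) for r in range(rows) for c in range(cols) if (r + c) % 2 == 0]
    rng.shuffle(coords)
    coords = coords[: min(len(coords), max_spots)]
    n = len(coords)
    positive = rng.random(n) < rng.uniform(0.05, 0.6)
    grid = make_grid(coords)
    return hex_embed(grid), positive


class TestHexEmbed:
    @pytest.mark.parametrize(
        "a,b,dist",
        [
            ((0, 0), (0, 2), 1.0),   # same row, next column slot
            ((0, 0), (1, 1), 1.0),   # diagonal hex neighbor
            ((0, 0), (0, 4), 2.0),   # two slots away
            ((0, 0), (2, 0), np.sqrt(3)),  # vertically stacked, not adjacent
        ],
    )
    def test_pair_distances(self, a, b, dist):
        grid = make_grid([a, b])
        xy = hex_embed(grid)
        assert np.hypot(*(xy[1] - xy[0])) == pytest.approx(dist)

    def test_all_six_neighbors_at_distance_one(self):
        center = (10, 10)
        neighbors = [(10, 8), (10, 12), (9, 9), (9, 11), (11, 9), (11, 11)]
        grid = make_grid([center] + neighbors)
        xy = hex_embed(grid)
        d = np.hypot(*(xy[1:] - xy[0]).T)
        np.testing.assert_allclose(d, 1.0)


class TestPositiveSpots:
    def test_high_expression_threshold_inclusive(self):
        g = make_grid([(0, 0), (0, 2), (1, 1)], expr=[1.0, 0.99, 2.0])
        pos = positive_spots(g, "CDKN1A", 1.0)
        assert pos.tolist() == [True, False, True]

    def test_plain_positivity_strict(self):
        g = make_grid([(0, 0), (0, 2)], expr=[0.0, 0.4])
        pos = positive_spots(g, "CDKN1A", 0.0)
        assert pos.tolist() == [False, True]

    def test_no_positive_spot_excludes_sample(self):
        g = make_grid([(0, 0), (0, 2)], expr=[0.2, 0.3])
        with pytest.raises(SampleExcludedError):
            positive_spots(g, "CDKN1A", 1.0)

    def test_unknown_gene(self):
        g = make_grid([(0, 0)], expr=[1.0])
        with pytest.raises(KeyError, match="SDHA"):
            positive_spots(g, "SDHA", 1.0)


class TestSpotsInClusters:
    def test_two_adjacent_positives(self):
        grid = make_grid([(0, 0), (0, 2), (0, 6)])
        xy = hex_embed(grid)
        assert spots_in_clusters(xy, [True, True, False]) == 2

    def test_isolated_positive(self):
        grid = make_grid([(0, 0), (0, 6)])
        xy = hex_embed(grid)
        assert spots_in_clusters(xy, [True, True]) == 0

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            xy, positive = random_hex_grid(rng)
            assert spots_in_clusters(xy, positive) == brute_force_in_clusters(xy, positive)

    def test_adding_adjacent_positive_never_decreases(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            xy, positive = random_hex_grid(rng, max_spots=80)
            before = spots_in_clusters(xy, positive)
            pos_idx = np.flatnonzero(positive)
            if not pos_idx.size:
                continue
            d = cdist(xy, xy[pos_idx]).min(axis=1)
            candidates = np.flatnonzero(~positive & (d <= 1 + 1e-6))
            if not candidates.size:
                continue
            grown = positive.copy()
            grown[candidates[0]] = True
            assert spots_in_clusters(xy, grown) >= before

    def test_relabeling_invariant(self):
        rng = np.random.default_rng(2)
        xy, positive = random_hex_grid(rng)
        perm = rng.permutation(len(positive))
        assert spots_in_clusters(xy[perm], positive[perm]) == spots_in_clusters(xy, positive)


class TestNullDistribution:
    @pytest.fixture
    def small_grid(self):
        grid = make_grid([(0, 0), (0, 2), (0, 4), (1, 1), (1, 3), (2, 0), (2, 4)])
        return hex_embed(grid)

    def test_all_positive_no_randomness(self, small_grid):
        full = spots_in_clusters(small_grid, np.ones(7, bool))
        draws = null_distribution(small_grid, 7, B=50, seed=0)
        assert (draws == full).all()

    @pytest.mark.parametrize("n_positive", [0, 1])
    def test_degenerate_counts(self, small_grid, n_positive):
        assert (null_distribution(small_grid, n_positive, B=20, seed=0) == 0).all()

    def test_too_many_positives(self, small_grid):
        with pytest.raises(ValueError, match="exceeds"):
            null_distribution(small_grid, 8, B=10, seed=0)

    def test_seeded_reproducible(self, small_grid):
        a = null_distribution(small_grid, 3, B=200, seed=7)
        b = null_distribution(small_grid, 3, B=200, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_mean_matches_exact_enumeration(self, small_grid):
        """Empirical null mean within 3 SE of the exact expectation from
        enumerating all C(7,2) positive placements."""
        exact = [
            spots_in_clusters(small_grid, np.isin(np.arange(7), pair))
            for pair in itertools.combinations(range(7), 2)
        ]
        exact_mean, exact_sd = np.mean(exact), np.std(exact)
        B = 4000
        draws = null_distribution(small_grid, 2, B=B, seed=11)
        se = exact_sd / np.sqrt(B)
        assert abs(draws.mean() - exact_mean) < 3 * se


class TestClusterTest:
    def test_observed_above_all_draws(self):
        res = cluster_test(30, np.zeros(100, int), alpha=0.05)
        assert res.percentile == 1.0
        assert res.call == "cluster"
        assert res.p_empirical == pytest.approx(1 / 101)

    def test_observed_at_null_median(self):
        draws = np.concatenate([np.full(50, 4), np.full(25, 3), np.full(25, 5)])
        res = cluster_test(4, draws)
        assert res.percentile == pytest.approx(0.5)
        assert res.call == "ns"

    def test_all_draws_equal_observed(self):
        res = cluster_test(5, np.full(100, 5))
        assert res.p_wilcoxon == 1.0
        assert res.call == "ns"

    def test_disperse_direction(self):
        res = cluster_test(0, np.full(100, 10), alpha=0.05)
        assert res.percentile == 0.0
        assert res.call == "disperse"

    def test_percentile_midrank_ties(self):
        draws = np.array([1, 2, 2, 3])
        res = cluster_test(2, draws)
        assert res.percentile == pytest.approx((1 + 0.5 * 2) / 4)


class TestEndToEnd:
    def test_run_spatial_test_on_clustered_sample(self):
        grid, _ = simulate_spatial(
            SpatialSimConfig(regime="clustered", contagion=1.0, n_positive=12, seed=5)
        )
        res = run_spatial_test(grid, "CDKN1A", threshold=1.0, B=500, seed=6)
        assert res.n_positive == 12
        assert res.observed_in_clusters == 12  # contagion 1 forces one component
        assert res.percentile > 0.95

    def test_relabeling_spots_leaves_result_unchanged(self):
        cfg = SpatialSimConfig(n_rows=10, n_cols=12, n_positive=8, seed=3)
        grid, _ = simulate_spatial(cfg)
        res1 = run_spatial_test(grid, "CDKN1A", threshold=1.0, B=300, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(grid.n_spots)
        shuffled = grid.subset(perm)
        res2 = run_spatial_test(shuffled, "CDKN1A", threshold=1.0, B=300, seed=4)
        assert res2.observed_in_clusters == res1.observed_in_clusters
        assert res2.n_positive == res1.n_positive
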