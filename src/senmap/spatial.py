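"""Monte-Carlo test for spatial clustering of positive spots on a hex grid.

Visium arrays pack spots hexagonally; with array coordinates embedded as
x = col/2, y = row * sqrt(3)/2 every spot's six neighbors sit at Euclidean
distance exactly 1, so "minimum point distance of 1" is the adjacency rule.
A positive spot is *in a cluster* when at least one other positive spot is
adjacent.  The null distribution of the in-cluster count is obtained by
repeatedly re-placing the same number of positive labels uniformly at random
over the observed spot positions; the observed count's percentile locates it
in that null (percentile > 0.5 leans clustered, < 0.5 dispersed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy import stats

from .io import SpotGrid

__all__ = [
    "SampleExcludedError",
    "SpatialClusterResult",
    "hex_embed",
    "positive_spots",
    "spots_in_clusters",
    "neighbor_table",
    "null_distribution",
    "cluster_test",
    "run_spatial_test",
]

ADJ_TOL = 1e-6


class SampleExcludedError(ValueError):
    """No spot reaches the positivity threshold; the sample is excluded."""


def hex_embed(g: SpotGrid) -> np.ndarray:
    """Embed array coordinates so hex neighbors are at distance exactly 1."""
    return np.column_stack([g.array_col / 2.0, g.array_row * (np.sqrt(3.0) / 2.0)])


def pixel_coordinates(g: SpotGrid, adj_tol: float = 0.05) -> tuple[np.ndarray, float]:
    """Pixel-space alternative: coordinates plus the adjacency radius.

    For real exports whose units are pixels, adjacency is defined as distance
    up to (1 + adj_tol) times the observed nearest-neighbor distance.
    """
    if g.pixel_x is None or g.pixel_y is None:
        raise ValueError("grid has no pixel coordinates")
    pos = np.column_stack([np.asarray(g.pixel_x), np.asarray(g.pixel_y)])
    tree = cKDTree(pos)
    d, _ = tree.query(pos, k=2)
    nn = float(np.min(d[:, 1]))
    return pos, nn * (1 + adj_tol)


def positive_spots(g: SpotGrid, gene: str, threshold: float) -> np.ndarray:
    """Boolean per spot: expression at/above threshold.

    A strictly positive threshold marks "highly-expressing" spots with >=;
    threshold 0 means plain positivity, strictly > 0.  If no spot qualifies
    the sample is excluded from the spatial test (raises
    :class:`SampleExcludedError`).
    """
    if gene not in g.expr.columns:
        raise KeyError(f"gene {gene!r} not in spot expression table")
    vals = g.expr[gene].to_numpy(dtype=float)
    pos = vals >= threshold if threshold > 0 else vals > 0
    if not pos.any():
        raise SampleExcludedError(
            f"sample {g.sample_id!r}: no spot reaches {gene} threshold {threshold}"
        )
    return pos


def spots_in_clusters(
    positions: np.ndarray, positive: np.ndarray, adj_tol: float = ADJ_TOL, radius: float = 1.0
) -> int:
    """Count positive spots with at least one adjacent positive spot."""
    pos_idx = np.flatnonzero(np.asarray(positive, dtype=bool))
    if pos_idx.size < 2:
        return 0
    pts = np.asarray(positions, dtype=float)[pos_idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius + adj_tol, output_type="ndarray")
    if pairs.size == 0:
        return 0
    return int(np.unique(pairs.ravel()).size)


def neighbor_table(
    positions: np.ndarray, adj_tol: float = ADJ_TOL, radius: float = 1.0
) -> tuple[np.ndarray, int]:
    """Padded neighbor-index table for fast repeated in-cluster counting.

    Returns (table, pad) where table[i] lists the indices adjacent to spot i,
    padded with the sentinel index ``pad`` (== n_spots) up to the maximum
    neighbor count (6 on a full hex lattice).
    """
    pts = np.asarray(positions, dtype=float)
    n = len(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius + adj_tol, output_type="ndarray")
    counts = np.zeros(n, dtype=int)
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    width = max(1, counts.max() if n else 1)
    table = np.full((n, width), n, dtype=np.int64)
    fill = np.zeros(n, dtype=int)
    for a, b in pairs:
        table[a, fill[a]] = b
        fill[a] += 1
        table[b, fill[b]] = a
        fill[b] += 1
    return table, n


def _counts_from_samples(table: np.ndarray, pad: int, samples: np.ndarray) -> np.ndarray:
    """In-cluster counts for many positive-label placements at once.

    ``samples`` is (B, n_positive) spot indices; returns length-B counts.
    """
    B = samples.shape[0]
    mask = np.zeros((B, pad + 1), dtype=bool)
    mask[np.arange(B)[:, None], samples] = True
    mask[:, pad] = False  # sentinel never positive
    nb = table[samples]  # (B, n_positive, width)
    has_pos_neighbor = mask[np.arange(B)[:, None, None], nb].any(axis=2)
    return has_pos_neighbor.sum(axis=1)


def null_distribution(
    positions: np.ndarray,
    n_positive: int,
    B: int = 10_000,
    seed: int = 0,
    adj_tol: float = ADJ_TOL,
    radius: float = 1.0,
) -> np.ndarray:
    """Null in-cluster counts under uniform random placement of positives.

    Each of the B draws places ``n_positive`` labels uniformly without
    replacement over the observed spot positions and records the in-cluster
    count, conditioning the null on the exact tissue geometry (edges and
    holes included).
    """
    n = len(positions)
    if n_positive > n:
        raise ValueError(f"n_positive={n_positive} exceeds n_spots={n}")
    if B < 1:
        raise ValueError("B must be >= 1")
    if n_positive < 2:
        return np.zeros(B, dtype=np.int64)
    rng = np.random.default_rng(seed)
    table, pad = neighbor_table(positions, adj_tol=adj_tol, radius=radius)
    if n_positive == n:
        samples = np.tile(np.arange(n), (B, 1))
    elif B * n <= 50_000_000:
        # vectorized without-replacement draws: top-k of random keys per row
        keys = rng.random((B, n))
        samples = np.argpartition(keys, n_positive, axis=1)[:, :n_positive]
    else:
        samples = np.empty((B, n_positive), dtype=np.int64)
        for b in range(B):
            samples[b] = rng.choice(n, size=n_positive, replace=False)
    # chunk to bound the (B, n_positive, width) working set
    out = np.empty(B, dtype=np.int64)
    step = max(1, int(2e6 // max(1, n_positive * table.shape[1])))
    for start in range(0, B, step):
        out[start : start + step] = _counts_from_samples(
            table, pad, samples[start : start + step]
        )
    return out


@dataclass
class SpatialClusterResult:
    """Observed in-cluster statistics against the Monte-Carlo null."""

    sample_id: str
    gene: str
    threshold: float
    n_spots: int
    n_positive: int
    observed_in_clusters: int
    null_draws: np.ndarray = field(repr=False)
    percentile: float = 0.0
    p_wilcoxon: float = 1.0
    p_empirical: float = 1.0
    call: str = "ns"

    @property
    def proportion_in_clusters(self) -> float:
        return self.observed_in_clusters / self.n_positive if self.n_positive else 0.0


def cluster_test(
    observed: int,
    null_draws: np.ndarray,
    alpha: float = 0.05,
    sample_id: str = "sample",
    gene: str = "",
    threshold: float = float("nan"),
    n_spots: int = 0,
    n_positive: int = 0,
) -> SpatialClusterResult:
    """Locate the observed in-cluster count within the Monte-Carlo null.

    The percentile uses mid-rank tie handling: (#draws below + half the
    draws equal) / B.  Two p-values are reported: a one-sided one-sample
    signed-rank test of the null draws against the observed count (in the
    direction the percentile indicates), and the recommended empirical
    Monte-Carlo p, (r + 1)/(B + 1) with r the number of draws at least as
    extreme in that direction.  The call is cluster/disperse only when the
    percentile leaves 0.5 on the right side and the empirical p clears alpha.
    """
    draws = np.asarray(null_draws)
    if draws.size == 0:
        raise ValueError("null_draws is empty")
    B = draws.size
    below = int((draws < observed).sum())
    equal = int((draws == observed).sum())
    at_least = int((draws >= observed).sum())
    at_most = int((draws <= observed).sum())
    percentile = (below + 0.5 * equal) / B

    p_emp_cluster = (at_least + 1) / (B + 1)
    p_emp_disperse = (at_most + 1) / (B + 1)

    diffs = draws.astype(float) - observed
    if np.all(diffs == 0):
        p_wilcoxon = 1.0
    else:
        alternative = "less" if percentile > 0.5 else ("greater" if percentile < 0.5 else "two-sided")
        try:
            p_wilcoxon = float(
                stats.wilcoxon(diffs, alternative=alternative, zero_method="wilcox").pvalue
            )
        except ValueError:  # all differences zero after zero-dropping
            p_wilcoxon = 1.0

    if percentile > 0.5 and p_emp_cluster <= alpha:
        call = "cluster"
    elif percentile < 0.5 and p_emp_disperse <= alpha:
        call = "disperse"
    else:
        call = "ns"

    return SpatialClusterResult(
        sample_id=sample_id,
        gene=gene,
        threshold=threshold,
        n_spots=n_spots,
        n_positive=n_positive,
        observed_in_clusters=int(observed),
        null_draws=draws,
        percentile=percentile,
        p_wilcoxon=p_wilcoxon,
        p_empirical=p_emp_cluster,
        call=call,
    )


def run_spatial_test(
    g: SpotGrid,
    gene: str,
    threshold: float = 1.0,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    use_pixels: bool = False,
    adj_tol: float = ADJ_TOL,
) -> SpatialClusterResult:
    """Full per-sample spatial clustering test for one gene and threshold."""
    if use_pixels:
        positions, radius = pixel_coordinates(g)
    else:
        positions, radius = hex_embed(g), 1.0
    positive = positive_spots(g, gene, threshold)
    observed = spots_in_clusters(positions, positive, adj_tol=adj_tol, radius=radius)
    draws = null_distribution(
        positions, int(positive.sum()), B=B, seed=seed, adj_tol=adj_tol, radius=radius
    )
    return cluster_test(
        observed,
        draws,
        alpha=alpha,
        sample_id=g.sample_id,
        gene=gene,
        threshold=threshold,
        n_spots=g.n_spots,
        n_positive=int(positive.sum()),
    )
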