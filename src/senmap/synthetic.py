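"""Synthetic single-cell and spatial data with planted ground truth.

The single-cell generator draws negative-binomial counts with log-normal
library sizes and plants a senescent subpopulation: a raised senescence
marker (so log-normalized expression clears the positivity threshold),
coherent shifts on a signed gene set (+delta on up genes, -delta on down
genes, applied as mean multipliers), and suppressed S/G2M marker genes so
the cells land in G1.  A configurable fraction of the remaining cells gets
elevated S or G2M means so phase assignment is exercised.

The spatial generator lays out a parity-correct hex lattice and places
positive spots completely at random (csr), by neighbor contagion
(clustered), or with an inhibition radius (dispersed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, SignedGeneSet, SpotGrid
from .gating import load_cell_cycle_genes

__all__ = [
    "SimConfig",
    "SpatialSimConfig",
    "simulate_sc",
    "simulate_spatial",
    "make_geneset_fixture",
    "senskin_fixture_path",
]


def senskin_fixture_path() -> Path:
    """Path of the shipped synthetic stand-in for the curated skin
    senescence panel (164 up-annotated genes plus LMNB1 down)."""
    return Path(str(resources.files("senmap") / "data" / "senskin_synthetic.tsv"))


@dataclass
class SimConfig:
    """Single-cell simulation parameters.

    ``effect_lognorm`` is the planted shift delta on the log-normalized
    scale, applied as a mean multiplier exp(+delta) to up genes and
    exp(-delta) to down genes of the senescent cells.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    n_celltypes: int = 3
    senescent_frac: float = 0.1
    effect_lognorm: float = 2.0
    nb_dispersion: float = 0.2
    libsize_mu: float = 8.52  # ln-scale; exp(mu) ~ 5000 UMIs
    libsize_sigma: float = 0.3
    cycling_frac: float = 0.4  # non-senescent cells given an S or G2M program
    marker_mean_senescent: float = 10.0  # expected marker count in senescent cells
    marker_mean_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.senescent_frac <= 1:
            raise ValueError("senescent_frac must be in [0, 1]")
        if self.effect_lognorm < 0:
            raise ValueError("effect_lognorm must be >= 0")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.cycling_frac <= 1:
            raise ValueError("cycling_frac must be in [0, 1]")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draws: NB with Var = m + dispersion * m^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_sc(
    config: SimConfig,
    geneset: SignedGeneSet,
    marker: str = "CDKN1A",
    cc_genes: tuple[list[str], list[str]] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate counts with a planted senescent subpopulation.

    Returns the count matrix (gene namespace: marker, gene-set symbols,
    cell-cycle markers, then filler genes) and a truth table per cell with
    columns cell_type, cycling, senescent.
    """
    rng = np.random.default_rng(config.seed)
    s_genes, g2m_genes = cc_genes if cc_genes is not None else load_cell_cycle_genes()

    named = [marker] + [g for g, _ in geneset.entries if g != marker]
    named += [g for g in s_genes + g2m_genes if g not in set(named)]
    if len(named) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {len(named)} named genes"
        )
    gene_ids = named + [f"G{i:05d}" for i in range(config.n_genes - len(named))]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # relative expression rates; named genes get controlled baselines
    rel = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
    rel /= rel.sum()
    libsize = rng.lognormal(config.libsize_mu, config.libsize_sigma, size=config.n_cells)
    mean_lib = float(np.exp(config.libsize_mu + config.libsize_sigma**2 / 2))
    rel[gene_pos[marker]] = config.marker_mean_background / mean_lib
    for g in s_genes + g2m_genes:
        rel[gene_pos[g]] = 1.0 / mean_lib  # ~1 count baseline
    set_rows_up = [gene_pos[g] for g in geneset.up_genes if g in gene_pos]
    set_rows_down = [gene_pos[g] for g in geneset.down_genes if g in gene_pos]
    for r in set_rows_up + set_rows_down:
        if gene_ids[r] != marker:
            rel[r] = rng.uniform(0.5, 2.0) / mean_lib  # moderate, z-scorable

    # cell assignments
    n = config.n_cells
    cell_type = rng.integers(config.n_celltypes, size=n)
    senescent = np.zeros(n, dtype=bool)
    n_sen = int(round(config.senescent_frac * n))
    if n_sen:
        senescent[rng.choice(n, size=n_sen, replace=False)] = True
    cycling = np.full(n, "none", dtype=object)
    candidates = np.flatnonzero(~senescent)
    n_cyc = int(round(config.cycling_frac * candidates.size))
    if n_cyc:
        chosen = rng.choice(candidates, size=n_cyc, replace=False)
        cycling[chosen] = rng.choice(["S", "G2M"], size=n_cyc)

    # per-cell mean matrix: libsize * normalized weights
    mult = np.ones((config.n_genes, n))
    for t in range(config.n_celltypes):
        marked = rng.random(config.n_genes) < 0.1  # mild cell-type signature
        mult[np.ix_(marked, cell_type == t)] *= 2.0
    sen = senescent
    if sen.any():
        mult[gene_pos[marker], sen] = (
            config.marker_mean_senescent / config.marker_mean_background
        )
        delta = config.effect_lognorm
        for r in set_rows_up:
            if gene_ids[r] != marker:
                mult[r, sen] *= np.exp(delta)
        for r in set_rows_down:
            mult[r, sen] *= np.exp(-delta)
        for g in s_genes + g2m_genes:
            mult[gene_pos[g], sen] *= 0.02  # non-replicating
    for state, genes in (("S", s_genes), ("G2M", g2m_genes)):
        cells = cycling == state
        if cells.any():
            rows = [gene_pos[g] for g in genes]
            mult[np.ix_(rows, cells)] *= 8.0

    # rates are per unit library size; no per-cell renormalization, so the
    # planted means (marker boost, +/-delta shifts, cc suppression) are exact
    mean = rel[:, None] * mult * libsize[None, :]
    counts = _nb_counts(rng, mean, config.nb_dispersion)

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "cell_type": pd.Categorical([f"type{t}" for t in cell_type]),
            "cycling": cycling,
            "senescent": senescent,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=sp.csr_matrix(counts),
        meta=truth.copy(),
    )
    return matrix, truth


@dataclass
class SpatialSimConfig:
    """Hex-lattice spot simulation parameters.

    The lattice takes every (row, col) with row < n_rows, col < n_cols and
    row + col even (Visium parity), keeps a random ``tissue_frac`` of
    positions as tissue, and places ``n_positive`` positive spots by regime.
    """

    n_rows: int = 30
    n_cols: int = 60
    tissue_frac: float = 1.0
    n_positive: int = 40
    regime: str = "csr"
    contagion: float = 0.8
    inhibition_radius: float = 2.0
    gene: str = "CDKN1A"
    threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("csr", "clustered", "dispersed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 < self.tissue_frac <= 1:
            raise ValueError("tissue_frac must be in (0, 1]")
        if not 0 <= self.contagion <= 1:
            raise ValueError("contagion must be in [0, 1]")
        n_tissue = int(round(self.tissue_frac * ((self.n_rows * self.n_cols + 1) // 2)))
        if self.n_positive > n_tissue:
            raise ValueError("n_positive exceeds the number of tissue spots")


def _hex_xy(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return np.column_stack([cols / 2.0, rows * (np.sqrt(3.0) / 2.0)])


def simulate_spatial(config: SpatialSimConfig) -> tuple[SpotGrid, np.ndarray]:
    """Simulate one spatial sample; returns the grid and true positive labels."""
    rng = np.random.default_rng(config.seed)
    rows, cols = np.meshgrid(
        np.arange(config.n_rows), np.arange(config.n_cols), indexing="ij"
    )
    keep = (rows + cols) % 2 == 0
    rows, cols = rows[keep], cols[keep]
    n_lattice = rows.size
    n_tissue = int(round(config.tissue_frac * n_lattice))
    tissue = np.sort(rng.choice(n_lattice, size=n_tissue, replace=False))
    rows, cols = rows[tissue], cols[tissue]
    xy = _hex_xy(rows, cols)

    # adjacency among tissue spots (distance exactly 1 in the hex embedding)
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    neighbor_sets: list[set[int]] = [set() for _ in range(n_tissue)]
    for a, b in tree.query_pairs(r=1.0 + 1e-6):
        neighbor_sets[a].add(b)
        neighbor_sets[b].add(a)

    positive = np.zeros(n_tissue, dtype=bool)
    k = config.n_positive
    if config.regime == "csr":
        positive[rng.choice(n_tissue, size=k, replace=False)] = True
    elif config.regime == "clustered":
        if k:
            positive[rng.integers(n_tissue)] = True
        while positive.sum() < k:
            frontier = sorted(
                {nb for i in np.flatnonzero(positive) for nb in neighbor_sets[i]}
                - set(np.flatnonzero(positive).tolist())
            )
            if frontier and rng.random() < config.contagion:
                positive[frontier[rng.integers(len(frontier))]] = True
            else:
                empty = np.flatnonzero(~positive)
                positive[empty[rng.integers(empty.size)]] = True
    else:  # dispersed
        order = rng.permutation(n_tissue)
        accepted: list[int] = []
        for cand in order:
            if len(accepted) == k:
                break
            if all(
                np.hypot(*(xy[cand] - xy[a])) >= config.inhibition_radius
                for a in accepted
            ):
                accepted.append(cand)
        if len(accepted) < k:
            warnings.warn(
                f"dispersed placement infeasible at radius {config.inhibition_radius}; "
                f"filling {k - len(accepted)} spot(s) uniformly"
            )
            remaining = np.setdiff1d(np.arange(n_tissue), accepted)
            accepted.extend(
                rng.choice(remaining, size=k - len(accepted), replace=False).tolist()
            )
        positive[accepted] = True

    # normalized expression of the query gene: clears threshold on positives
    expr = np.zeros(n_tissue)
    if config.threshold > 0:
        expr[positive] = config.threshold + rng.exponential(0.5, size=int(positive.sum()))
        expr[~positive] = rng.uniform(0, 0.5 * config.threshold, size=int((~positive).sum()))
    else:
        expr[positive] = rng.exponential(1.0, size=int(positive.sum())) + 1e-3

    spot_ids = [f"spot{r:03d}x{c:03d}" for r, c in zip(rows.tolist(), cols.tolist())]
    grid = SpotGrid(
        spot_ids=spot_ids,
        array_row=rows,
        array_col=cols,
        expr=pd.DataFrame({config.gene: expr}, index=pd.Index(spot_ids, name="spot_id")),
        sample_id=f"sim-{config.regime}-{config.seed}",
    )
    return grid, positive


def make_geneset_fixture(
    n_up: int = 164, n_down: int = 1, namespace: str = "SSK"
) -> SignedGeneSet:
    """Deterministic signed gene set mirroring the curated panel's shape:
    by default 164 up genes and a single down gene named LMNB1."""
    if n_up + n_down < 1:
        raise ValueError("gene set must have at least one entry")
    entries = [(f"{namespace}U{i:03d}", "up") for i in range(n_up)]
    down_names = []
    if n_down >= 1:
        lmnb1_ok = "LMNB1" not in {g for g, _ in entries}
        down_names.append("LMNB1" if lmnb1_ok else f"{namespace}D000")
        down_names += [f"{namespace}D{i:03d}" for i in range(1, n_down)]
    entries += [(g, "down") for g in down_names]
    return SignedGeneSet(name=f"{namespace}-fixture", entries=entries)
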