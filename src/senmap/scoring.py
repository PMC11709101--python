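"""Signed gene-set composite scores.

The composite score of a signed gene set for cell i is

    score_i = (1/m) * sum_j z_ij  -  (1/k) * sum_l z_il

where the first sum runs over the m genes expected up, the second over the
k genes expected down, and z_ij is the gene-wise z-score of cell i's
log-normalized expression (population standard deviation, i.e. divide by n).
Because every gene's z-scores sum to zero over cells, the per-cell composite
averages to zero over the dataset — scores are interpreted relative to the
dataset mean, not as absolute enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignedGeneSet

__all__ = ["DegenerateGeneError", "CompositeResult", "zscore_gene", "composite_score", "score_by_group"]


class DegenerateGeneError(ValueError):
    """A gene with zero variance cannot be z-scored."""


@dataclass
class CompositeResult:
    """Per-cell composite scores plus bookkeeping about the genes used."""

    geneset_name: str
    cell_ids: list[str]
    scores: np.ndarray
    genes_used_up: int
    genes_used_down: int
    dropped_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"geneset": self.geneset_name, "score": self.scores},
            index=pd.Index(self.cell_ids, name="cell_id"),
        )


def zscore_gene(values: np.ndarray) -> np.ndarray:
    """Z-score one gene across cells with the population SD (divide by n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    sd = x.std()  # ddof=0: population SD
    if sd == 0:
        raise DegenerateGeneError("zero variance")
    return (x - x.mean()) / sd


def composite_score(m: ExpressionMatrix, gs: SignedGeneSet) -> CompositeResult:
    """Normalized sum of z-scores of up genes minus that of down genes.

    Genes absent from the matrix or with zero variance are dropped and the
    normalizers m (up) and k (down) recomputed over the genes actually used;
    dropped genes are reported.  If a direction ends up with no usable gene
    its term is zero.
    """
    if m.lognorm is None:
        raise ValueError("composite_score requires the lognorm layer")
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}

    dropped: list[str] = []
    sums = {"up": np.zeros(m.n_cells), "down": np.zeros(m.n_cells)}
    used = {"up": 0, "down": 0}
    for sym, direction in gs.entries:
        row_idx = gene_pos.get(sym)
        if row_idx is None:
            dropped.append(sym)
            continue
        x = np.asarray(m.lognorm[row_idx].todense()).ravel()
        try:
            z = zscore_gene(x)
        except DegenerateGeneError:
            dropped.append(sym)
            continue
        sums[direction] += z
        used[direction] += 1
    if used["up"] + used["down"] == 0:
        raise ValueError(
            f"gene set {gs.name!r}: no usable genes (all absent or zero-variance)"
        )
    score = np.zeros(m.n_cells)
    if used["up"]:
        score += sums["up"] / used["up"]
    if used["down"]:
        score -= sums["down"] / used["down"]
    return CompositeResult(
        geneset_name=gs.name,
        cell_ids=list(m.cell_ids),
        scores=score,
        genes_used_up=used["up"],
        genes_used_down=used["down"],
        dropped_genes=dropped,
    )


_STAR_CUTOFFS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cutoff, stars in _STAR_CUTOFFS:
        if p <= cutoff:
            return stars
    return "ns"


def score_by_group(
    result: CompositeResult, cells: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Summarize composite scores by a cell annotation and test the groups.

    Two groups are compared with an unpaired two-sided Wilcoxon rank-sum
    (Mann-Whitney) test — the groups are independent cells, so the unpaired
    test is the appropriate one; three or more with Kruskal-Wallis.  Returns
    one row per group (n, median, mean) with the shared p-value and
    conventional significance stars.
    """
    if grouping not in cells.columns:
        raise KeyError(f"grouping column {grouping!r} not in cell table")
    scores = result.to_frame().join(cells[[grouping]], how="inner")
    groups = {name: sub["score"].to_numpy() for name, sub in scores.groupby(grouping, observed=True)}
    if any(len(v) == 0 for v in groups.values()) or not groups:
        raise ValueError("every group must be nonempty")
    samples = list(groups.values())
    if len(samples) == 1:
        p = np.nan
    elif len(samples) == 2:
        p = float(stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided").pvalue)
    else:
        flat = np.concatenate(samples)
        if np.all(flat == flat[0]):  # Kruskal-Wallis is undefined when every value ties
            p = 1.0
        else:
            p = float(stats.kruskal(*samples).pvalue)
    rows = []
    for name, vals in groups.items():
        rows.append(
            {
                "group": name,
                "n": len(vals),
                "median": float(np.median(vals)),
                "mean": float(np.mean(vals)),
                "p": p,
                "stars": significance_stars(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(rows)
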