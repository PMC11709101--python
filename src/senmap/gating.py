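"""Senescent-cell gating: marker positivity, cell-cycle scoring, phase calls.

A cell is gated senescent when it is positive for a senescence marker gene
(CDKN1A/p21 or CDKN2A/p16 by default) on the log-normalized scale AND is
non-replicating, i.e. assigned to G1 (which includes G0) by module scoring
of standard S-phase and G2M marker lists.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "load_cell_cycle_genes",
    "marker_positive",
    "module_score",
    "assign_phase",
    "score_cell_cycle",
    "gate_senescent",
]

POSITIVITY_THRESHOLD = 0.5  # log-normalized expression, strict >


def load_cell_cycle_genes(
    s_path: str | Path | None = None, g2m_path: str | Path | None = None
) -> tuple[list[str], list[str]]:
    """Return the shipped S-phase and G2M marker symbol lists.

    Custom plain-text files (one symbol per line) may be supplied to
    override either list.
    """

    def _load(path: str | Path | None, default_name: str) -> list[str]:
        if path is not None:
            text = Path(path).read_text()
        else:
            text = (resources.files("senmap") / "data" / default_name).read_text()
        return [line.strip() for line in text.splitlines() if line.strip()]

    return _load(s_path, "s_phase_genes.txt"), _load(g2m_path, "g2m_genes.txt")


def marker_positive(
    m: ExpressionMatrix, gene: str, threshold: float = POSITIVITY_THRESHOLD
) -> np.ndarray:
    """Boolean per cell: log-normalized expression strictly above threshold."""
    return m.lognorm_row(gene) > threshold


def module_score(
    m: ExpressionMatrix,
    genes: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Average expression of a gene module relative to binned control genes.

    All genes are ranked by dataset-mean log-normalized expression and split
    into ``n_bins`` equal-size bins.  For each module gene present in the
    matrix, ``n_ctrl`` control genes are drawn without replacement from its
    bin (the whole bin when it is smaller).  The score per cell is the mean
    over module genes minus the mean over the pooled control draws, so a
    module that looks like background scores near zero.
    """
    if m.lognorm is None:
        raise ValueError("module_score requires the lognorm layer")
    present = [g for g in genes if g in set(m.gene_ids)]
    if not present:
        raise ValueError("none of the module genes are present in the matrix")

    dense = np.asarray(m.lognorm.todense())
    gene_means = dense.mean(axis=1)
    order = np.argsort(gene_means, kind="stable")
    # equal-size bins by rank; remainders spread over the leading bins
    bin_of = np.empty(m.n_genes, dtype=int)
    bin_of[order] = np.arange(m.n_genes) * n_bins // m.n_genes

    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(m.gene_ids)}
    set_rows = np.array(sorted(idx[g] for g in present))  # order-independent draws
    ctrl_rows: list[np.ndarray] = []
    for r in set_rows:
        pool = np.flatnonzero(bin_of == bin_of[r])
        take = min(n_ctrl, pool.size)
        ctrl_rows.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.concatenate(ctrl_rows)
    return dense[set_rows].mean(axis=0) - dense[ctrl].mean(axis=0)


def assign_phase(s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """Map (S, G2M) module scores to phase labels.

    Both scores non-positive means the cell shows neither replication
    program: G1 (which includes G0).  Otherwise the larger score wins; an
    exact positive tie falls back to G1, the conservative non-replicating
    call for a senescence pipeline.
    """
    s = np.atleast_1d(np.asarray(s_score, dtype=float))
    g = np.atleast_1d(np.asarray(g2m_score, dtype=float))
    if not (np.isfinite(s).all() and np.isfinite(g).all()):
        raise ValueError("cell-cycle scores must be finite")
    phase = np.where(s > g, "S", "G2M")
    phase = np.where((np.maximum(s, g) <= 0) | (s == g), "G1", phase)
    if np.isscalar(s_score) and np.isscalar(g2m_score):
        return phase[0]
    return phase


def score_cell_cycle(
    m: ExpressionMatrix,
    s_genes: Sequence[str] | None = None,
    g2m_genes: Sequence[str] | None = None,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute S/G2M module scores and phase for every cell."""
    if s_genes is None or g2m_genes is None:
        s_default, g2m_default = load_cell_cycle_genes()
        s_genes = s_genes or s_default
        g2m_genes = g2m_genes or g2m_default
    s = module_score(m, s_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g = module_score(m, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    return pd.DataFrame(
        {"s_score": s, "g2m_score": g, "phase": assign_phase(s, g)},
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def gate_senescent(cells: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Set the senescent flag: marker-positive AND non-replicating (G1).

    ``cells`` must carry a ``<gene>_pos`` boolean column and a ``phase``
    column; all other columns pass through unchanged.
    """
    pos_col = f"{gene}_pos"
    if pos_col not in cells.columns:
        raise KeyError(f"marker {gene!r} not scored: column {pos_col!r} missing")
    if "phase" not in cells.columns:
        raise KeyError("phase column missing; run cell-cycle scoring first")
    out = cells.copy()
    out["senescent"] = out[pos_col].to_numpy(dtype=bool) & (
        out["phase"].to_numpy() == "G1"
    )
    return out
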