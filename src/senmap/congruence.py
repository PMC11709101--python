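"""Differential-expression direction calls and congruence statistics.

A target subpopulation (e.g. CDKN1A+ non-replicating cells) is compared to
the remaining cells gene by gene with Wilcoxon rank-sum tests, gated by a
natural-log fold-change cutoff and Bonferroni correction.  Congruence of a
signed gene set is the count of its genes whose called direction matches
their annotated direction; two congruence proportions are compared with a
one-sided exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignedGeneSet

__all__ = ["de_test", "congruence", "compare_congruence", "CongruenceResult"]

FC_CUTOFF = 0.25  # natural-log fold change
ALPHA = 0.05
EXACT_MAX_N = 25  # exact rank-sum path when both groups are at most this size


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact null distribution when both groups are small and the pooled values
    are tie-free; otherwise the normal approximation with tie correction.
    """
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    if tie_free and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def de_test(
    m: ExpressionMatrix,
    in_cells: np.ndarray,
    out_cells: np.ndarray,
    fc_cutoff: float = FC_CUTOFF,
    alpha: float = ALPHA,
    pseudocount: float = 1.0,
    min_pct: float = 0.0,
    bonferroni_n: int | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression of ``in_cells`` versus ``out_cells``.

    Cells are given as boolean masks or integer positions over the cell axis.
    The fold change is computed on de-logged means,

        log_fc = ln((mean(exp(ln_in) - 1) + c) / (mean(exp(ln_out) - 1) + c))

    with pseudocount c.  Genes below the fold-change cutoff (or the optional
    minimum fraction expressing in both groups) are reported ``ns`` with
    p = 1 and are not tested.  The Bonferroni multiplier is the total number
    of genes in the matrix unless overridden.
    """
    if m.lognorm is None:
        raise ValueError("de_test requires the lognorm layer")

    def _as_index(cells: np.ndarray) -> np.ndarray:
        cells = np.asarray(cells)
        return np.flatnonzero(cells) if cells.dtype == bool else cells

    idx_in, idx_out = _as_index(in_cells), _as_index(out_cells)
    if np.intersect1d(idx_in, idx_out).size:
        raise ValueError("in/out cell groups overlap")
    if idx_in.size < 3 or idx_out.size < 3:
        raise ValueError("each group needs at least 3 cells")

    dense = np.asarray(m.lognorm.todense())
    ln_in, ln_out = dense[:, idx_in], dense[:, idx_out]
    mean_in = np.expm1(ln_in).mean(axis=1)
    mean_out = np.expm1(ln_out).mean(axis=1)
    log_fc = np.log((mean_in + pseudocount) / (mean_out + pseudocount))
    pct_in = (ln_in > 0).mean(axis=1)
    pct_out = (ln_out > 0).mean(axis=1)

    n_bonf = bonferroni_n if bonferroni_n is not None else m.n_genes
    testable = np.abs(log_fc) >= fc_cutoff
    if min_pct > 0:
        testable &= (pct_in >= min_pct) | (pct_out >= min_pct)

    p = np.ones(m.n_genes)
    for gi in np.flatnonzero(testable):
        p[gi] = _rank_sum_p(ln_in[gi], ln_out[gi])
    p_bonf = np.minimum(1.0, p * n_bonf)

    direction = np.full(m.n_genes, "ns", dtype=object)
    sig = testable & (p_bonf <= alpha)
    direction[sig & (log_fc > 0)] = "up"
    direction[sig & (log_fc < 0)] = "down"

    return pd.DataFrame(
        {
            "log_fc": log_fc,
            "p": p,
            "p_bonf": p_bonf,
            "direction": direction,
            "pct_in": pct_in,
            "pct_out": pct_out,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )


@dataclass
class CongruenceResult:
    """Direction agreement between a signed gene set and DE calls."""

    geneset: str
    n_total: int
    n_congruent: int
    flags: pd.Series  # per present set gene: congruent or not
    absent_genes: list[str]

    @property
    def proportion(self) -> float:
        return self.n_congruent / self.n_total if self.n_total else 0.0


def congruence(
    de: pd.DataFrame, gs: SignedGeneSet, direction_only: bool = False
) -> CongruenceResult:
    """Count set genes whose DE direction matches their annotation.

    A gene is congruent iff its called direction is not ``ns`` and equals the
    annotated direction; with ``direction_only`` the significance gate is
    ignored and the sign of the fold change alone is compared.  Genes absent
    from the DE table are excluded from numerator and denominator and
    reported separately.
    """
    present = [(g, d) for g, d in gs.entries if g in de.index]
    absent = [g for g, _ in gs.entries if g not in de.index]
    if not present:
        raise ValueError(f"no gene of set {gs.name!r} present in the DE table")
    flags = {}
    for g, annotated in present:
        if direction_only:
            fc = de.loc[g, "log_fc"]
            called = "up" if fc > 0 else ("down" if fc < 0 else "ns")
        else:
            called = de.loc[g, "direction"]
        flags[g] = called == annotated
    series = pd.Series(flags, name="congruent")
    return CongruenceResult(
        geneset=gs.name,
        n_total=len(present),
        n_congruent=int(series.sum()),
        flags=series,
        absent_genes=absent,
    )


def compare_congruence(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "less"
) -> float:
    """One-sided exact binomial comparison of two congruence proportions.

    Tests k2 successes of n2 trials against the null success probability
    k1/n1 by exact tail summation.  ``alternative="less"`` asks whether the
    second proportion is smaller than the first.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError(f"invalid counts k={k}, n={n}")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    p0 = k1 / n1
    return float(stats.binomtest(k2, n2, p0, alternative=alternative).pvalue)
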