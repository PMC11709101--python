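# Methods

This note records the models, conventions, and numerical choices behind
senmap, and what the synthetic-data tests do and do not demonstrate.

## Normalization and QC

Counts are log-normalized per cell as `ln(1 + scale · count / cell_total)`
with `scale = 10,000` by default. The scale factor is a convention (the
value used by the dominant single-cell toolchains) rather than a derived
quantity; it matters because the marker-positivity threshold (0.5) is
applied on this scale, so a different scale requires re-examining the
threshold. Cells with zero total count get all-zero log-normalized values.

Cell QC removes cells expressing **more than 5,000 genes** (doublet proxy)
or with **more than 5% mitochondrial reads** (apoptosis proxy); spot QC
removes spots with **more than 30% mitochondrial reads or fewer than 200
detected genes**. All cutoffs are strict inequalities on the removal side
and configurable. Mitochondrial genes are detected by a case-insensitive
symbol prefix (`MT-` by default). Duplicate gene symbols in references are
tolerated by suffixing (`-1`, `-2`, ...) with a warning rather than
erroring, since public references contain real duplicates.

## Senescent-cell gating

A cell is gated senescent iff marker log-normalized expression is strictly
above 0.5 **and** its cell-cycle phase is G1 (which includes G0):
senescence implies exit from the replication program, so S/G2M cells are
excluded regardless of marker level.

Phase comes from module scores of the standard 43 S-phase and 54 G2M marker
symbols (shipped as plain text, overridable). The module score of a gene
list is the mean log-normalized expression over the list minus the mean
over control genes: all genes are ranked by dataset-mean expression and cut
into 25 equal-size bins, and 100 controls per list gene are drawn without
replacement from the gene's bin (the whole bin when it is smaller), with a
fixed seed. Control draws iterate genes in sorted row order so the score is
exactly invariant to the order of the input gene list.

Phase assignment: both scores ≤ 0 → G1; otherwise the larger score wins;
an exact tie → G1. The tie/negative rule is our choice (the non-replicating
call is the conservative default for a senescence pipeline; positive ties
have essentially zero probability on real data) — it is documented here
because no standard fixes it.

## Composite score

For a signed gene set with m up genes and k down genes,
`score_i = mean_up(z_ij) − mean_down(z_il)` with gene-wise z-scores using
the **population** standard deviation (divide by n, not n−1). Genes absent
from the matrix or with zero variance are dropped and m/k recomputed over
the genes actually used (dropping keeps the "normalized sum" interpretable;
imputing z = 0 would shrink scores toward zero by an arbitrary amount);
dropped genes are reported. Consequences used as test invariants: scores
average to exactly zero over cells; negating all directions negates scores;
adding a constant to one gene's expression leaves scores unchanged.

Z-scores are computed across the full input matrix. When samples come from
different batches this conflates within- and between-sample variation; a
per-sample option is the natural extension but the cross-dataset score is
the primary definition here.

Group comparisons of scores use the unpaired two-sided Wilcoxon rank-sum
test for two groups and Kruskal-Wallis for three or more. The groups being
compared are independent sets of cells, so the *unpaired* rank-sum test is
the correct choice even where paired ("signed-rank") terminology is
sometimes used loosely for such comparisons.

## Differential expression and congruence

DE of a subpopulation versus the rest: fold change on de-logged means,
`log_fc = ln((mean(exp(ln_in)−1)+1) / (mean(exp(ln_out)−1)+1))` (natural
log, pseudocount 1 on both means, matching the dominant toolchain). Genes
with |log_fc| < 0.25 are reported `ns` with p = 1 and are not tested.
Tested genes use the two-sided Wilcoxon rank-sum: the exact null
distribution when both groups have ≤ 25 cells and the pooled values are
tie-free, otherwise the normal approximation with tie correction. The
Bonferroni multiplier is the **total number of genes in the matrix**, not
just the tested genes — again the dominant convention, configurable. No
minimum-fraction-expressing filter is applied by default (available as an
option).

A set gene is congruent when its called direction is non-`ns` and equals
its annotation; genes absent from the matrix are excluded from both
numerator and denominator and reported. Because congruence is gated on
Bonferroni significance, tightening alpha can only reduce the congruent
count (a test invariant). A `direction_only` mode compares only the sign
of the fold change, for workflows where the inputs are already
significance-filtered marker lists.

Two congruence proportions k1/n1 and k2/n2 are compared by a one-sided
exact binomial test of k2 successes in n2 trials under null probability
k1/n1, by exact tail summation (no normal approximation). Degenerate nulls
(k1 = 0 or k1 = n1) return the exact degenerate tail (0 or 1).

## Spatial clustering test

Array coordinates (row, col with row+col even) are embedded as
x = col/2, y = row·√3/2, which makes all six hex-neighbor distances exactly
1 — so "adjacent" is "distance ≤ 1 + tol" with tol = 1e-6. For pixel-space
exports an alternative mode sets the adjacency radius to (1 + 0.05) times
the observed nearest-neighbor distance.

Highly-expressing spots are called at normalized expression ≥ threshold
(1.0 by default); plain positivity (threshold 0) uses strictly > 0. A
sample where no spot reaches threshold is excluded (signalled as a distinct
exception), not scored as zero.

The null conditions on the exact observed spot positions: each of B
(default 10,000) draws re-places the observed number of positive labels
uniformly without replacement and records the in-cluster count. Edge spots
simply have fewer neighbors; no boundary correction is needed because the
null uses the same geometry. The percentile of the observed count uses
mid-rank tie handling — (#draws below + ½·#draws equal)/B — so ties do not
force a cluster/disperse call.

Two p-values are reported. `p_wilcoxon` is a one-sided one-sample
signed-rank test of the null draws against the observed count, in the
direction the percentile indicates; it is kept for comparability with the
published procedure, but testing B simulated draws against one observed
constant makes its p-value scale with B rather than with evidence.
`p_empirical = (r+1)/(B+1)`, with r the number of draws at least as extreme,
is the statistically valid Monte-Carlo p and is what the cluster/disperse
call uses (together with the percentile side). Per-sample p-values are
reported raw; a Benjamini-Hochberg flag is available when many samples are
screened.

## Synthetic data

Single-cell counts are gamma-Poisson (negative binomial, Var = μ + φμ²,
φ = 0.2 by default) with log-normal library sizes (median ≈ 5,000 UMIs) and
log-normal relative gene abundances. Rates are per unit library size with
no per-cell renormalization, so planted effects are exact in expectation:
senescent cells (default 10%) get marker mean raised to ~10 counts
(background 0.05, giving > 95% positivity at threshold 0.5), up/down set
genes multiplied by e^{±δ} (δ = 2 by default), and S/G2M genes suppressed
×0.02; 40% of the remaining cells get an S or G2M program (×8) so phase
assignment is exercised. Cell types add mild signatures (×2 on a random
10% of genes).

What this does **not** emulate: dropout beyond NB sampling, batch effects,
ambient RNA, doublets, or continuous cell-cycle progression. Passing the
recovery tests shows the gate and score behave correctly when their
assumptions hold — marker separation and coherent set shifts — not that
they are robust to those artifacts.

Spatial samples are parity-correct hex lattices (default 30 × 60, i.e. 900
spots) with positives placed uniformly (csr), grown by neighbor contagion
(clustered; with probability = contagion the next positive is a uniformly
chosen empty neighbor of the current positive set, else a uniform empty
spot), or sequentially with an inhibition radius (dispersed; falls back to
uniform filling with a warning when infeasible). Expression of the query
gene is generated directly on the normalized scale (threshold-clearing on
positives), since the spatial stage consumes normalized values.

## Problem sizes and determinism

Default verification sizes: recovery at 2,000 cells × 2,000 genes;
calibration with 500 runs of B = 1,000 null draws on the 900-spot lattice
(rejection rate at α = 0.05 expected in [0.03, 0.07] — the empirical p is
slightly conservative by discreteness); power with 100 clustered runs.
Every random stage takes an explicit seed; the pipeline driver derives
per-stage seeds by hashing (global seed, stage name) so adding or
reordering stages never shifts another stage's stream. Identical config and
seed give byte-identical outputs.

## Known limitations

- Marker positivity is a hard threshold on a noisy quantity; cells near 0.5
  flip with depth. The gate inherits the marker's biology: CDKN1A is also
  induced transiently by stress without senescence.
- The composite score is relative to the dataset mean; it is not comparable
  across datasets without joint normalization.
- The exact rank-sum path requires tie-free data; log-normalized counts tie
  often, so most real calls use the tie-corrected normal approximation.
- The spatial statistic counts spots in clusters; it does not distinguish
  one large cluster from many pairs with the same in-cluster count.
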