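# senmap

Mapping cellular senescence in single-cell and spatial transcriptomics of
human skin (and similar tissues).

Senescent cells are irreversibly cell-cycle-arrested cells that accumulate
with chronological age and with stressors such as UV exposure. In
transcriptomic data they have no single perfect marker, so this package
implements a combined strategy:

- **Gating**: a cell is called senescent when it is positive for a canonical
  marker (CDKN1A/p21 or CDKN2A/p16; log-normalized expression > 0.5) *and*
  non-replicating, i.e. assigned to G1/G0 by module scoring of standard
  S-phase and G2M marker genes.
- **Composite scoring** of a signed senescence gene set (genes annotated
  "up" or "down" in senescent cells). For cell *i* with *m* up genes and
  *k* down genes:

  score_i = (1/m) Σ_j z_ij − (1/k) Σ_l z_il,  z_ij = (x_ij − x̄_j) / σ_j

  where x_ij is log-normalized expression and σ_j is the population
  (divide-by-n) standard deviation of gene *j* across cells. Scores average
  to zero over the dataset by construction.
- **Congruence**: per-gene differential expression of a subpopulation versus
  the rest (Wilcoxon rank-sum, natural-log fold-change cutoff 0.25,
  Bonferroni-corrected α = 0.05); a set gene is *congruent* when its called
  direction matches its annotation. Congruence proportions of two
  subpopulations are compared with a one-sided exact binomial test.
- **Spatial clustering test**: on a Visium-style hexagonal array, embed
  array coordinates as x = col/2, y = row·√3/2 so all six hex neighbors sit
  at distance exactly 1. A positive spot is *in a cluster* when another
  positive spot is adjacent. The observed in-cluster count is compared to a
  Monte-Carlo null (default B = 10,000 uniform re-placements of the same
  number of positive labels over the same spot positions); the percentile
  (> 0.5 leans clustering, < 0.5 dispersal) and an empirical p-value
  (r+1)/(B+1) are reported.

A synthetic-data module generates negative-binomial count matrices with a
planted marker-positive, non-replicating subpopulation carrying coherent
signed-set shifts, and hex-lattice spot samples with random, clustered, or
dispersed positives — so the whole pipeline is testable without any
external dataset.

## Worked example

Simulate 1,000 cells with a 10% planted senescent population (marker
boosted, signed-set genes shifted by δ = 2, cycle genes suppressed), then
gate, score, and evaluate congruence:

```sh
senmap simulate sc --config sc_config.yaml --seed 42 --out-dir sim
senmap gate  --matrix sim/matrix.mtx --genes sim/genes.txt --cells sim/cells.txt \
             --marker CDKN1A --seed 1 --out cells.tsv
senmap score --matrix sim/matrix.mtx --genes sim/genes.txt --cells sim/cells.txt \
             --geneset sim/geneset.tsv --out scores.tsv
senmap congruence --matrix sim/matrix.mtx --genes sim/genes.txt --cells sim/cells.txt \
             --geneset sim/geneset.tsv --cells-table cells.tsv --out congruence.tsv
```

prints

```
105 of 1000 cells gated senescent
scored 1000 cells with 164 up / 1 down genes (0 dropped)
165/165 genes congruent (100%); 0 absent
```

The gate recovers roughly the planted 10% (105 cells: marker-positive G1
cells, including a few background false positives); the signed set used 164
up genes and the single down gene; and every set gene's differential
expression in the gated cells matches its annotated direction.

Spatial test on a simulated 30 × 60 hex sample whose 40 positive spots were
grown by neighbor contagion (strength 0.8), versus one placed completely at
random:

```sh
senmap spatial --positions clustered_sim/positions.csv --expr clustered_sim/spots_expr.tsv \
               --gene CDKN1A --threshold 1.0 -B 10000 --seed 3 --out clustered.tsv
# positions: 38/40 in clusters, percentile 1.000, p_empirical 0.0001 (cluster)

senmap spatial --positions csr_sim/positions.csv --expr csr_sim/spots_expr.tsv \
               --gene CDKN1A --threshold 1.0 -B 10000 --seed 7 --out spatial.tsv
# positions: 6/40 in clusters, percentile 0.207, p_empirical 0.8576 (ns)
```

38 of 40 contagion-grown positives have an adjacent positive — above every
one of the 10,000 null draws — while the uniformly placed positives sit
inside the null.

The same stages are available as library functions (`senmap.gate_senescent`,
`senmap.composite_score`, `senmap.de_test`, `senmap.congruence`,
`senmap.run_spatial_test`, ...), and `senmap run --config run.yaml` executes
the full pipeline from one YAML file with deterministic per-stage seeding.

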