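# Methods

This note documents the statistical models, algorithmic conventions, and
numerical choices implemented in `ppiclust`, and the scope of the synthetic
data generator used for validation.

## 1. Interactome

The reference graph is an undirected, weighted edge list over gene symbols
with confidence scores on a 0–1000 scale. Loading applies, in order: an
optional identifier→symbol map, symbol upper-casing, removal of self-loops,
collapsing of duplicate edges (keeping the maximum confidence), and a
confidence threshold (default ≥ 700, "high confidence"). All path queries
use **unweighted hop distance** (breadth-first search); confidence scores
gate edge inclusion but never weight paths.

## 2. Variant processing

### Low-quality flags

A variant is flagged low-quality if any of: ≥ 3 variants within a ±10 bp
window on the same chromosome (inclusive, counting itself); ≥ 4 alternative
mapping locations; depth `DP < 10`; `QUAL < 30`; quality-by-depth
`QD < 1.5`; strand bias `FS > 200`. A missing metric never fires its rule.

### Pathogenicity filter

A variant passes if **all** hold: `DP ≥ 10`, PolyPhen-2 HDIV ≥ 0.957
(inclusive), SIFT < 0.05, CADD (phred) > 10, population MAF (`ExAC_ALL`)
< 0.05. A missing annotation fails the filter (conservative).

### Association test

Case/control association per variant uses the Cochran–Armitage trend test
in its score form: with allele doses `g_i ∈ {0,1,2}` and phenotype
`y_i ∈ {0,1}`, the statistic is `χ² = (N−1)·r²` where `r` is the Pearson
correlation between dose and phenotype; p-values come from the 1-df
chi-square distribution. Monomorphic variants return `(0, 1)`.

**Stratification adjustment.** Genotypes are mean-imputed per variant,
centered, and scaled by `sqrt(p̂(1−p̂))`; the top `n_pcs` (default 10) left
singular vectors of the resulting matrix are regressed out of every dose
vector *and* of the phenotype, and the trend statistic is recomputed on the
residuals with `χ² = (N−K−1)·r²` to account for the lost degrees of
freedom. `n_pcs = 0` reproduces the unadjusted test exactly.

Calibration is quantified by the genomic-control inflation factor
`λ = median(χ²) / F⁻¹_{χ²₁}(0.5)` (the denominator ≈ 0.4549), which is ≈ 1
for a calibrated test. On confounded two-subpopulation nulls the unadjusted
test is inflated (λ ≫ 1) while the adjusted test holds λ near 1 and
empirical type-I error within [0.03, 0.07] at α = 0.05. Note the *raw*
median chi-square of a calibrated 1-df test is ≈ 0.455, not 1; λ is the
conventional normalization of that median.

### Seed genes

For each sample, variants passing the pathogenicity filter and carried by
that sample (dose ≥ 1) are grouped by gene; each gene takes its minimum
variant p-value, genes are ranked by (p, symbol) — alphabetical
tie-breaking makes the ranking total — and the top K (default 30) become
the sample's seed genes.

## 3. Sample networks

For every unordered pair of a sample's seeds present in the interactome:
hop distance 1 contributes the direct edge; hop distance exactly 2
contributes **all** shared neighbors as imputed nodes, each with both
connecting edges (not a single arbitrary shortest path — this is the
determinism-critical tie rule). Pairs farther apart contribute nothing.
Seeds left without any incident edge are dropped from the node set but
reported, so unconnected seeds cannot inflate similarity.
`max_path_length = 1` restricts to the seed-induced subgraph.

## 4. Similarity, clustering, and branch tests

Similarity between two samples is the Jaccard index of their network node
sets (seeds + imputed); distance is `1 − J`. Samples with empty networks
are excluded and reported. Samples are sorted by identifier before the
matrix is built, making every downstream result invariant to input order.

UPGMA (average linkage) is implemented directly via the Lance–Williams
update; node heights are merge-distance/2, and ties are broken by the
lowest (row-major) index pair so the dendrogram is fully deterministic. The
implementation is validated against an exhaustive average-linkage oracle
(all ≤ 6-leaf matrices) and SciPy's `linkage(..., 'average')` heights.

Each internal branch with `n` members, `k` of the branch's dominant group
(ties counted as case-dominant), is scored with the one-sided
hypergeometric tail `P[X ≥ k]` against the cohort composition
(`scipy.stats.hypergeom.sf`, validated exhaustively against exact binomial
sums for all tables with N ≤ 30). **Significant clusters** are the maximal
branches with `p < α` (default 0.001) and size ≥ `min_size` (default 3)
having no significant ancestor; they are labelled A, B, … by descending
size. Each cluster carries a layered network (union of member networks
with per-node role — seed precedence over imputed — group membership, and
support counts) and **unique genes**: its members' retained-seed union
minus every other cluster's union (the full union if only one cluster is
reported).

## 5. Separation

For gene sets A and B on the interactome, `d_AA` is the mean over genes of
A of the hop distance to the nearest *other* gene of A (self excluded);
`d_AB` is the mean, over genes of A and of B, of the nearest-neighbor
distance to the opposite set, where a gene in both sets contributes 0.
Then `s_AB = d_AB − (d_AA + d_BB)/2`. Genes absent from the interactome
are dropped and counted; unreachable pairs (different components) are
excluded from means and counted. A set with fewer than two retained genes
is degenerate and raises an error; in matrix form failed cells become NaN.
Negative `s` indicates topologically overlapping neighborhoods.

## 6. Synthetic data generator

Scope: the generator exists to validate the pipeline, not to model biology.

- **Interactome** — stochastic block model: `n_nodes` (500) split evenly
  into `n_modules` (10), edge probability `p_within` (0.3) inside and
  `p_between` (0.01) across modules; symbols `G00001…`.
- **Cohort** — `n_cases` (40) + `n_controls` (40); each planted group
  (default: 20 cases) draws `round(f·K)` of its K (30) seeds uniformly from
  its designated module (default f = 25/30) and the rest uniformly from all
  nodes; all other samples draw K seeds uniformly. f = 0 is exactly the
  null.
- **Variant layer** (optional) — per-gene variants with baseline MAFs from
  `baseline_maf_range`; a `damaging_frac` of variants gets annotations that
  pass the pathogenicity filter; planted samples carry damaging variants in
  their module's genes with probability `signal_carrier_p`. Stratified
  nulls use a two-subpopulation Balding–Nichols model (Fst 0.1) with
  confounded group composition (80% of cases vs 20% of controls from
  population 1).
- All stages are reproducible from `rng_seed`; sub-stages derive
  independent streams (`rng_seed`, `+1`, `+2`).

## 7. Numerical and determinism choices

- Hop distances are exact integers; separation arithmetic is double
  precision and matches a brute-force all-pairs-BFS oracle to 1e-12.
- Hypergeometric tails use `scipy.stats.hypergeom.sf` (log-gamma based);
  exhaustive comparison to exact binomial sums shows relative error < 1e-9.
- UPGMA tie-breaking, sample sorting, `sort_keys` JSON, and
  timestamp-free outputs make reruns byte-identical and results invariant
  to sample order.

## 8. Limitations

- Path expansion stops at one intermediary (`max_path_length ≤ 2`); no
  confidence-weighted path scoring.
- The PCA adjustment is a simplified EIGENSTRAT-style residualization, not
  a full mixed-model association method; it assumes stratification is
  captured by the top principal components.
- Branch p-values are not corrected for the number of branches tested by
  default (a Bonferroni option exists); the α = 0.001 threshold is the
  analysis convention, not a family-wise guarantee.
- The hypergeometric branch test conditions on cluster membership derived
  from the same data; p-values are enrichment scores for ranking branches,
  not tests of an independent hypothesis.
- The generator's discrete p-value support means KS-based uniformity
  checks require cohorts of a few hundred samples; this is a property of
  the trend statistic at small N, not an implementation artifact.
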