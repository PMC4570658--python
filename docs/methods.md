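# Methods

This note documents the models and procedures implemented in `devdup`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not establish.

## 1. Pairwise differential expression and the ternary matrix

The pipeline deliberately avoids a count-level DE model.  Expression arrives
as a non-negative gene × sample table (FPKM-like; units are not enforced
beyond non-negativity).  For each ordered sample pair (i, j) — i before j in
file order; n samples give n(n−1)/2 pairs, 45 for the canonical 10-sample
timecourse — the call is

    +1  if log2((x_j + c)/(x_i + c)) ≥ τ
    −1  if log2((x_j + c)/(x_i + c)) ≤ −τ
     0  otherwise,

forced to 0 when both samples sit below `expression_floor`.  Defaults:
pseudocount c = 1, τ = 1 (two-fold), floor = 1.  The sign convention
(+1 = up in the later-listed sample) is arbitrary but stable; reversing the
sample order flips every sign (tested).

When replicate groups are supplied the conditions become the groups and a
Welch t-test on log2(x + c) across replicate columns gates the calls, with
Benjamini–Hochberg control at `fdr_threshold` (default 0.01) applied within
each comparison.  This is a transparent stand-in for the external
overdispersed caller used in genome-scale studies; because everything
downstream consumes only the ternary calls, the caller is a pluggable
boundary and a precomputed ternary matrix can be supplied directly.

**Housekeeping rule.**  Expression ≥ 10 in every sample *and* an all-zero
ternary row.  With τ → ∞ the housekeeping set degenerates to "≥ 10
everywhere" (tested).  Note that without replicates the fold-change caller
cannot separate biological noise from signal: at simulator noise σ = 0.25 a
flat gene has roughly even odds of one spurious two-fold call somewhere in
the 45 comparisons, so the realized housekeeping set is a conservative
subset of the truly flat genes.  At σ = 0 recovery is exact (tested).

**Stage-specificity statistic.**  For a gene set, the per-sample expression
distributions are pooled within each stage group; every pair of stages is
compared with a two-sided Wilcoxon rank-sum test and the *maximum* p over
stage pairs is reported.  The max makes the statistic small only when every
stage differs from every other.  The null is exact — a tie-aware permutation
distribution computed by subset-sum dynamic programming over doubled
midranks — whenever both sides have ≤ 12 values, and a tie-corrected normal
approximation beyond that.  scipy's exact method refuses ties, which is why
the exact null is computed in-house; scipy and brute-force enumeration serve
as oracles in the tests.

**Sample overview.**  Spearman correlation matrix of the samples (constant
samples flagged, correlations reported as missing); PCA of samples on
centred expression restricted to genes positive in all samples (switchable
to "any"); and average-linkage hierarchical clustering on Euclidean
distances between rows of the sample × sample DE-count matrix, exported as
a dendrogram in Newick.  The linkage choice is ours — the clustering these
overviews are modelled on specifies only the distance.

## 2. Biclustering

A bicluster is (G, C, s) — genes, comparisons, and a sign s_c ∈ {−1, +1}
per comparison — with additive score

    score = Σ_{g∈G, c∈C}  a·[x_gc = s_c]  −  b·[x_gc = 0]  −  d·[x_gc = −s_c]

Defaults a = 1, b = 1, d = 2: a contradiction costs twice a missing call.
The scheme is inspired by coherent-submatrix biclustering of discretized
expression data but uses fixed weights instead of likelihood-derived edge
weights, so published full-data bicluster counts are a qualitative
benchmark, not a reproduction target.

The search is deterministic:

1. **Seeds.**  Every gene pair with its set of equal-nonzero comparisons
   (discarded below `min_comparisons`), plus every single gene with its
   nonzero comparison set.  Singleton seeds are required for completeness:
   a matrix in which no two genes agree anywhere can still contain a
   positive-score single-gene bicluster.
2. **Greedy local search.**  Repeatedly apply the single best-scoring
   addition or removal of one gene or one comparison; an added comparison
   takes the majority sign of the current genes (ties → +1).  All state is
   maintained incrementally (per-gene contributions, per-column sign
   counts), so one iteration costs O(n + m).
3. **Plateau escape.**  At a local optimum, each zero-delta addition is
   tried once followed by a fresh descent; the first strict improvement is
   adopted and the loop repeats.  This resolves the common geometry where a
   gene and a comparison only pay off jointly.  With this step the top
   reported bicluster attains the exhaustive-search maximum on all 500
   random matrices up to 6 × 6 in the acceptance suite.
4. **Filters.**  Keep optima with score ≥ θ (default 10) and the size
   floors (5 genes, 3 comparisons); then scan in descending score and drop
   any bicluster whose gene-set Jaccard with an already-kept one exceeds
   `max_overlap_jaccard` (default 0.75).  Surviving biclusters may still
   overlap — developmental modules do.

Tie-breaking everywhere (seed order, equal-delta moves, sign ties) is by
matrix position, making the output a pure function of matrix and config.
Raising θ only ever removes biclusters (tested); output is deterministic.
An optional seed-pruning flag (on by default) skips seeds already contained
in a previously found optimum; it changes runtime, not results, in all
tested regimes, and can be disabled.

The **regulated set** is the union of member genes over all biclusters.

## 3. Orthology classification

Inputs: all-vs-all protein similarity hits (query, subject, e-value,
bitscore) with species tags, a focal species, a designated comparison
species for one-to-one calls, and a panel of species for homolog status.
All stages use hits with e-value strictly below 10⁻³.

1. **Best interspecies hits** per gene, ranked by bitscore (database-size
   independent), ties by smaller e-value then lexicographic subject id.
2. **Inparalogs.**  Gene a is flagged when some within-species hit
   (a → a′) has bitscore strictly greater than a's best interspecies
   bitscore b*(a).  Genes with b*(a) = 0 are never flagged — they cannot
   enter the reciprocal stage anyway.  The definition is directional
   (evaluated from a's side); a symmetric variant (both members must beat
   their own b*) is available as a config switch.  Whether the historical
   procedure compared bitscores or e-values is not recoverable; bitscore is
   used for both ranking and the inparalog comparison for consistency.
3. **One-to-one orthologs.**  (a, b) is accepted iff the best hits are
   mutual and neither a nor b has an inparalog.
4. **Paralog components.**  Undirected graph over focal genes, an edge when
   a hit in either direction passes the threshold; connected components are
   extracted after *removing* the one-to-one genes, so a one-to-one gene
   sitting inside a larger family is still not "multicopy".  Genes absent
   from every hit table are isolated vertices.
5. **Five classes.**  one_to_one; else conserved (any panel hit) vs orphan;
   each split into multicopy (component size > 1) vs singleton.  The five
   counts always partition the focal gene set (fuzz-tested over 100 random
   worlds).

`evaluate_against_curated` scores predicted one-to-one calls against a
manually curated table of comparison-species genes (verdict: has / has no
one-to-one ortholog), reporting the confusion counts, agreement fractions,
and curated genes outside the hit universe as "unassessable".

## 4. Enrichment statistics

One-sided exact hypergeometric tails in both directions (enrichment
P(X ≥ k), depletion P(X ≤ k)), no approximation; enrichment factor
(k/n)/(K/N), undefined when K = 0 or n = 0.  The choice of the
hypergeometric (= one-tailed Fisher) test is ours — the analyses this
mirrors report raw P values without naming the test.  Benjamini–Hochberg is
applied within each analysis batch and raw p is always emitted alongside q.
The universe defaults to all genes with an orthology call.  Contingency
configurations that cannot arise from real sets (k below the forced minimum
n + K − N) are rejected as inconsistencies.  Exactness is verified against
integer-arithmetic tail enumeration for every configuration with N ≤ 60.

## 5. Phylogeny × expression

**Profile coherence.**  All within-family pairwise Spearman correlations,
summarised per family by the median; the background is the correlation of
randomly drawn (seeded) cross-family gene pairs, and the per-family
empirical p is the add-one-corrected fraction of background pairs reaching
the family median.  Families with fewer than two expressed members are
skipped with a notice.

**Lineage-specific clades.**  Maximal clades whose tips are exclusively
focal-species, size ≥ 2 ("maximal": the parent contains a non-focal tip),
matching brute-force enumeration over all internal nodes on random trees.
Unrooted input is rooted at the midpoint of the path between the two most
distant non-focal tips (unit branch lengths where absent); an outgroup
override and a no-reroot switch exist.  The association between clade
membership and the regulated set is the exact overlap test over tree tips —
a formalisation of what is otherwise a visual argument, and documented as
such.  The count of regulated tips with one-to-one calls comes from the
orthology module, not from tree topology.

## 6. The synthetic world

`synthio` simulates what the analysis assumes, not sequence evolution:

- **Families.**  One ancestral gene per family; per lineage, copy number
  1 + Poisson(dup_rate), duplication times uniform in the post-speciation
  interval (serial budding off the trunk).  No post-duplication loss —
  loss is folded into `orphan_fraction`, the probability that a family has
  no detectable non-focal member.
- **Similarity.**  bitscore = S₀·e^(−kt) with t the pair's divergence time,
  optional Gaussian noise on the log score, hits below a detectability
  floor omitted, e-value mapped monotonically from bitscore.  Any strictly
  monotone map suffices for the rank-based orthology rules; with zero noise
  every within-species paralog post-dates speciation and is therefore a
  true inparalog, making the classification exactly recoverable (tested).
- **Expression.**  10 samples in 3 stage groups (early / dauer / late,
  3-2-5).  A regulated family draws one archetype (early-high, dauer-high,
  late-high: 100 vs 2 FPKM-like units) shared by all members with
  independent log-normal noise (σ default 0.25, natural-log scale);
  unregulated families are flat at a family level drawn log-uniformly in
  [20, 200], above the housekeeping floor.  Regulation is sampled at the
  *family* level with a multiplicative odds boost (default 3) for multicopy
  families — the planted duplication/regulation association.

Defaults anchor the world to a real two-nematode system: orphan fraction
0.32, duplication rate 0.4 per lineage (≈ half of focal genes in multigene
families), baseline regulated fraction 0.17.  These were fixed once, before
any acceptance measurement, and are not tuned.

**What a green test does not establish.**  The generator has no read
counts, no library-size or length effects, no within-family expression
divergence (subfunctionalisation), no cross-family sequence similarity, and
no gene loss after duplication.  Recovery results on this world therefore
certify the *procedures* (rules applied correctly, statistics exact), not
genome-scale counts from real data, which additionally depend on external
gene models, proteomes and DE software.

**Known power limit.**  Because regulation is family-level, gene-level
enrichment tests on simulated worlds are family-clustered, and with 500
families the realized multicopy/regulation odds ratio has a log-scale
Monte-Carlo SE near 0.22.  Under the default composition the strict
"significant at p < 0.01 in ≥ 19 of 20 fixed seeds" recovery check fails in
a minority of seeds (the direction, factor > 1, is essentially always
recovered); the corresponding acceptance test is left failing rather than
inflating duplication rates or regulated fractions beyond the documented
world.  The boost = 1 calibration check passes.

## 7. Numerical and degenerate-input conventions

- Expression values are doubles; 6 significant digits on write (round-trip
  tested at that precision).
- Duplicate (query, subject) hits collapse to the best bitscore, then the
  smallest e-value; self-hits are dropped on load.
- Constant samples make Spearman undefined: flagged, reported as missing.
- A stage group with zero samples, an empty universe, a bicluster gene
  outside the matrix, an interspecies hit routed into inparalog detection —
  all raise diagnostic errors rather than degrade silently.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seed and config give byte-identical outputs (tested).
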