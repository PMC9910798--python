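# Methods

This note documents the statistical models, the defaults and why they
were chosen, the operationalizations of steps that are often left
informal, what the synthetic-data generator does and does not emulate,
and the package's known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Evidence scoring

Every evidence row is one (source, raw interactor id, publication id,
PSI-MI method code) tuple. After identifier harmonization and method
regrouping, rows deduplicate on *(gene symbol, publication id, method
group)*: the same finding reported by two aggregator databases counts
once, which prevents source-count inflation of the scores. Per symbol,
PS counts distinct non-missing publication ids and MS distinct
non-missing method groups; a missing publication or an unmappable
method code contributes zero to its score rather than being imputed.
FS = PS + MS, and the interactome keeps strictly FS > `fs_threshold`
(default 2): an interaction seen in one publication with one technique
has FS = 2 and is treated as unreplicated. Symbols are upper-cased
before merging because approved human gene symbols are upper case
while raw exports vary. The seed's own self-interaction evidence is
scored and retained like any other member.

Whether a publication counted in PS must itself carry a mappable
method is deliberately left uncoupled: PS and MS are independent
distinct counts. Coupling them would only lower FS for records that
the FS ≤ 2 filter already polices.

## Expression quality control

Three per-tissue rules with the boundary semantics stated exactly:

- a gene is removed when its zero-count fraction in a tissue is
  **strictly greater** than `max_zero_fraction` (default 0.05); the
  whole row is removed, since a gene unusable in one tissue cannot
  enter cross-tissue comparisons;
- a sample is removed when its mapping rate is **strictly below**
  `min_mapping_rate` (default 0.80);
- outlier samples are flagged from the pairwise Pearson-correlation
  dendrogram (average linkage on 1 − r). Dendrogram-based outlier calls are
  usually made by eye, so the package fixes an explicit rule: the tree
  is cut at the **absolute** dissimilarity 0.5 — i.e. average
  correlation 0.5, far below the similarity of genuine within-tissue
  expression profiles and far above that of an unrelated sample — and
  samples in clusters holding less than 10% of the tissue's samples
  are flagged. Both constants are exposed
  (`max_dissimilarity`, `min_cluster_fraction`). Relative-height cuts
  (a fraction of the root height) were rejected: on a homogeneous
  tissue the root height is itself noise-scale, so any relative cut
  fragments the tree and flags healthy samples. Zero-variance samples
  are flagged directly (correlation undefined).

Finally the matrix is restricted to interactome members with usable
counts in every tissue; members absent from the matrix or exceeding
the zero-fraction rule anywhere are logged with reasons. The run
aborts if the seed itself fails this restriction, since every
downstream quantity is seed-centric.

## Pairwise differential expression

Normalization is the median-of-ratios construction: for genes with
nonzero counts in all samples, the per-sample factor is the median of
count-to-geometric-mean ratios (medians interpolated in log space, the
convention of the reference implementations). When DEA runs on a small
targeted panel — here, the interactome members — size factors should
be supplied from the full post-QC gene universe
(`pairwise_dea(size_factors=...)`, as the pipeline does): a panel
dominated by genuinely tissue-variable genes distorts its own
normalization, and genome-wide factors are the field-standard choice.

The two-group test is a delta-method Wald test on the difference of
log normalized group means. Per gene, dispersion α is the average of
the two within-group method-of-moments estimates
((var − μ·mean(1/s)) / μ²), floored at 1e−8, with no shrinkage across
genes — shrinkage is an internal refinement of specific tools, and
the plain plug-in estimate keeps the test self-contained. The variance of a log
group mean is approximated by (1/n)·(mean(1/s)/μ + α), and the Wald
statistic is referred to a t distribution with n_A + n_B − 2 degrees
of freedom: Monte-Carlo calibration during development showed the
normal reference mildly anti-conservative at n = 20 + 20 with
estimated dispersions, while the t reference centres the type-I error
at the nominal 0.05 (the acceptance script re-measures this at run
time). Groups with zero counts on both sides are flagged untestable
(p = 1, lfc = 0); a half-count continuity guard keeps one-sided zeros
testable. A gene-wise plug-in dispersion and a delta-method variance
are deliberate simplifications; the acceptance surface is calibration
and planted-effect recovery, not byte-identity with any specific tool.

P-values are corrected twice:
Benjamini–Hochberg across genes within each tissue pair (the default
automatic adjustment of standard DE tools), then Bonferroni across the
T(T−1)/2 pairs, significance at final p < 0.05. The second
correction is deliberately conservative: it trades power for a strict
family-wise bound over the whole pair family.

Rank scores: for each significant pair only the higher tissue's score
increments, so `Score^Ex` is bounded by T − 1 and a gene's row sum by
T(T−1)/2. The high-specificity threshold 12 means "higher than 12 of
14 other tissues" only at T = 15; for other T
it rescales as ceil((T−1)·12/14). The Methods-style inclusive form
(≥ 12) is the default; the strict form is a flag.

## Dendrograms and the cut rule

Heatmap-style clustering uses Euclidean distance with complete linkage
(the defaults of the standard heatmap stacks), on
log2(normalized per-tissue mean + 1) for expression and on 2^r for
co-expression; both metric and linkage are arguments. The shared cut
rule scans every horizontal cut at the distinct merge heights and
returns the partition with the most clusters subject to no cluster
being a singleton, ties broken by the lowest qualifying height; with
two leaves the single pair is returned. The implementation goes
through `scipy.cluster.hierarchy.cut_tree`; tests compare it against an
independent union-find enumeration on random trees.

## Co-expression

Correlations are computed on raw read counts (a log1p switch is available on request at call sites by
transforming the matrix first). Per-tissue p-values are Bonferroni
corrected over the interactor count but do not gate any downstream
step by default — tissue extraction thresholds on r only.

The reference null pools correlations between the seed and `n_sets`
(default 1000) random gene sets of interactome-matched size drawn from
the post-QC universe excluding the seed; undefined correlations are
excluded and counted. The comparison with the observed coefficients is
made programmatic by a two-sample KS test plus the median shift, while
density curves on a shared grid are emitted for visual parity with
distribution-overlay figures.

Tissue ranking uses one-way ANOVA followed by Tukey's HSD on the
tissue-grouped coefficients; for each pair with adjusted p < 0.05 the
tissue with the higher mean increments its score. No correction beyond
Tukey's family-wise adjustment is applied.

**Selection of the highest-co-expression cluster.** The no-singletons
cut is intentionally fine-grained, and on data with one homogeneous
high-correlation block it frequently splits that block into several
pure fragments (the behaviour is scale-free in the sample size). Any
naive mean-difference test then separates the fragments "significantly",
because hierarchical clustering has minimized exactly the within-group
variance being tested — a selective-inference trap. The package
therefore: (1) summarizes each interactor by its mean coefficient
across tissues, treating the gene — not the (gene, tissue) cell — as
the independent unit, since one gene's coefficients are correlated;
(2) partitions the clusters into a high and a low stratum by the
optimal two-group split of their mean coefficients (for two clusters
this is simply top vs bottom; ties break toward the smaller top so a
clearly dominant cluster is returned alone); and (3) keeps a t-test as the inferential step — the high stratum is
selected only if its genes beat the remaining genes in a one-sided
Welch test at p < 0.05, otherwise the maximal-mean cluster alone is
returned. With a clean two-level structure this reduces exactly to
"the cluster that beats all others"; under fragmentation it reassembles
the block instead of returning an arbitrary fragment.

## Tissue-specific extraction and enrichment

The combined table is a lossless long-form join of rank scores and
coefficients over identical gene and tissue universes. Extraction
applies rank > 8 **strict** and r ≥ 0.7 **inclusive**; union is the default combination (rank-only and coefficient-only
members are meaningful on their own, which is what a union preserves),
with intersection as an option. Every member records its trigger and every output records the
thresholds used, sufficient to re-run the extraction bit-identically.

Enrichment p-values are the hypergeometric upper tail (identical to
Fisher's one-tailed exact test) against a background of all annotated
genes in the loaded collection (custom backgrounds accepted).
Bonferroni is over the tested terms. The term-size ceilings are ≤ 1500
for general queries and ≤ 80 for tissue-specific ones, both inclusive;
the required-gene filter keeps only terms whose enrichment
intersection contains the seed; memberships tagged as electronically
inferred can be dropped before testing. No parent/child redundancy
collapsing is performed. Semantic grouping is entirely
dictionary-driven input: no default grouping ships, because any such
dictionary is a curation artifact, not a computable object.

## The synthetic-data generator

`SimulationConfig` defaults define the study conditions: 15 tissues
(11 brain-like, of which three form a striatum-like clade and one is
cerebellum-like; 4 periphery-like), 50 samples per tissue (a
scaled-down bulk-atlas design; analyses that specify their own sample
size, such as the null-calibration and fold-recovery checks, are run
at those sizes), 2000 genes (the universe must exceed the 1501
term-size boundary), NB dispersion 0.1, base log-means Normal(log 100,
1).

Counts are negative-binomial with a per-gene, per-tissue log-mean

    base + brain·[brain tissue] + offset(tissue) + DE shift + w·z − w²/2

where per-gene brain effects (sd 0.4) separate brain from periphery,
per-gene tissue offsets (sd 0.25) individualize tissues, the clade
shares one per-gene offset (mean −0.4, sd 0.3, small per-tissue noise)
so it is recoverable as a dendrogram clade while keeping clade rank
scores low, 10 planted genes carry a 4-fold shift in the
cerebellum-like tissue (these genes are brain/periphery-neutral: a
gene planted as *uniquely* high must not also carry a class effect of
comparable size), and the latent factor z ~ N(0,1), shared per sample
by the seed and 20 planted interactors within clade tissues only,
creates the planted co-expression. The −w²/2 term mean-centres the
latent factor so planting co-expression does not plant differential
expression.

The factor weight w has no convenient closed form as a function of the
target Pearson r on the count scale, so it is calibrated empirically:
mean sample correlation over many moderate-size replicates on a weight
grid, monotonized and inverted (single large draws are unusable — the
log-scale factor makes one-draw correlations heavy-tail unstable).
Calibration is per gene against the seed (count noise depends on the
gene's base mean), cached, and driven by a fixed internal RNG so
results do not depend on the caller's seed. Planted co-expressed genes
and the seed have floored base means (log 4.2 and log 5.0): partners
of a well-expressed hub are themselves well-expressed where the
co-expression operates, and this keeps the planted signal clear of the
zero-count filter.

QC pathologies are planted explicitly: 2 samples with mapping rates
drawn in [0.5, 0.79), 3 members with excess zeros in one clade tissue,
2 members absent from the matrix entirely, plus 15 planted evidence
rows with FS ≤ 2, one obsolete and one unreviewed identifier on the
PPI side. The GMT plants one genuinely enriched term (seed + half the
interactome) and terms sitting exactly on the filter boundaries
(sizes 1501 and 81, a significant seed-free term, an electronically
tagged term).

**What the generator does not emulate:** real expression covariance
between genes (beyond the planted factor), batch effects, library-size
gradients confounded with tissue, isoform structure, and the long-tail
ascertainment biases of curated PPI databases. Passing recovery tests
therefore demonstrates that the pipeline's logic is correct and
calibrated under its stated model — not that real-data runs will reach
the same recovery rates.

## Problem sizes

The test suite and acceptance script use: 50-row evidence fixtures for
scoring oracles; 100 random 10-gene × 6-tissue verdict matrices; 200
random trees (≤ 12 leaves) for the cut oracle; one 2000-gene null
simulation at 2 × 20 samples for test calibration; 5 simulation seeds
at 30 samples/tissue for fold recovery and 5 at the default 50 for
co-expression recovery; 50 runs of 800-gene simulations for the
resampling-null calibration; and 10 seeds for the enrichment
boundaries. These sizes give stable rates while keeping a full run in
about a minute.

## Known limitations

- The NB test is a plug-in Wald test: no dispersion shrinkage, no
  outlier refitting. It is calibrated at moderate n but will be
  anti-conservative for very small groups (n < 5) or extreme
  dispersions.
- The no-singletons cut is intrinsically unstable on homogeneous data;
  the stratum-based cluster selection compensates for the
  co-expression use case, but cluster *boundaries* themselves should
  not be over-interpreted.
- Correlations on raw counts are sensitive to sequencing-depth
  variation; depth is not confounded with tissue in the simulator, but
  real analyses may prefer correlating normalized or log counts.
- Multiple Correspondence Analysis of functional-group composition and
  any live database querying are out of scope; family annotations are
  accepted as an input table.
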