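# seednet

Tissue-specific differentiation of a seed-protein interactome from
RNA-seq expression.

Curated protein–protein interaction (PPI) databases describe *whether*
two proteins can interact, but almost never *where*: the underlying
experiments come from cell lines and in-vitro systems with no tissue
dimension. For a hub protein ("seed") whose function is suspected to
vary across tissues — kinases with both neuronal and immune roles are
the classic case — this package reconstructs a quality-controlled
interactome around the seed and then differentiates it into
tissue-specific interactomes using bulk RNA-seq read counts.

It is written for computational biologists who have (a) evidence
exports from PPI aggregators, (b) a tissue-labelled read-count matrix
(GCT or TSV), and (c) optionally a GMT gene-set collection, and who
want the full chain from raw evidence to per-tissue networks and
enrichment, with every threshold explicit and every stochastic step
seeded.

## The method

**Interactome construction.** Evidence rows from several source
databases are harmonized to approved gene symbols (obsolete and
unreviewed identifiers dropped), detection-method codes from the
molecular-interaction ontology (`MI:nnnn`) are regrouped into technique
categories so that methodological synonyms are not double-counted, and
records are merged on the key *(symbol, publication, method group)*.
Each interactor then receives

- PS — the number of distinct reporting publications,
- MS — the number of distinct detection-method groups,
- FS = PS + MS,

and only interactors with FS > 2 (replicated beyond a single
publication-plus-method) are kept.

**Expression QC.** Per tissue: genes with zero counts in more than 5%
of samples are removed; samples with read-mapping rates below 80% are
removed; samples falling outside the main cluster(s) of the pairwise
Pearson-correlation dendrogram are flagged as outliers. The matrix is
finally restricted to interactome members measurable in every tissue.

**Differential-expression rank scores.** Every gene is tested between
every unordered pair of the *T* tissues with a two-group
negative-binomial Wald test on median-of-ratios normalized counts
(gene-wise method-of-moments dispersion). P-values are
Benjamini–Hochberg-adjusted across genes within each pair and then
Bonferroni-corrected across the *T(T−1)/2* pairs. For gene *I* and
tissue *A*, `Score^Ex[I, A]` counts the tissues in which *I* is
significantly lower than in *A* (final p < 0.05); a score of *T−1*
marks a uniquely-high tissue, and scores ≥ 12 (at *T* = 15) define the
high-specificity set. Hierarchical clustering of the log2 normalized
per-tissue means yields tissue and gene dendrograms; the gene
dendrogram is cut to give the largest number of clusters containing no
singletons, and the cluster holding the seed is the seed's expression
cluster.

**Co-expression.** Pearson correlation between the seed and each
interactor is computed per tissue (Bonferroni over interactors) and
compared against a reference null built from 1000 random gene sets of
interactome-matched size. One-way ANOVA with Tukey's HSD over the
per-tissue coefficient distributions gives each tissue an integer
`Score^coex` (number of tissues with significantly lower
coefficients). Interactors are clustered on the cell-wise `2**r`
matrix with the same no-singletons cut, and the highest-co-expression
cluster is selected by one-sided t-tests on the clusters' member
coefficients.

**Tissue-specific interactomes.** Rank scores and coefficients are
joined into one long-form table; a tissue-specific interactome keeps
the genes with rank score > 8 (strict) or correlation ≥ 0.7
(inclusive) for that tissue, recording which threshold triggered each
member. Protein-family subsets (e.g. one GTPase family) can be carved
out of every tissue network.

**Enrichment.** Gene lists are tested against a GMT collection with
Fisher's one-tailed (hypergeometric upper-tail) test, Bonferroni
correction, a term-size ceiling (1500 general / 80 tissue-specific), a
required-gene filter (only terms whose intersection contains the
seed), and optional removal of electronically inferred annotations;
retained terms can be grouped by a user-supplied semantic dictionary.

A first-class simulator (`seednet.simulate`) generates every input
with planted, recoverable structure — planned PS/MS/FS, a planted
tissue clade, planted fold changes, a latent-factor co-expressed set
with calibrated target correlation, sub-threshold mapping rates, and a
planted enriched term — so the whole pipeline is testable end to end
without any downloads.

## Worked example

Recover a planted co-expressed set from simulated counts
(`examples/04_coexpression.py`; all examples run in seconds):

```bash
$ python examples/04_coexpression.py
mean coefficient of the planted set, per clade tissue:
striatum_a    0.810
striatum_b    0.758
striatum_c    0.687

striatum_a: median shift vs reference = 0.165, KS p = 7.18e-08

tissue co-expression rank scores (top 5):
tissue
striatum_a    12
striatum_c    12
striatum_b    12
brain_07       0
blood_like     0

highest-co-expression cluster: 20 members, 20 of 20 planted recovered
```

Twenty of sixty interactors were planted to share a latent factor with
the seed (target r = 0.8) in a three-tissue striatum-like clade. The
per-tissue means sit around the target; the observed coefficient
distribution is shifted well above the random-gene-set reference
(median shift 0.165, Kolmogorov–Smirnov p ≈ 7e−8); the Tukey ranking
puts the three clade tissues on top (each beating 12 of the 14 other
tissues); and the selected highest-co-expression cluster is exactly
the planted set.

The other scripts in `examples/` walk through interactome construction
(`01`), expression QC (`02`), DEA rank scores (`03`), tissue-specific
extraction (`05`), enrichment (`06`) and the orchestrated pipeline with
its manifest (`07`).

The same stages are available from the shell:

```bash
seednet simulate --seed 1 --out inputs/
seednet run-all --config run.yaml --out results/
```

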