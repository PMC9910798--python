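"""Pairwise cross-tissue differential expression and the per-tissue rank score.

For every unordered pair of tissues, every gene is tested with a
two-group negative-binomial Wald test on median-of-ratios normalized
counts (gene-wise method-of-moments dispersion, no shrinkage). P-values
are corrected twice: Benjamini-Hochberg across genes within each tissue
pair, then Bonferroni across the ``T*(T-1)/2`` pairs. For gene *I* and
tissue *A*, the rank score ``Score^Ex[I, A]`` counts the tissues in
which *I* is expressed significantly lower than in *A* (final corrected
p < alpha), so it is bounded by ``T - 1``.

The module also builds the expression heatmap clustering: hierarchical
dendrograms of tissues and of genes on the log2 normalized per-tissue
mean matrix, the no-singletons maximal cut, and extraction of the
cluster containing the seed gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

from .gct import CountMatrix
from .hclust import cut_max_no_singletons, linkage_to_newick

__all__ = [
    "estimate_size_factors",
    "nb_pairwise_test",
    "pairwise_dea",
    "correct_pairwise",
    "rank_scores",
    "high_specificity_set",
    "ExpressionClustering",
    "cluster_expression",
    "seed_cluster",
]

_DISPERSION_FLOOR = 1e-8


def estimate_size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors.

    For each gene expressed in every sample, the per-sample ratio to the
    gene's geometric mean is formed; the factor of a sample is the
    median of those ratios. Columns that are scalar multiples of each
    other get factors in exactly that ratio.
    """
    values = np.asarray(counts, dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; supply a "
            "pseudo-reference (pseudo_reference=True in pairwise_dea)"
        )
    ref = values[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    return np.exp(np.median(ratios, axis=0))


def _group_moments(block: np.ndarray, sf: np.ndarray):
    """Normalized group mean, sample variance and mean inverse size factor."""
    q = block / sf[None, :]
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    c = float(np.mean(1.0 / sf))
    return m, v, c


def nb_pairwise_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test, vectorized over genes.

    Counts are (genes x samples) raw integers; size factors are per
    sample. Dispersion per gene is the average of the two within-group
    method-of-moments estimates ``(var - mu * mean(1/s)) / mu^2``,
    floored at 1e-8. The Wald statistic is the difference of log
    normalized group means over its delta-method standard error,
    referred to a t distribution with ``n_a + n_b - 2`` degrees of
    freedom (the small-sample allowance for the estimated dispersion and
    variance).

    Returns a frame with ``lfc`` (log2, A vs B), ``pvalue`` and an
    ``untestable`` flag (genes with zero counts in both groups:
    lfc 0, p 1).
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]

    m_a, v_a, c_a = _group_moments(counts_a, sf_a)
    m_b, v_b, c_b = _group_moments(counts_b, sf_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (v_a - m_a * c_a) / np.square(m_a)
        alpha_b = (v_b - m_b * c_b) / np.square(m_b)
    stacked = np.stack([alpha_a, alpha_b])
    defined = np.isfinite(stacked)
    alpha = np.where(defined, stacked, 0.0).sum(axis=0) / np.maximum(
        defined.sum(axis=0), 1
    )
    alpha = np.where(defined.any(axis=0), alpha, _DISPERSION_FLOOR)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)

    # half-a-count continuity guard so one-sided zeros stay testable
    eps_a = 0.5 * c_a / n_a
    eps_b = 0.5 * c_b / n_b
    ma = m_a + eps_a
    mb = m_b + eps_b
    lfc = np.log2(ma / mb)

    var_log_a = (1.0 / (ma * n_a)) * c_a + alpha / n_a
    var_log_b = (1.0 / (mb * n_b)) * c_b + alpha / n_b
    se = np.sqrt(var_log_a + var_log_b)
    z = (np.log(ma) - np.log(mb)) / se
    pvalue = 2.0 * stats.t.sf(np.abs(z), df=n_a + n_b - 2)
    pvalue = np.clip(pvalue, np.nextafter(0, 1), 1.0)

    untestable = (m_a == 0) & (m_b == 0)
    lfc = np.where(untestable, 0.0, lfc)
    pvalue = np.where(untestable, 1.0, pvalue)
    return pd.DataFrame({"lfc": lfc, "pvalue": pvalue, "untestable": untestable})


def correct_pairwise(results: pd.DataFrame, n_pairs: int) -> pd.DataFrame:
    """Apply the final Bonferroni across tissue pairs.

    ``results`` must carry a within-pair adjusted column ``padj_pair``;
    the final p is ``min(1, padj_pair * n_pairs)``.
    """
    out = results.copy()
    out["padj_final"] = np.minimum(1.0, out["padj_pair"] * n_pairs)
    return out


def pairwise_dea(
    matrix: CountMatrix,
    alpha: float = 0.05,
    size_factors: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """All-pairs DEA over the tissues of a count matrix.

    Size factors default to a median-of-ratios fit on ``matrix`` itself,
    but should be supplied from the full post-QC gene universe when
    ``matrix`` is a small targeted panel (a panel dominated by genuinely
    tissue-variable genes distorts its own normalization). Within each
    tissue pair, p-values are BH-adjusted across genes; the final
    Bonferroni multiplies by the number of pairs. Returns the long-form
    result table (one row per gene x unordered pair, fold change signed
    A vs B with A < B lexicographically) and the size-factor vector.
    """
    tissues = matrix.tissues
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues for pairwise DEA")
    if size_factors is None:
        sf = estimate_size_factors(matrix.counts)
        sf_by_sample = pd.Series(sf, index=matrix.counts.columns)
    else:
        sf_by_sample = size_factors.loc[matrix.counts.columns].astype(float)
        sf = sf_by_sample.to_numpy()
    pairs = list(combinations(tissues, 2))
    frames = []
    for tissue_a, tissue_b in pairs:
        cols_a = matrix.samples_in(tissue_a)
        cols_b = matrix.samples_in(tissue_b)
        res = nb_pairwise_test(
            matrix.counts[cols_a].to_numpy(),
            matrix.counts[cols_b].to_numpy(),
            sf_by_sample[cols_a].to_numpy(),
            sf_by_sample[cols_b].to_numpy(),
        )
        res.insert(0, "gene", matrix.genes)
        res.insert(1, "tissue_a", tissue_a)
        res.insert(2, "tissue_b", tissue_b)
        res["padj_pair"] = multipletests(res["pvalue"], method="fdr_bh")[1]
        frames.append(res)
    table = pd.concat(frames, ignore_index=True)
    table = correct_pairwise(table, len(pairs))
    table["significant"] = table["padj_final"] < alpha
    return table, sf


def rank_scores(
    dea_table: pd.DataFrame,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene per-tissue rank scores from signed significance verdicts.

    For every significant pair, only the tissue with the higher
    normalized mean increments; non-significant pairs change nothing.
    A pair claiming significance in both directions for one gene is a
    contract violation and raises.
    """
    if tissues is None:
        tissues = sorted(set(dea_table["tissue_a"]) | set(dea_table["tissue_b"]))
    genes = list(dict.fromkeys(dea_table["gene"]))
    scores = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=tissues)
    sig = dea_table[dea_table["significant"]]
    dup = sig.duplicated(subset=["gene", "tissue_a", "tissue_b"], keep=False)
    if dup.any():
        raise ValueError("inconsistent verdicts: duplicated significant pairs")
    zero_lfc = sig["lfc"] == 0
    if zero_lfc.any():
        raise ValueError("significant pair with undirected (zero) fold change")
    for row in sig.itertuples():
        winner = row.tissue_a if row.lfc > 0 else row.tissue_b
        scores.loc[row.gene, winner] += 1
    return scores


def high_specificity_set(
    rank_matrix: pd.DataFrame,
    min_score: int = 12,
    strict: bool = False,
) -> dict[str, list[str]]:
    """Per-tissue lists of genes with uniquely high expression.

    The default threshold of 12 carries its intended meaning ("higher
    than 12 of 14 other tissues") at T = 15; for other tissue counts it
    is rescaled as ``ceil((T - 1) * 12 / 14)``. ``strict`` switches the
    comparison from >= to >.
    """
    n_tissues = rank_matrix.shape[1]
    threshold = min_score if n_tissues == 15 else math.ceil((n_tissues - 1) * 12 / 14)
    out: dict[str, list[str]] = {}
    for tissue in rank_matrix.columns:
        column = rank_matrix[tissue]
        hits = column[column > threshold] if strict else column[column >= threshold]
        out[tissue] = sorted(hits.index)
    return out


@dataclass
class ExpressionClustering:
    """Tissue and gene dendrograms of the log2 normalized mean matrix."""

    mean_matrix: pd.DataFrame  # genes x tissues, log2(normalized mean + 1)
    gene_linkage: np.ndarray
    tissue_linkage: np.ndarray | None
    clusters: list[set[str]]
    cut_height: float

    def gene_newick(self) -> str:
        return linkage_to_newick(self.gene_linkage, list(self.mean_matrix.index))

    def tissue_newick(self) -> str | None:
        if self.tissue_linkage is None:
            return None
        return linkage_to_newick(self.tissue_linkage, list(self.mean_matrix.columns))

    def assignments(self) -> pd.Series:
        labels = {}
        for i, cluster in enumerate(
            sorted(self.clusters, key=lambda c: (-len(c), sorted(c)[0])), start=1
        ):
            for gene in cluster:
                labels[gene] = i
        return pd.Series(labels, name="cluster").loc[self.mean_matrix.index]


def normalized_mean_matrix(
    matrix: CountMatrix,
    size_factors: np.ndarray,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(per-tissue mean of size-factor-normalized counts + pseudocount)."""
    normalized = matrix.counts / size_factors[None, :]
    means = {
        tissue: normalized[matrix.samples_in(tissue)].mean(axis=1)
        for tissue in matrix.tissues
    }
    return np.log2(pd.DataFrame(means) + pseudocount)


def cluster_expression(
    mean_matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
) -> ExpressionClustering:
    """Hierarchical clustering of tissues (columns) and genes (rows)."""
    import warnings as _warnings

    gene_Z = linkage(mean_matrix.to_numpy(), method=method, metric=metric)
    if mean_matrix.shape[1] >= 3:
        tissue_Z = linkage(mean_matrix.to_numpy().T, method=method, metric=metric)
    else:
        _warnings.warn("fewer than 3 tissues: tissue dendrogram skipped", stacklevel=2)
        tissue_Z = None
    clusters, height = cut_max_no_singletons(gene_Z, list(mean_matrix.index))
    return ExpressionClustering(mean_matrix, gene_Z, tissue_Z, clusters, height)


def seed_cluster(clusters: list[set[str]], seed_symbol: str) -> set[str]:
    """The gene cluster containing the seed."""
    for cluster in clusters:
        if seed_symbol in cluster:
            return cluster
    raise KeyError(f"seed {seed_symbol!r} absent from clustering input")
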