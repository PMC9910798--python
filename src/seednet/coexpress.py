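"""Seed-interactor co-expression per tissue, with a resampling null.

For each tissue, Pearson correlation is computed between the seed
gene's read counts and each interactor's counts across that tissue's
samples (p-values Bonferroni-corrected over the interactor count). The
strength of the observed correlations is judged against a reference
distribution built from many random gene sets of interactome-matched
size. Tissues are compared by one-way ANOVA followed by Tukey's HSD on
the per-tissue coefficient distributions, giving an integer rank score
per tissue (number of other tissues with significantly lower
coefficients). Finally interactors are clustered on the cell-wise
``2**r`` transformed coefficient matrix and the cluster with the
highest co-expression is selected by pairwise one-sided t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .gct import CountMatrix
from .hclust import cut_max_no_singletons, linkage_to_newick

__all__ = [
    "CoexTable",
    "tissue_coexpression",
    "coexpression_table",
    "ReferenceDistribution",
    "build_reference",
    "compare_to_reference",
    "coex_rank_scores",
    "CoexClustering",
    "cluster_coexpression",
]


def _pearson_vs_seed(block: np.ndarray, seed_row: np.ndarray):
    """Correlate each row of ``block`` with ``seed_row`` (vectorized).

    Returns (r, p, valid); rows with zero variance get r = nan,
    valid = False.
    """
    n = seed_row.size
    seed_centered = seed_row - seed_row.mean()
    seed_ss = float(seed_centered @ seed_centered)
    block_centered = block - block.mean(axis=1, keepdims=True)
    block_ss = np.einsum("ij,ij->i", block_centered, block_centered)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (block_centered @ seed_centered) / np.sqrt(block_ss * seed_ss)
    valid = np.isfinite(r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return np.where(valid, r, np.nan), np.where(valid, p, np.nan), valid


@dataclass
class CoexTable:
    """Interactor x tissue Pearson coefficients with corrected p-values."""

    r: pd.DataFrame
    p_bonferroni: pd.DataFrame
    invalid: pd.DataFrame  # True where r undefined (zero variance)

    @property
    def tissues(self) -> list[str]:
        return list(self.r.columns)

    def write_tsv(self, path) -> None:
        self.r.to_csv(path, sep="\t", index_label="gene")


def tissue_coexpression(
    matrix: CountMatrix,
    seed_symbol: str,
    interactors: list[str],
    tissue: str,
) -> pd.DataFrame:
    """One tissue's column: r, raw p, Bonferroni p per interactor.

    Bonferroni is over the number of interactors tested in the tissue.
    Raises if the seed has zero variance in the tissue (the whole column
    would be undefined).
    """
    block = matrix.tissue_counts(tissue)
    if block.shape[1] < 3:
        raise ValueError(f"tissue {tissue!r} has < 3 samples")
    seed_row = block.loc[seed_symbol].to_numpy(dtype=float)
    if seed_row.std() == 0:
        raise ValueError(f"seed {seed_symbol} has zero variance in {tissue!r}")
    sub = block.loc[interactors].to_numpy(dtype=float)
    r, p, valid = _pearson_vs_seed(sub, seed_row)
    p_bonf = np.minimum(1.0, p * len(interactors))
    return pd.DataFrame(
        {"r": r, "pvalue": p, "p_bonferroni": p_bonf, "valid": valid},
        index=pd.Index(interactors, name="gene"),
    )


def coexpression_table(
    matrix: CountMatrix,
    seed_symbol: str,
    interactors: list[str] | None = None,
) -> CoexTable:
    """Full interactor x tissue coefficient table."""
    if interactors is None:
        interactors = [g for g in matrix.genes if g != seed_symbol]
    columns_r, columns_p, columns_v = {}, {}, {}
    for tissue in matrix.tissues:
        col = tissue_coexpression(matrix, seed_symbol, interactors, tissue)
        columns_r[tissue] = col["r"]
        columns_p[tissue] = col["p_bonferroni"]
        columns_v[tissue] = ~col["valid"]
    return CoexTable(
        pd.DataFrame(columns_r), pd.DataFrame(columns_p), pd.DataFrame(columns_v)
    )


@dataclass
class ReferenceDistribution:
    """Pooled null correlations from random interactome-sized gene sets."""

    per_tissue: dict[str, np.ndarray]
    n_sets: int
    set_size: int
    rng_seed: int
    n_excluded: dict[str, int] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        frame = pd.DataFrame(
            {t: pd.Series(v) for t, v in self.per_tissue.items()}
        )
        frame.to_csv(path, sep="\t", index=False)


def build_reference(
    matrix: CountMatrix,
    seed_symbol: str,
    set_size: int,
    n_sets: int = 1000,
    rng_seed: int = 0,
) -> ReferenceDistribution:
    """Correlations between the seed and random gene sets, per tissue.

    Sets are drawn (without replacement within a set) from all post-QC
    genes excluding the seed; undefined correlations (zero-variance
    genes) are excluded from the pool and counted.
    """
    universe = [g for g in matrix.genes if g != seed_symbol]
    if len(universe) < set_size:
        raise ValueError(
            f"gene universe ({len(universe)}) smaller than set size {set_size}"
        )
    rng = np.random.default_rng(rng_seed)
    draws = np.stack(
        [rng.choice(len(universe), size=set_size, replace=False) for _ in range(n_sets)]
    )
    per_tissue: dict[str, np.ndarray] = {}
    n_excluded: dict[str, int] = {}
    universe_index = pd.Index(universe)
    for tissue in matrix.tissues:
        block = matrix.tissue_counts(tissue)
        seed_row = block.loc[seed_symbol].to_numpy(dtype=float)
        sub = block.loc[universe_index].to_numpy(dtype=float)
        r_all, _, valid = _pearson_vs_seed(sub, seed_row)
        pooled = r_all[draws.ravel()]
        keep = np.isfinite(pooled)
        per_tissue[tissue] = pooled[keep]
        n_excluded[tissue] = int((~keep).sum())
    return ReferenceDistribution(per_tissue, n_sets, set_size, rng_seed, n_excluded)


def compare_to_reference(
    coex_column: np.ndarray | pd.Series,
    reference: np.ndarray,
    grid_size: int = 256,
) -> dict:
    """Programmatic interactome-vs-reference comparison for one tissue.

    Returns the median shift, a two-sample KS statistic and p-value, and
    both density curves evaluated on a shared grid (for visual parity
    with distribution-overlay figures).
    """
    observed = np.asarray(coex_column, dtype=float)
    observed = observed[np.isfinite(observed)]
    reference = np.asarray(reference, dtype=float)
    reference = reference[np.isfinite(reference)]
    if observed.size == 0 or reference.size == 0:
        raise ValueError("both distributions must be non-empty")
    ks = stats.ks_2samp(observed, reference)
    lo = min(observed.min(), reference.min()) - 0.05
    hi = max(observed.max(), reference.max()) + 0.05
    grid = np.linspace(lo, hi, grid_size)

    def density(sample: np.ndarray) -> np.ndarray:
        if np.ptp(sample) == 0:  # degenerate: point mass
            out = np.zeros_like(grid)
            out[np.argmin(np.abs(grid - sample[0]))] = 1.0
            return out
        return stats.gaussian_kde(sample)(grid)

    return {
        "median_shift": float(np.median(observed) - np.median(reference)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "grid": grid,
        "observed_density": density(observed),
        "reference_density": density(reference),
    }


def coex_rank_scores(coex: CoexTable, alpha: float = 0.05) -> pd.Series:
    """Tukey-based per-tissue rank scores of the coefficient distributions.

    One-way ANOVA across tissues followed by Tukey's HSD; for each pair
    with adjusted p < alpha, the tissue with the higher mean coefficient
    increments. Bounded by T - 1.
    """
    tissues = coex.tissues
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues for the coefficient ANOVA")
    long = coex.r.melt(var_name="tissue", value_name="r").dropna()
    if long.groupby("tissue")["r"].count().min() < 2:
        raise ValueError("every tissue needs >= 2 defined coefficients")
    tukey = pairwise_tukeyhsd(long["r"].to_numpy(), long["tissue"].to_numpy(), alpha)
    scores = pd.Series(0, index=pd.Index(tissues, name="tissue"), dtype=int)
    groups = [str(g) for g in tukey.groupsunique]
    from itertools import combinations as _combinations

    for (g1, g2), p_adj, meandiff in zip(
        _combinations(groups, 2), tukey.pvalues, tukey.meandiffs
    ):
        # meandiff is mean(g2) - mean(g1)
        if p_adj < alpha:
            winner = g2 if meandiff > 0 else g1
            scores[winner] += 1
    return scores


@dataclass
class CoexClustering:
    """Dendrograms and clusters of the 2**r transformed coefficient matrix."""

    transformed: pd.DataFrame  # interactors x tissues, 2**r
    interactor_linkage: np.ndarray
    tissue_linkage: np.ndarray | None
    clusters: list[set[str]]
    cut_height: float
    highest_cluster: set[str]
    imputed: list[str] = field(default_factory=list)

    def interactor_newick(self) -> str:
        return linkage_to_newick(
            self.interactor_linkage, list(self.transformed.index)
        )

    def tissue_newick(self) -> str | None:
        if self.tissue_linkage is None:
            return None
        return linkage_to_newick(self.tissue_linkage, list(self.transformed.columns))


def _select_highest_cluster(
    coex_r: pd.DataFrame,
    clusters: list[set[str]],
    alpha: float = 0.05,
) -> set[str]:
    """Members of the statistically highest co-expression cluster(s).

    Each interactor is summarized by its mean coefficient across
    tissues (coefficients of one gene are correlated, so the gene — not
    the cell — is the independent unit). Clusters are split into a high
    and a low stratum by the optimal
    within-variance-minimizing two-group partition of their mean
    coefficients — with two clusters this is simply top vs bottom, and
    a fragmented equally-high block reassembles into one stratum. The
    high stratum is returned if its genes beat the rest in a one-sided
    Welch t-test at p < alpha, else the maximal-mean cluster alone.
    """
    gene_means = coex_r.mean(axis=1, skipna=True)
    pooled = {
        i: gene_means.loc[sorted(c)].to_numpy() for i, c in enumerate(clusters)
    }
    pooled = {i: v[np.isfinite(v)] for i, v in pooled.items()}
    means = {i: v.mean() for i, v in pooled.items()}
    if len(clusters) == 1:
        return set(clusters[0])

    def beats(a: np.ndarray, b: np.ndarray) -> bool:
        if a.size < 2 or b.size < 2:
            return bool(a.mean() > b.mean())
        return bool(
            stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
            < alpha
        )

    # delimit the high stratum by the optimal 1-D two-group split of
    # cluster means (exhaustive over sorted prefixes)
    order = sorted(means, key=means.get, reverse=True)
    best_split, best_ss = None, np.inf
    for k in range(1, len(order)):
        high, low = order[:k], order[k:]

        def wss(group: list[int]) -> float:
            values = np.array([means[i] for i in group])
            return float(np.sum((values - values.mean()) ** 2))

        ss = wss(high) + wss(low)
        if ss < best_ss - 1e-12:
            best_ss, best_split = ss, k
    high = order[:best_split]
    high_values = np.concatenate([pooled[i] for i in high])
    low_values = np.concatenate([pooled[i] for i in order[best_split:]])
    if beats(high_values, low_values):
        return set().union(*(clusters[i] for i in high))
    return set(clusters[order[0]])


def cluster_coexpression(
    coex: CoexTable,
    metric: str = "euclidean",
    method: str = "complete",
    alpha: float = 0.05,
) -> CoexClustering:
    """Cluster interactors and tissues on the 2**r matrix; pick the
    highest-co-expression cluster.

    Missing coefficients (zero-variance genes) are imputed as r = 0 for
    clustering only and reported in ``imputed``.
    """
    r = coex.r.copy()
    imputed = sorted(r.index[r.isna().any(axis=1)])
    r = r.fillna(0.0)
    transformed = np.power(2.0, r)
    values = transformed.to_numpy()
    if np.allclose(values, values.ravel()[0]):
        warnings.warn("all coefficients equal: single cluster", stacklevel=2)
        cluster = set(r.index)
        Z = linkage(values, method=method, metric=metric)
        return CoexClustering(transformed, Z, None, [cluster], 0.0, cluster, imputed)
    interactor_Z = linkage(values, method=method, metric=metric)
    tissue_Z = (
        linkage(values.T, method=method, metric=metric)
        if transformed.shape[1] >= 3
        else None
    )
    clusters, height = cut_max_no_singletons(interactor_Z, list(r.index))
    highest = _select_highest_cluster(coex.r.fillna(0.0), clusters, alpha)
    return CoexClustering(
        transformed, interactor_Z, tissue_Z, clusters, height, highest, imputed
    )
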