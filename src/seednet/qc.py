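"""Per-tissue quality control of the read-count matrix.

Four steps, applied tissue by tissue:

1. drop low-count genes (zero counts in more than 5% of the tissue's
   samples),
2. drop samples with read-mapping rates below 80%,
3. flag outlier samples by pairwise Pearson correlation of read counts
   followed by hierarchical clustering on distance ``1 - r``,
4. restrict the matrix to interactome members with usable expression in
   every tissue.

The outlier rule is an operationalization of a visual dendrogram check:
average linkage on ``1 - r``; the "main cluster(s)" are the largest
clusters jointly holding at least ``main_fraction`` of the samples, and
everything outside them is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .gct import CountMatrix
from .hclust import labels_to_clusters
from .ppi import Interactome

__all__ = [
    "QcReport",
    "filter_low_count_genes",
    "filter_samples_by_mapping_rate",
    "detect_outlier_samples",
    "subset_to_interactome",
    "run_qc",
]


@dataclass
class QcReport:
    """Per-tissue log of dropped genes / samples with reasons."""

    dropped_genes: list[dict] = field(default_factory=list)
    dropped_samples: list[dict] = field(default_factory=list)
    flagged_outliers: list[dict] = field(default_factory=list)
    dropped_members: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, entries in (
            ("gene", self.dropped_genes),
            ("sample", self.dropped_samples),
            ("outlier", self.flagged_outliers),
            ("member", self.dropped_members),
        ):
            for entry in entries:
                rows.append({"kind": kind, **entry})
        return pd.DataFrame(rows, columns=["kind", "id", "tissue", "reason"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_low_count_genes(
    matrix: CountMatrix,
    tissue: str,
    max_zero_fraction: float = 0.05,
    report: QcReport | None = None,
) -> CountMatrix:
    """Drop genes with zero counts in strictly more than the allowed
    fraction of the tissue's samples.

    The whole row is removed: a gene unreliable in one tissue cannot
    enter cross-tissue comparisons anyway.
    """
    block = matrix.tissue_counts(tissue)
    if block.shape[1] < 2:
        raise ValueError(f"tissue {tissue!r} has fewer than 2 samples")
    zero_fraction = (block == 0).mean(axis=1)
    bad = zero_fraction[zero_fraction > max_zero_fraction].index
    if report is not None:
        for gene in bad:
            report.dropped_genes.append(
                {"id": gene, "tissue": tissue,
                 "reason": f"zero in {zero_fraction[gene]:.1%} of samples"}
            )
    keep = [g for g in matrix.genes if g not in set(bad)]
    return matrix.subset_genes(keep)


def filter_samples_by_mapping_rate(
    matrix: CountMatrix,
    min_rate: float = 0.80,
    report: QcReport | None = None,
) -> CountMatrix:
    """Drop samples whose mapping rate is strictly below ``min_rate``."""
    meta = matrix.samples
    if "mapping_rate" not in meta.columns or meta["mapping_rate"].isna().any():
        missing = (
            list(meta.index)
            if "mapping_rate" not in meta.columns
            else list(meta.index[meta["mapping_rate"].isna()])
        )
        raise ValueError(f"mapping_rate missing for samples: {missing[:10]}")
    bad = meta.index[meta["mapping_rate"] < min_rate]
    if report is not None:
        for sample in bad:
            report.dropped_samples.append(
                {"id": sample, "tissue": meta.loc[sample, "tissue"],
                 "reason": f"mapping rate {meta.loc[sample, 'mapping_rate']:.3f} < {min_rate}"}
            )
    return matrix.drop_samples(list(bad))


def detect_outlier_samples(
    matrix: CountMatrix,
    tissue: str,
    max_dissimilarity: float = 0.5,
    min_cluster_fraction: float = 0.10,
    report: QcReport | None = None,
) -> set[str]:
    """Flag samples outside the main cluster(s) of the similarity dendrogram.

    Pairwise Pearson correlation on read counts; average linkage on
    ``1 - r``; the dendrogram is cut at the absolute dissimilarity
    ``max_dissimilarity`` (default 0.5, i.e. average correlation 0.5 —
    well below the within-tissue similarity of expression profiles and
    well above that of an unrelated sample). Samples in clusters
    holding less than ``min_cluster_fraction`` of the tissue's samples
    are flagged. Constant (zero-variance) samples are flagged directly
    since their correlation is undefined. A homogeneous tissue collapses
    into one main cluster and flags nothing.
    """
    block = matrix.tissue_counts(tissue)
    sample_ids = list(block.columns)
    if len(sample_ids) < 3:
        raise ValueError(f"tissue {tissue!r} needs >= 3 samples for outlier detection")
    values = block.to_numpy(dtype=float)
    stds = values.std(axis=0)
    degenerate = {sample_ids[j] for j in np.flatnonzero(stds == 0)}
    usable = [s for s in sample_ids if s not in degenerate]
    flagged = set(degenerate)
    if len(usable) >= 3:
        sub = block[usable].to_numpy(dtype=float)
        corr = np.corrcoef(sub, rowvar=False)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=max_dissimilarity, criterion="distance")
        clusters = labels_to_clusters(labels, usable)
        cutoff = min_cluster_fraction * len(usable)
        for cluster in clusters:
            if len(cluster) < cutoff:
                flagged |= cluster
    if report is not None:
        for sample in sorted(flagged):
            reason = "zero variance" if sample in degenerate else "outside main cluster"
            report.flagged_outliers.append(
                {"id": sample, "tissue": tissue, "reason": reason}
            )
    return flagged


def subset_to_interactome(
    matrix: CountMatrix,
    interactome: Interactome,
    max_zero_fraction: float = 0.05,
    report: QcReport | None = None,
) -> CountMatrix:
    """Restrict to interactome members measurable in all tissues.

    Members absent from the matrix, or with more than the allowed
    fraction of zero counts in at least one tissue, are removed and
    logged. The seed gene must survive, otherwise the run aborts.
    """
    wanted = sorted(interactome.symbols | {interactome.seed_symbol})
    present = [g for g in wanted if g in set(matrix.genes)]
    missing = [g for g in wanted if g not in set(matrix.genes)]
    if report is not None:
        for gene in missing:
            report.dropped_members.append(
                {"id": gene, "tissue": "", "reason": "not found"}
            )
    keep = []
    for gene in present:
        worst = None
        for tissue in matrix.tissues:
            block = matrix.tissue_counts(tissue)
            frac = float((block.loc[gene] == 0).mean())
            if frac > max_zero_fraction:
                worst = (tissue, frac)
                break
        if worst is None:
            keep.append(gene)
        elif report is not None:
            report.dropped_members.append(
                {"id": gene, "tissue": worst[0],
                 "reason": f"zero in {worst[1]:.1%} of samples"}
            )
    if interactome.seed_symbol not in keep:
        raise RuntimeError(
            f"seed gene {interactome.seed_symbol} lacks usable expression data"
        )
    return matrix.subset_genes(keep)


def run_qc(
    matrix: CountMatrix,
    interactome: Interactome | None = None,
    max_zero_fraction: float = 0.05,
    min_mapping_rate: float = 0.80,
    max_dissimilarity: float = 0.5,
    min_cluster_fraction: float = 0.10,
    drop_outliers: bool = True,
) -> tuple[CountMatrix, QcReport]:
    """Run the full QC chain across all tissues."""
    report = QcReport()
    matrix = filter_samples_by_mapping_rate(matrix, min_mapping_rate, report)
    for tissue in matrix.tissues:
        matrix = filter_low_count_genes(matrix, tissue, max_zero_fraction, report)
    if drop_outliers:
        flagged: set[str] = set()
        for tissue in matrix.tissues:
            flagged |= detect_outlier_samples(
                matrix, tissue, max_dissimilarity, min_cluster_fraction, report
            )
        if flagged:
            matrix = matrix.drop_samples(sorted(flagged))
    if interactome is not None:
        matrix = subset_to_interactome(matrix, interactome, max_zero_fraction, report)
    return matrix, report
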