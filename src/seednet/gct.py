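"""Gene x sample read-count container with GCT / TSV text IO.

GCT is the expression-matrix text format used by large expression
compendia: a ``#1.2`` version line, a dimensions line (genes, samples),
then a header with ``Name`` and ``Description`` columns followed by one
column per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "read_gct", "write_gct", "read_sample_meta"]


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with per-sample tissue labels.

    ``counts`` is indexed by gene symbol; ``samples`` is indexed by
    sample id and carries at least a ``tissue`` column, optionally
    ``mapping_rate``. ``descriptions`` holds a secondary gene id per row
    (e.g. a versioned stable id), used for GCT round-trips.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    descriptions: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        if "tissue" not in self.samples.columns:
            raise ValueError("sample metadata must carry a 'tissue' column")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    # -- basic views ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def samples_in(self, tissue: str) -> pd.Index:
        if tissue not in set(self.samples["tissue"]):
            raise KeyError(f"tissue {tissue!r} not present")
        return self.samples.index[self.samples["tissue"] == tissue]

    def tissue_counts(self, tissue: str) -> pd.DataFrame:
        return self.counts[self.samples_in(tissue)]

    # -- subsetting ----------------------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        genes = [g for g in genes if g in self.counts.index]
        desc = self.descriptions.loc[genes] if self.descriptions is not None else None
        return CountMatrix(self.counts.loc[genes], self.samples.copy(), desc)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        cols = [s for s in sample_ids if s in self.counts.columns]
        return CountMatrix(
            self.counts[cols], self.samples.loc[cols].copy(),
            self.descriptions,
        )

    def drop_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return self.subset_samples(keep)

    # -- IO ------------------------------------------------------------
    def write_gct(self, path: str | Path) -> None:
        write_gct(self, path)

    def write_sample_meta(self, path: str | Path) -> None:
        self.samples.to_csv(path, sep="\t", index_label="sample_id")


def write_gct(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    n_genes, n_samples = matrix.counts.shape
    desc = (
        matrix.descriptions
        if matrix.descriptions is not None
        else pd.Series(matrix.counts.index, index=matrix.counts.index)
    )
    with open(path, "w") as handle:
        handle.write("#1.2\n")
        handle.write(f"{n_genes}\t{n_samples}\n")
        header = ["Name", "Description", *matrix.counts.columns]
        handle.write("\t".join(map(str, header)) + "\n")
        body = matrix.counts.copy()
        body.insert(0, "Description", desc.loc[body.index].to_numpy())
        body.to_csv(handle, sep="\t", header=False)


def read_gct(
    path: str | Path,
    samples: pd.DataFrame | None = None,
) -> CountMatrix:
    """Read a GCT file; ``samples`` supplies tissue labels if given.

    Without metadata, every sample is labelled tissue ``'all'``.
    """
    path = Path(path)
    with open(path) as handle:
        version = handle.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"{path}: not a GCT file (first line {version!r})")
        dims = handle.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        table = pd.read_csv(handle, sep="\t")
    if table.shape[0] != n_genes or table.shape[1] - 2 != n_samples:
        raise ValueError(
            f"{path}: dimension line says {n_genes}x{n_samples}, "
            f"body is {table.shape[0]}x{table.shape[1] - 2}"
        )
    counts = table.set_index("Name").drop(columns=["Description"])
    counts.index.name = None
    descriptions = table.set_index("Name")["Description"]
    descriptions.index.name = None
    if samples is None:
        samples = pd.DataFrame({"tissue": "all"}, index=counts.columns)
    return CountMatrix(counts, samples.loc[counts.columns], descriptions)


def read_counts_tsv(path: str | Path, samples: pd.DataFrame) -> CountMatrix:
    """Plain TSV alternative: first column gene id, one column per sample."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(table, samples.loc[table.columns])


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV keyed by sample id (tissue, mapping_rate...)."""
    meta = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"sample_id": str})
    if "mapping_rate" in meta.columns:
        meta["mapping_rate"] = meta["mapping_rate"].astype(float)
    return meta
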