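"""Combine DEA rank scores and co-expression coefficients; extract
tissue-specific interactomes.

The combined table holds, for every retained gene and tissue, the
integer expression rank score and the seed co-expression coefficient
(plus its corrected p-value). A tissue-specific interactome keeps the
genes passing ``rank > rank_min`` (strict) OR ``r >= r_min`` (inclusive)
for that tissue — defaults 8 and 0.7 — and records which threshold
triggered each member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "combine_tables",
    "read_combined_table",
    "TissueInteractome",
    "extract_tissue_interactome",
    "subset_by_family",
]


def combine_tables(
    rank_matrix: pd.DataFrame,
    coex_r: pd.DataFrame,
    coex_p: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Lossless long-form join of rank scores and coefficients.

    Both inputs are gene x tissue; their universes must match exactly
    (mismatches raise, listing the offenders). One row per (gene,
    tissue) pair with columns ``rank_score``, ``r`` and optionally
    ``p_bonferroni``.
    """
    if rank_matrix.index.has_duplicates or coex_r.index.has_duplicates:
        raise ValueError("duplicated gene ids in input matrices")
    gene_mismatch = set(rank_matrix.index) ^ set(coex_r.index)
    tissue_mismatch = set(rank_matrix.columns) ^ set(coex_r.columns)
    if gene_mismatch or tissue_mismatch:
        raise ValueError(
            f"universe mismatch; genes {sorted(gene_mismatch)[:5]} "
            f"tissues {sorted(tissue_mismatch)[:5]}"
        )
    rank_long = rank_matrix.stack(future_stack=True).rename("rank_score")
    r_long = coex_r.loc[rank_matrix.index, rank_matrix.columns].stack(future_stack=True)
    combined = pd.concat([rank_long, r_long.rename("r")], axis=1)
    if coex_p is not None:
        p_long = coex_p.loc[rank_matrix.index, rank_matrix.columns].stack(future_stack=True)
        combined["p_bonferroni"] = p_long
    combined.index.names = ["gene", "tissue"]
    return combined.reset_index()


def read_combined_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class TissueInteractome:
    """Members passing the per-tissue thresholds, with trigger provenance."""

    tissue: str
    members: pd.DataFrame  # gene, rank_score, r, trigger
    rank_min: int
    r_min: float
    mode: str
    n_universe: int = 0

    @property
    def symbols(self) -> set[str]:
        return set(self.members["gene"])

    def trigger_counts(self) -> dict[str, int]:
        return self.members["trigger"].value_counts().to_dict()

    def fraction_of_interactome(self) -> dict[str, float]:
        """Per-trigger member fractions relative to the full gene universe."""
        if not self.n_universe:
            return {}
        rank_n = (self.members["rank_score"] > self.rank_min).sum()
        coef_n = (self.members["r"] >= self.r_min).sum()
        return {
            "rank": rank_n / self.n_universe,
            "coefficient": coef_n / self.n_universe,
            "members": len(self.members) / self.n_universe,
        }

    def provenance(self) -> dict:
        return {
            "tissue": self.tissue,
            "rank_min": self.rank_min,
            "r_min": self.r_min,
            "mode": self.mode,
        }

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            prov = self.provenance()
            handle.write(
                "# " + "\t".join(f"{k}={v}" for k, v in prov.items()) + "\n"
            )
            self.members.to_csv(handle, sep="\t", index=False)

    def to_graph(self, seed_symbol: str) -> nx.Graph:
        """Star graph seed-member with rank/coefficient node attributes."""
        graph = nx.Graph(tissue=self.tissue, **{
            k: str(v) for k, v in self.provenance().items() if k != "tissue"
        })
        graph.add_node(seed_symbol, role="seed")
        for row in self.members.itertuples():
            graph.add_node(
                row.gene,
                rank_score=int(row.rank_score),
                r=float(row.r) if pd.notna(row.r) else 0.0,
                trigger=row.trigger,
            )
            graph.add_edge(seed_symbol, row.gene)
        return graph

    def write_graphml(self, path: str | Path, seed_symbol: str) -> None:
        nx.write_graphml(self.to_graph(seed_symbol), path)


def extract_tissue_interactome(
    combined: pd.DataFrame,
    tissue: str,
    rank_min: int = 8,
    r_min: float = 0.7,
    mode: str = "union",
) -> TissueInteractome:
    """Threshold the combined table for one tissue.

    ``union`` keeps genes with rank_score > rank_min OR r >= r_min;
    ``intersection`` requires both. Each member records its trigger
    (``rank`` / ``coefficient`` / ``both``).
    """
    if tissue not in set(combined["tissue"]):
        raise KeyError(f"tissue {tissue!r} not in combined table")
    if mode not in {"union", "intersection"}:
        raise ValueError(f"unknown mode {mode!r}")
    block = combined[combined["tissue"] == tissue].copy()
    by_rank = block["rank_score"] > rank_min
    by_coef = block["r"].fillna(float("-inf")) >= r_min
    keep = (by_rank | by_coef) if mode == "union" else (by_rank & by_coef)
    members = block[keep].copy()
    trigger = pd.Series("rank", index=members.index)
    trigger[by_coef[keep] & ~by_rank[keep]] = "coefficient"
    trigger[by_coef[keep] & by_rank[keep]] = "both"
    members["trigger"] = trigger
    members = members[["gene", "rank_score", "r", "trigger"]].reset_index(drop=True)
    return TissueInteractome(
        tissue, members, rank_min, r_min, mode, n_universe=len(block)
    )


def subset_by_family(
    tissue_interactomes: dict[str, TissueInteractome],
    family_genes: list[str],
) -> dict[str, TissueInteractome]:
    """Restrict each tissue's interactome to a protein-family gene list.

    Both metrics are preserved on the restricted members so the subsets
    remain exportable for visualization.
    """
    family = {g.upper() for g in family_genes}
    out: dict[str, TissueInteractome] = {}
    for tissue, net in tissue_interactomes.items():
        members = net.members[net.members["gene"].str.upper().isin(family)]
        if members.empty:
            warnings.warn(
                f"family restriction empty for tissue {tissue!r}", stacklevel=2
            )
        out[tissue] = TissueInteractome(
            tissue, members.reset_index(drop=True),
            net.rank_min, net.r_min, net.mode, net.n_universe,
        )
    return out
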