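"""Gene-set overrepresentation with Fisher's one-tailed test.

A query gene list is tested against every term of a GMT collection
with the hypergeometric upper tail (equivalent to Fisher's one-tailed
exact test), Bonferroni-corrected over the tested terms. Filtering
mirrors a specificity-focused workflow: a term-size ceiling (1500 for
general queries, 80 for tissue-specific ones), a required gene that
must appear in the enrichment intersection (so only terms the seed
itself contributes to are kept), and optional removal of memberships
tagged as electronically inferred before testing. Surviving terms can
be grouped into broader semantic classes via a user dictionary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "EnrichmentResult",
    "fisher_enrichment",
    "filter_terms",
    "group_terms",
    "FunctionalGroups",
]


@dataclass
class GeneSetCollection:
    """Terms with member genes; memberships may carry evidence tags.

    ``terms`` maps term id -> set of gene symbols; ``tags`` maps
    (term id, gene) -> evidence tag for tagged memberships. The
    statistical background is the union of all annotated genes.
    """

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    tags: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def background(self) -> set[str]:
        out: set[str] = set()
        for members in self.terms.values():
            out |= members
        return out

    def term_size(self, term_id: str) -> int:
        return len(self.terms[term_id])

    def drop_tagged(self, tag: str) -> "GeneSetCollection":
        """Remove memberships carrying ``tag`` (e.g. electronic annotations)."""
        terms = {
            tid: {g for g in members if self.tags.get((tid, g)) != tag}
            for tid, members in self.terms.items()
        }
        terms = {tid: members for tid, members in terms.items() if members}
        tags = {
            key: value for key, value in self.tags.items()
            if value != tag and key[0] in terms
        }
        return GeneSetCollection(terms, dict(self.names), tags)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term id, description, then member genes).

    A member written as ``SYMBOL|TAG`` carries an evidence tag.
    """
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    tags: dict[tuple[str, str], str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term_id, description, *genes = fields
            members = set()
            for entry in genes:
                if not entry:
                    continue
                if "|" in entry:
                    symbol, tag = entry.split("|", 1)
                    tags[(term_id, symbol.upper())] = tag
                else:
                    symbol = entry
                members.add(symbol.upper())
            terms[term_id] = members
            names[term_id] = description
    return GeneSetCollection(terms, names, tags)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    pvalue: float
    p_bonferroni: float
    term_size: int
    intersection: frozenset[str]


def fisher_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail p per term, Bonferroni over tested terms.

    The background defaults to all annotated genes in the collection;
    query genes outside the background are dropped with a warning.
    """
    if not query:
        raise ValueError("empty query gene list")
    background = set(background) if background is not None else collection.background
    query = {g.upper() for g in query}
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the background dropped",
            stacklevel=2,
        )
        query &= background
    if not query:
        raise ValueError("no query genes inside the background")
    M = len(background)
    N = len(query)
    results = []
    n_terms = len(collection.terms)
    for term_id, members in collection.terms.items():
        members = members & background
        K = len(members)
        overlap = query & members
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=collection.names.get(term_id, term_id),
                pvalue=min(p, 1.0),
                p_bonferroni=min(1.0, p * n_terms),
                term_size=collection.term_size(term_id),
                intersection=frozenset(overlap),
            )
        )
    return sorted(results, key=lambda r: (r.pvalue, r.term_id))


def filter_terms(
    results: list[EnrichmentResult],
    max_term_size: int = 1500,
    require_gene: str | None = None,
    alpha: float | None = 0.05,
) -> list[EnrichmentResult]:
    """Apply the specificity filters.

    Keeps terms with size <= max_term_size whose intersection contains
    ``require_gene`` (when given); ``alpha`` additionally restricts to
    Bonferroni-significant terms (pass None to keep all).
    """
    out = []
    required = require_gene.upper() if require_gene else None
    for result in results:
        if result.term_size > max_term_size:
            continue
        if required is not None and required not in result.intersection:
            continue
        if alpha is not None and result.p_bonferroni >= alpha:
            continue
        out.append(result)
    return out


@dataclass
class FunctionalGroups:
    """Semantic grouping of retained terms with contributing query genes."""

    term_to_group: dict[str, str]
    group_genes: dict[str, set[str]]

    def membership_matrix(self) -> pd.DataFrame:
        """0/1 gene x group matrix of contributions."""
        genes = sorted(set().union(*self.group_genes.values())) if self.group_genes else []
        groups = sorted(self.group_genes)
        data = {
            group: [int(g in self.group_genes[group]) for g in genes]
            for group in groups
        }
        return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def group_terms(
    results: list[EnrichmentResult],
    dictionary: dict[str, str] | None = None,
) -> FunctionalGroups:
    """Group retained terms via a term -> group dictionary.

    Terms without a dictionary entry fall into ``"ungrouped"``. Each
    group's contributing query genes are the union of its terms'
    intersections.
    """
    dictionary = dictionary or {}
    term_to_group: dict[str, str] = {}
    group_genes: dict[str, set[str]] = {}
    for result in results:
        group = dictionary.get(result.term_id, "ungrouped")
        term_to_group[result.term_id] = group
        group_genes.setdefault(group, set()).update(result.intersection)
    return FunctionalGroups(term_to_group, group_genes)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "pvalue": r.pvalue,
                "p_bonferroni": r.p_bonferroni,
                "term_size": r.term_size,
                "intersection": ";".join(sorted(r.intersection)),
            }
            for r in results
        ],
        columns=[
            "term_id", "term_name", "pvalue", "p_bonferroni",
            "term_size", "intersection",
        ],
    )
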