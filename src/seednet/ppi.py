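"""Build a quality-controlled seed-protein interactome from curated PPI evidence.

Evidence rows exported from interaction aggregators (one row per
seed-interactor evidence item) are harmonized to approved gene symbols,
detection methods are regrouped into technique categories via a PSI-MI
grouping dictionary, records are merged across sources with duplicate
removal, and each interactor is scored:

* ``PS`` (publication score): number of distinct reporting publications,
* ``MS`` (method score): number of distinct detection-method groups,
* ``FS`` (final score): ``PS + MS``.

Interactors with ``FS`` at or below a threshold (default 2 — i.e. one
publication and one method, never replicated) are removed, as are
identifiers that are obsolete or map to unreviewed protein entries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "InteractionEvidence",
    "ScoredInteractor",
    "Interactome",
    "parse_evidence_table",
    "load_id_mapping",
    "load_method_dictionary",
    "harmonize_ids",
    "regroup_methods",
    "merge_sources",
    "score_interactors",
    "filter_interactome",
    "source_overlap_tally",
]

_MI_CODE_RE = re.compile(r"^MI:\d{4}$")


@dataclass
class InteractionEvidence:
    """One row of raw interaction evidence for the seed protein."""

    source_db: str
    interactor_raw_id: str
    id_namespace: str = "symbol"
    publication_id: str | None = None
    method_code: str | None = None
    method_label: str | None = None
    gene_symbol: str | None = None
    method_group: str | None = None

    def __post_init__(self) -> None:
        if self.method_code is not None and not _MI_CODE_RE.match(self.method_code):
            raise ValueError(
                f"method_code {self.method_code!r} does not match 'MI:' + 4 digits"
            )


@dataclass(frozen=True)
class ScoredInteractor:
    """Interactor with publication / method / final scores (FS = PS + MS)."""

    gene_symbol: str
    PS: int
    MS: int
    FS: int

    def __post_init__(self) -> None:
        if self.FS != self.PS + self.MS:
            raise ValueError("FS must equal PS + MS")
        if self.PS < 0 or self.MS < 0:
            raise ValueError("scores must be non-negative")


@dataclass
class Interactome:
    """Scored interactors surviving quality control, with provenance."""

    seed_symbol: str
    members: list[ScoredInteractor]
    sources: dict[str, frozenset[str]] = field(default_factory=dict)
    dropped: pd.DataFrame | None = None
    fs_threshold: int = 2

    @property
    def symbols(self) -> set[str]:
        return {m.gene_symbol for m in self.members}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_symbol": m.gene_symbol,
                "PS": m.PS,
                "MS": m.MS,
                "FS": m.FS,
                "sources": ";".join(sorted(self.sources.get(m.gene_symbol, ()))),
            }
            for m in sorted(self.members, key=lambda m: (-m.FS, m.gene_symbol))
        ]
        return pd.DataFrame(rows, columns=["gene_symbol", "PS", "MS", "FS", "sources"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_edge_list(self, path: str | Path) -> None:
        """Weighted seed-interactor edge list (weight = FS)."""
        frame = self.to_frame()
        edges = pd.DataFrame(
            {
                "seed": self.seed_symbol,
                "interactor": frame["gene_symbol"],
                "weight": frame["FS"],
            }
        )
        edges.to_csv(path, sep="\t", index=False)


def parse_evidence_table(
    table_path: str | Path,
    source_label: str,
    column_map: Mapping[str, str] | None = None,
) -> list[InteractionEvidence]:
    """Parse one source's evidence TSV into records.

    ``column_map`` maps logical field names (``interactor_id``,
    ``publication_id``, ``method_code``, ``method_label``, ``namespace``)
    to the column headers of the file. Missing publication / method cells
    are preserved as missing, never imputed.
    """
    path = Path(table_path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {
        "interactor_id": "interactor_id",
        "publication_id": "publication_id",
        "method_code": "method_code",
        "method_label": "method_label",
        "namespace": "namespace",
    }
    if column_map:
        cmap.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if table.empty:
        warnings.warn(f"evidence table {path} is empty", stacklevel=2)
        return []
    if cmap["interactor_id"] not in table.columns:
        raise ValueError(
            f"{path}: missing mandatory column {cmap['interactor_id']!r} "
            f"(found {list(table.columns)})"
        )

    def cell(row: pd.Series, key: str) -> str | None:
        col = cmap[key]
        if col not in table.columns:
            return None
        value = row[col].strip()
        return value or None

    records: list[InteractionEvidence] = []
    for _, row in table.iterrows():
        records.append(
            InteractionEvidence(
                source_db=source_label,
                interactor_raw_id=row[cmap["interactor_id"]].strip(),
                id_namespace=cell(row, "namespace") or "symbol",
                publication_id=cell(row, "publication_id"),
                method_code=cell(row, "method_code"),
                method_label=cell(row, "method_label"),
            )
        )
    return records


def load_id_mapping(path: str | Path) -> pd.DataFrame:
    """Load an ID-mapping TSV: raw_id, namespace, gene_symbol, reviewed, obsolete."""
    mapping = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"raw_id", "gene_symbol"}
    missing = required - set(mapping.columns)
    if missing:
        raise ValueError(f"id mapping {path} lacks columns: {sorted(missing)}")
    if "namespace" not in mapping.columns:
        mapping["namespace"] = "symbol"
    for flag in ("reviewed", "obsolete"):
        if flag not in mapping.columns:
            mapping[flag] = "true" if flag == "reviewed" else "false"
    return mapping


def load_method_dictionary(path: str | Path) -> dict[str, str]:
    """Two-column TSV (method_code, method_group) -> dict."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    code_col, group_col = table.columns[:2]
    return dict(zip(table[code_col].str.strip(), table[group_col].str.strip()))


def _truthy(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "y", "t"}


def harmonize_ids(
    evidence: Iterable[InteractionEvidence],
    mapping: pd.DataFrame,
) -> tuple[list[InteractionEvidence], pd.DataFrame]:
    """Attach approved gene symbols; drop obsolete / unreviewed / unmapped IDs.

    Returns the harmonized evidence and a dropped-record log with a
    ``reason`` column (``obsolete``, ``unreviewed``, ``unmapped``).
    Symbols are upper-cased so evidence for raw IDs mapping to the same
    symbol pools under one key.
    """
    lut: dict[tuple[str, str], pd.Series] = {}
    for _, row in mapping.iterrows():
        lut[(row["namespace"].strip(), row["raw_id"].strip())] = row
    kept: list[InteractionEvidence] = []
    dropped_rows: list[dict] = []
    for record in evidence:
        entry = lut.get((record.id_namespace, record.interactor_raw_id))
        reason = None
        if entry is None:
            reason = "unmapped"
        elif _truthy(entry["obsolete"]) or not entry["gene_symbol"].strip():
            reason = "obsolete"
        elif not _truthy(entry["reviewed"]):
            reason = "unreviewed"
        if reason is not None:
            dropped_rows.append(
                {
                    "source_db": record.source_db,
                    "raw_id": record.interactor_raw_id,
                    "namespace": record.id_namespace,
                    "reason": reason,
                }
            )
            continue
        record.gene_symbol = entry["gene_symbol"].strip().upper()
        kept.append(record)
    dropped = pd.DataFrame(
        dropped_rows, columns=["source_db", "raw_id", "namespace", "reason"]
    )
    return kept, dropped


def regroup_methods(
    evidence: Iterable[InteractionEvidence],
    dictionary: Mapping[str, str],
) -> tuple[list[InteractionEvidence], list[str]]:
    """Assign each record's PSI-MI code to its method group.

    Unknown codes keep ``method_group = None`` and are returned in a
    report list (reported, never silently grouped).
    """
    unknown: set[str] = set()
    out: list[InteractionEvidence] = []
    for record in evidence:
        if record.method_code is None:
            record.method_group = None
        elif record.method_code in dictionary:
            record.method_group = dictionary[record.method_code]
        else:
            record.method_group = None
            unknown.add(record.method_code)
        out.append(record)
    return out, sorted(unknown)


def _dedup_key(record: InteractionEvidence) -> tuple:
    return (record.gene_symbol, record.publication_id, record.method_group)


def merge_sources(
    evidence_lists: Sequence[Iterable[InteractionEvidence]],
) -> list[InteractionEvidence]:
    """Merge harmonized, regrouped evidence from several sources.

    Duplicates are removed on the key (gene_symbol, publication_id,
    method_group) so the same finding reported by two databases counts
    once; per-symbol source provenance is retained on the surviving
    record's ``source_db`` (semicolon-joined, sorted).
    """
    merged: dict[tuple, InteractionEvidence] = {}
    provenance: dict[tuple, set[str]] = {}
    for records in evidence_lists:
        for record in records:
            if record.gene_symbol is None:
                raise ValueError("merge_sources requires harmonized evidence")
            key = _dedup_key(record)
            provenance.setdefault(key, set()).update(record.source_db.split(";"))
            if key not in merged:
                merged[key] = record
    out = []
    for key, record in merged.items():
        record.source_db = ";".join(sorted(provenance[key]))
        out.append(record)
    return out


def source_overlap_tally(merged: Iterable[InteractionEvidence]) -> dict[int, int]:
    """Count interactor symbols present in exactly 1, 2, ... sources."""
    per_symbol: dict[str, set[str]] = {}
    for record in merged:
        per_symbol.setdefault(record.gene_symbol, set()).update(
            record.source_db.split(";")
        )
    tally: dict[int, int] = {}
    for sources in per_symbol.values():
        tally[len(sources)] = tally.get(len(sources), 0) + 1
    return tally


def score_interactors(merged: Iterable[InteractionEvidence]) -> list[ScoredInteractor]:
    """Per symbol: PS = distinct publications, MS = distinct method groups.

    Missing publication ids contribute 0 to PS; missing or unmapped
    method codes contribute 0 to MS. The seed's own symbol is scored
    like any other if self-interaction evidence exists.
    """
    pubs: dict[str, set[str]] = {}
    groups: dict[str, set[str]] = {}
    for record in merged:
        symbol = record.gene_symbol
        if symbol is None:
            raise ValueError("score_interactors requires harmonized evidence")
        pubs.setdefault(symbol, set())
        groups.setdefault(symbol, set())
        if record.publication_id is not None:
            pubs[symbol].add(record.publication_id)
        if record.method_group is not None:
            groups[symbol].add(record.method_group)
    return [
        ScoredInteractor(symbol, len(pubs[symbol]), len(groups[symbol]),
                         len(pubs[symbol]) + len(groups[symbol]))
        for symbol in sorted(pubs)
    ]


def filter_interactome(
    scored: Sequence[ScoredInteractor],
    seed_symbol: str,
    fs_threshold: int = 2,
    sources: Mapping[str, set[str]] | None = None,
    dropped_log: pd.DataFrame | None = None,
) -> Interactome:
    """Keep interactors with strictly FS > fs_threshold.

    Removed members are appended to the dropped log with their FS, so
    removal reasons stay enumerable downstream.
    """
    members = [m for m in scored if m.FS > fs_threshold]
    removed = [m for m in scored if m.FS <= fs_threshold]
    removed_frame = pd.DataFrame(
        [
            {
                "source_db": "",
                "raw_id": m.gene_symbol,
                "namespace": "symbol",
                "reason": f"FS<={fs_threshold} (FS={m.FS})",
            }
            for m in removed
        ],
        columns=["source_db", "raw_id", "namespace", "reason"],
    )
    if dropped_log is not None and not dropped_log.empty:
        removed_frame = pd.concat([dropped_log, removed_frame], ignore_index=True)
    if not members:
        warnings.warn("interactome is empty after FS filtering", stacklevel=2)
    source_sets = {
        m.gene_symbol: frozenset(sources.get(m.gene_symbol, ()))
        for m in members
    } if sources else {}
    return Interactome(
        seed_symbol=seed_symbol.upper(),
        members=members,
        sources=source_sets,
        dropped=removed_frame,
        fs_threshold=fs_threshold,
    )


def build_interactome(
    evidence_lists: Sequence[Iterable[InteractionEvidence]],
    mapping: pd.DataFrame,
    method_dictionary: Mapping[str, str],
    seed_symbol: str,
    fs_threshold: int = 2,
) -> tuple[Interactome, list[str]]:
    """Full ingestion: harmonize, regroup, merge, score, FS-filter.

    Returns the interactome and the list of unknown PSI-MI codes seen.
    """
    harmonized = []
    dropped_frames = []
    unknown_all: set[str] = set()
    for records in evidence_lists:
        kept, dropped = harmonize_ids(records, mapping)
        kept, unknown = regroup_methods(kept, method_dictionary)
        unknown_all.update(unknown)
        harmonized.append(kept)
        dropped_frames.append(dropped)
    merged = merge_sources(harmonized)
    per_symbol_sources: dict[str, set[str]] = {}
    for record in merged:
        per_symbol_sources.setdefault(record.gene_symbol, set()).update(
            record.source_db.split(";")
        )
    scored = score_interactors(merged)
    dropped_log = pd.concat(dropped_frames, ignore_index=True) if dropped_frames else None
    interactome = filter_interactome(
        scored, seed_symbol, fs_threshold,
        sources=per_symbol_sources, dropped_log=dropped_log,
    )
    return interactome, sorted(unknown_all)
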