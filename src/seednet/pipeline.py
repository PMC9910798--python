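"""End-to-end orchestration: from raw inputs to tissue-specific interactomes.

``run_pipeline`` executes the stages in dependency order —

1. build-interactome (PPI ingestion, scoring, FS filter)
2. qc-counts (per-tissue QC, interactome restriction)
3. dea-rank (pairwise DEA, rank scores, expression clustering)
4. coexpress (coefficients, reference null, Tukey scores, clustering)
5. tissue-nets (combined table, per-tissue threshold extraction)
6. enrich (overrepresentation of the seed's expression/co-expression
   clusters)

— writing each stage's artifacts and a JSON run manifest with parameter
provenance and input digests into the output directory. Reruns with an
unchanged config and inputs reproduce identical outputs (stochastic
steps are driven by the configured RNG seed); stages whose inputs and
parameters are unchanged are skipped via the digest cache unless
``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpress, dea, enrich, ppi, qc, tissue
from .gct import read_gct, read_sample_meta

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs, thresholds and toggles of one pipeline run."""

    # inputs
    evidence_tables: dict[str, str] = field(default_factory=dict)  # label -> path
    id_mapping: str = ""
    method_dictionary: str = ""
    counts: str = ""
    sample_meta: str = ""
    gmt: str = ""
    term_groups: str = ""          # optional term -> semantic group TSV
    seed_symbol: str = "SEED1"

    # thresholds
    fs_threshold: int = 2
    max_zero_fraction: float = 0.05
    min_mapping_rate: float = 0.80
    alpha: float = 0.05
    high_specificity_min: int = 12
    rank_min: int = 8
    r_min: float = 0.7
    term_size_general: int = 1500
    term_size_tissue: int = 80
    n_random_sets: int = 1000
    rng_seed: int = 17

    # stage toggles
    run_enrichment: bool = True
    extract_mode: str = "union"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data: dict = {"stages": {}, "status": "running"}
        if self.path.exists():
            try:
                self.data = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                pass
            self.data["status"] = "running"

    def stage_key(self, stage: str, inputs: list[Path], params: dict) -> str:
        h = hashlib.sha256()
        for p in inputs:
            h.update(_digest(p).encode())
        h.update(json.dumps(params, sort_keys=True, default=str).encode())
        return h.hexdigest()[:16]

    def is_current(self, stage: str, key: str, outputs: list[Path]) -> bool:
        entry = self.data["stages"].get(stage)
        return (
            entry is not None
            and entry.get("key") == key
            and all(Path(p).exists() for p in entry.get("outputs", []))
            and bool(outputs) == bool(entry.get("outputs"))
        )

    def record(self, stage: str, key: str, inputs: list[Path],
               params: dict, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "key": key,
            "inputs": [str(p) for p in inputs],
            "params": {k: str(v) for k, v in params.items()},
            "outputs": [str(p) for p in outputs],
        }
        self.save()

    def finish(self, status: str) -> None:
        self.data["status"] = status
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, outdir: str | Path, force: bool = False) -> Path:
    """Run all stages; returns the output directory.

    Raises on stage failure after recording partial completion in the
    manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    manifest = _Manifest(outdir)

    try:
        _run_stages(config, outdir, manifest, force)
    except Exception:
        manifest.finish("failed")
        raise
    manifest.finish("complete")
    return outdir


def _run_stages(config: RunConfig, outdir: Path, manifest: _Manifest,
                force: bool) -> None:
    # ---- stage 1: interactome ----------------------------------------
    stage = "build-interactome"
    inputs = [Path(p) for p in config.evidence_tables.values()]
    inputs += [Path(config.id_mapping), Path(config.method_dictionary)]
    params = {"fs_threshold": config.fs_threshold, "seed": config.seed_symbol}
    key = manifest.stage_key(stage, inputs, params)
    interactome_tsv = outdir / "interactome.tsv"
    dropped_tsv = outdir / "interactome_dropped.tsv"
    edges_tsv = outdir / "interactome_edges.tsv"
    if force or not manifest.is_current(stage, key, [interactome_tsv]):
        evidence_lists = []
        mapping = ppi.load_id_mapping(config.id_mapping)
        dictionary = ppi.load_method_dictionary(config.method_dictionary)
        for label, path in config.evidence_tables.items():
            evidence_lists.append(ppi.parse_evidence_table(path, label))
        interactome, unknown_codes = ppi.build_interactome(
            evidence_lists, mapping, dictionary,
            config.seed_symbol, config.fs_threshold,
        )
        interactome.write_tsv(interactome_tsv)
        interactome.write_edge_list(edges_tsv)
        if interactome.dropped is not None:
            interactome.dropped.to_csv(dropped_tsv, sep="\t", index=False)
        (outdir / "unknown_method_codes.txt").write_text(
            "\n".join(unknown_codes) + ("\n" if unknown_codes else "")
        )
        manifest.record(stage, key, inputs, params,
                        [interactome_tsv, dropped_tsv, edges_tsv])

    interactome_frame = pd.read_csv(interactome_tsv, sep="\t")
    members = [
        ppi.ScoredInteractor(r.gene_symbol, int(r.PS), int(r.MS), int(r.FS))
        for r in interactome_frame.itertuples()
    ]
    interactome = ppi.Interactome(
        seed_symbol=config.seed_symbol.upper(), members=members,
        fs_threshold=config.fs_threshold,
    )

    # ---- stage 2: QC ---------------------------------------------------
    stage = "qc-counts"
    inputs = [Path(config.counts), Path(config.sample_meta), interactome_tsv]
    params = {
        "max_zero_fraction": config.max_zero_fraction,
        "min_mapping_rate": config.min_mapping_rate,
    }
    key = manifest.stage_key(stage, inputs, params)
    qc_gct = outdir / "counts_qc.gct"
    members_gct = outdir / "counts_members.gct"
    qc_meta_tsv = outdir / "samples_qc.tsv"
    qc_report_tsv = outdir / "qc_report.tsv"
    if force or not manifest.is_current(stage, key, [qc_gct, members_gct]):
        meta = read_sample_meta(config.sample_meta)
        matrix = read_gct(config.counts, samples=meta)
        qc_matrix, report = qc.run_qc(
            matrix,
            interactome=None,
            max_zero_fraction=config.max_zero_fraction,
            min_mapping_rate=config.min_mapping_rate,
        )
        member_matrix = qc.subset_to_interactome(
            qc_matrix, interactome, config.max_zero_fraction, report
        )
        qc_matrix.write_gct(qc_gct)
        member_matrix.write_gct(members_gct)
        qc_matrix.write_sample_meta(qc_meta_tsv)
        report.write_tsv(qc_report_tsv)
        manifest.record(stage, key, inputs, params,
                        [qc_gct, members_gct, qc_meta_tsv, qc_report_tsv])

    qc_meta = read_sample_meta(qc_meta_tsv)
    qc_matrix = read_gct(qc_gct, samples=qc_meta)
    member_matrix = read_gct(members_gct, samples=qc_meta)

    # ---- stage 3: DEA ranks ---------------------------------------------
    stage = "dea-rank"
    inputs = [members_gct]
    params = {"alpha": config.alpha,
              "high_specificity_min": config.high_specificity_min}
    key = manifest.stage_key(stage, inputs, params)
    dea_tsv = outdir / "dea_pairwise.tsv"
    ranks_tsv = outdir / "rank_matrix.tsv"
    dea_clusters_tsv = outdir / "dea_clusters.tsv"
    if force or not manifest.is_current(stage, key, [ranks_tsv]):
        # normalization from the full post-QC universe, not the member panel
        universe_sf = pd.Series(
            dea.estimate_size_factors(qc_matrix.counts),
            index=qc_matrix.counts.columns,
        )
        table, size_factors = dea.pairwise_dea(
            member_matrix, config.alpha, size_factors=universe_sf
        )
        ranks = dea.rank_scores(table, member_matrix.tissues)
        means = dea.normalized_mean_matrix(member_matrix, size_factors)
        clustering = dea.cluster_expression(means)
        table.to_csv(dea_tsv, sep="\t", index=False)
        ranks.to_csv(ranks_tsv, sep="\t", index_label="gene")
        clustering.assignments().to_csv(
            dea_clusters_tsv, sep="\t", index_label="gene", header=["cluster"]
        )
        (outdir / "den_dea_genes.nwk").write_text(clustering.gene_newick() + "\n")
        tissue_newick = clustering.tissue_newick()
        if tissue_newick:
            (outdir / "den_dea_tissues.nwk").write_text(tissue_newick + "\n")
        high = dea.high_specificity_set(ranks, config.high_specificity_min)
        (outdir / "high_specificity.json").write_text(
            json.dumps(high, indent=2, sort_keys=True)
        )
        seed_members = dea.seed_cluster(clustering.clusters, config.seed_symbol)
        (outdir / "dea_cluster_seed.txt").write_text(
            "\n".join(sorted(seed_members)) + "\n"
        )
        manifest.record(stage, key, inputs, params,
                        [dea_tsv, ranks_tsv, dea_clusters_tsv])

    ranks = pd.read_csv(ranks_tsv, sep="\t", index_col="gene")

    # ---- stage 4: co-expression -----------------------------------------
    stage = "coexpress"
    inputs = [qc_gct, members_gct]
    params = {"n_random_sets": config.n_random_sets, "rng_seed": config.rng_seed,
              "alpha": config.alpha}
    key = manifest.stage_key(stage, inputs, params)
    coex_tsv = outdir / "coex_table.tsv"
    coex_p_tsv = outdir / "coex_pvalues.tsv"
    reference_tsv = outdir / "coex_reference.tsv"
    coex_scores_tsv = outdir / "coex_scores.tsv"
    coex_clusters_tsv = outdir / "coex_clusters.tsv"
    if force or not manifest.is_current(stage, key, [coex_tsv]):
        interactors = [g for g in member_matrix.genes if g != config.seed_symbol]
        coex = coexpress.coexpression_table(
            member_matrix, config.seed_symbol, interactors
        )
        coex.r.to_csv(coex_tsv, sep="\t", index_label="gene")
        coex.p_bonferroni.to_csv(coex_p_tsv, sep="\t", index_label="gene")
        reference = coexpress.build_reference(
            qc_matrix, config.seed_symbol, set_size=len(interactors),
            n_sets=config.n_random_sets, rng_seed=config.rng_seed,
        )
        reference.write_tsv(reference_tsv)
        shifts = {
            t: {k: v for k, v in coexpress.compare_to_reference(
                coex.r[t], reference.per_tissue[t]
            ).items() if not hasattr(v, "shape")}
            for t in coex.tissues
        }
        (outdir / "coex_reference_shift.json").write_text(
            json.dumps(shifts, indent=2, sort_keys=True)
        )
        scores = coexpress.coex_rank_scores(coex, config.alpha)
        scores.to_csv(coex_scores_tsv, sep="\t", header=["score"])
        clustering = coexpress.cluster_coexpression(coex, alpha=config.alpha)
        assignments = {}
        for i, cluster in enumerate(
            sorted(clustering.clusters, key=lambda c: (-len(c), sorted(c)[0])), 1
        ):
            for gene in cluster:
                assignments[gene] = i
        pd.Series(assignments, name="cluster").sort_index().to_csv(
            coex_clusters_tsv, sep="\t", index_label="gene"
        )
        (outdir / "den_coex_interactors.nwk").write_text(
            clustering.interactor_newick() + "\n"
        )
        tissue_newick = clustering.tissue_newick()
        if tissue_newick:
            (outdir / "den_coex_tissues.nwk").write_text(tissue_newick + "\n")
        (outdir / "coex_cluster_seed.txt").write_text(
            "\n".join(sorted(clustering.highest_cluster)) + "\n"
        )
        manifest.record(
            stage, key, inputs, params,
            [coex_tsv, coex_p_tsv, reference_tsv, coex_scores_tsv,
             coex_clusters_tsv],
        )

    coex_r = pd.read_csv(coex_tsv, sep="\t", index_col="gene")
    coex_p = pd.read_csv(coex_p_tsv, sep="\t", index_col="gene")

    # ---- stage 5: tissue-specific interactomes ---------------------------
    stage = "tissue-nets"
    inputs = [ranks_tsv, coex_tsv]
    params = {"rank_min": config.rank_min, "r_min": config.r_min,
              "mode": config.extract_mode}
    key = manifest.stage_key(stage, inputs, params)
    combined_tsv = outdir / "combined_table.tsv"
    nets_dir = outdir / "tissue_interactomes"
    if force or not manifest.is_current(stage, key, [combined_tsv]):
        interactor_ranks = ranks.loc[coex_r.index]
        combined = tissue.combine_tables(interactor_ranks, coex_r, coex_p)
        combined.to_csv(combined_tsv, sep="\t", index=False)
        nets_dir.mkdir(exist_ok=True)
        outputs = [combined_tsv]
        for t in sorted(set(combined["tissue"])):
            net = tissue.extract_tissue_interactome(
                combined, t, config.rank_min, config.r_min, config.extract_mode
            )
            path = nets_dir / f"{t}.tsv"
            net.write_tsv(path)
            net.write_graphml(nets_dir / f"{t}.graphml", config.seed_symbol)
            outputs.append(path)
        manifest.record(stage, key, inputs, params, outputs)

    # ---- stage 6: enrichment --------------------------------------------
    if config.run_enrichment and config.gmt:
        stage = "enrich"
        inputs = [Path(config.gmt), outdir / "dea_cluster_seed.txt",
                  outdir / "coex_cluster_seed.txt"]
        params = {
            "term_size_general": config.term_size_general,
            "term_size_tissue": config.term_size_tissue,
            "alpha": config.alpha,
        }
        key = manifest.stage_key(stage, inputs, params)
        general_tsv = outdir / "enrichment_interactome.tsv"
        if force or not manifest.is_current(stage, key, [general_tsv]):
            collection = enrich.read_gmt(config.gmt)
            dictionary = None
            if config.term_groups:
                groups_frame = pd.read_csv(config.term_groups, sep="\t")
                dictionary = dict(
                    zip(groups_frame.iloc[:, 0], groups_frame.iloc[:, 1])
                )
            outputs = []
            queries = {
                "interactome": (
                    set(coex_r.index) | {config.seed_symbol},
                    config.term_size_general,
                ),
                "dea_cluster": (
                    set((outdir / "dea_cluster_seed.txt").read_text().split()),
                    config.term_size_tissue,
                ),
                "coex_cluster": (
                    set((outdir / "coex_cluster_seed.txt").read_text().split())
                    | {config.seed_symbol},
                    config.term_size_tissue,
                ),
            }
            for name, (query, size_cutoff) in queries.items():
                results = enrich.fisher_enrichment(query, collection)
                retained = enrich.filter_terms(
                    results, size_cutoff, require_gene=config.seed_symbol,
                    alpha=config.alpha,
                )
                path = outdir / f"enrichment_{name}.tsv"
                enrich.results_to_frame(retained).to_csv(path, sep="\t", index=False)
                outputs.append(path)
                if dictionary is not None and retained:
                    groups = enrich.group_terms(retained, dictionary)
                    matrix_path = outdir / f"functional_groups_{name}.tsv"
                    groups.membership_matrix().to_csv(matrix_path, sep="\t")
                    outputs.append(matrix_path)
            manifest.record(stage, key, inputs, params, outputs)
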