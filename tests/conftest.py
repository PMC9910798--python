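"""Shared fixtures: one default simulation and one full pipeline run,
generated once per session and reused by the read-only tests."""

from __future__ import annotations

import pytest

from seednet.pipeline import RunConfig, run_pipeline
from seednet.simulate import (
    SimulationConfig,
    simulate_annotations,
    simulate_counts,
    simulate_ppi_sources,
    write_all_inputs,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=11)


@pytest.fixture(scope="session")
def ppi_sim(default_config):
    return simulate_ppi_sources(default_config)


@pytest.fixture(scope="session")
def counts_sim(default_config):
    return simulate_counts(default_config)


@pytest.fixture(scope="session")
def annotation_sim(default_config):
    return simulate_annotations(default_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, default_config):
    """Full pipeline on the default simulation (run once)."""
    root = tmp_path_factory.mktemp("pipeline")
    write_all_inputs(default_config, root / "inputs")
    config = RunConfig(
        evidence_tables={
            s: str(root / f"inputs/evidence_{s}.tsv")
            for s in ("sourceA", "sourceB", "sourceC")
        },
        id_mapping=str(root / "inputs/id_mapping.tsv"),
        method_dictionary=str(root / "inputs/method_groups.tsv"),
        counts=str(root / "inputs/counts.gct"),
        sample_meta=str(root / "inputs/samples.tsv"),
        gmt=str(root / "inputs/gene_sets.gmt"),
        seed_symbol=default_config.seed_symbol,
        n_random_sets=100,
        rng_seed=11,
    )
    outdir = run_pipeline(config, root / "out")
    return {"root": root, "config": config, "outdir": outdir}
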