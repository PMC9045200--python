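import json
from pathlib import Path

import pytest

from ribotide import simulate
from ribotide.pipeline import PipelineConfig, run_pipeline

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> dict:
    """One full pipeline run at default study conditions (seeded).

    Shared by the recovery, positional, and determinism checks so the
    simulation is only executed when needed, and exactly once.
    """
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(
        outdir=outdir, sim=simulate.SimulationConfig(seed=DEFAULT_SEED)
    )
    report = run_pipeline(config)
    genome, annotations, truth = simulate.generate_genome(config.sim)
    truth = simulate.plant_effects(
        truth, simulate.default_effect_panel(annotations)
    )
    return {
        "config": config,
        "outdir": Path(outdir),
        "report": report,
        "genome": genome,
        "annotations": annotations,
        "truth": truth,
        "roles": simulate.panel_gene_ids(annotations),
    }


@pytest.fixture
def small_sim():
    """A fast low-depth simulation for structural tests."""
    config = simulate.SimulationConfig(
        seed=7,
        n_operons=4,
        genes_per_operon=2,
        gene_length_range=(150, 300),
        rpf_depth=5000,
        rna_depth=5000,
    )
    genome, annotations, truth = simulate.generate_genome(config)
    truth = simulate.plant_effects(
        truth, simulate.default_effect_panel(annotations)
    )
    return config, genome, annotations, truth
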