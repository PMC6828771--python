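import numpy as np
import pandas as pd
import pytest

from woundchrom.simulate import (SyntheticConfig, plant_truth,
                                 simulate_chip, simulate_expression)


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    """Default study conditions at a desk-scale gene count."""
    return SyntheticConfig(n_genes=600, seed=11)


@pytest.fixture(scope="session")
def synth_truth(synth_config):
    truth, genes = plant_truth(synth_config)
    return truth, genes


@pytest.fixture(scope="session")
def synth_expression(synth_truth, synth_config):
    truth, _ = synth_truth
    return simulate_expression(truth, synth_config)


@pytest.fixture(scope="session")
def synth_chip(synth_truth, synth_config):
    truth, genes = synth_truth
    return simulate_chip(truth, genes, synth_config)


@pytest.fixture(scope="session")
def state(synth_chip, synth_truth, synth_config):
    """Pre-wound marking-state table over the session dataset."""
    from woundchrom.states import build_state_table

    truth, genes = synth_truth
    cov, peaks = synth_chip
    return build_state_table(peaks, cov, genes,
                             promoter_bp=synth_config.promoter_bp)


@pytest.fixture(scope="session")
def synth_dataset_dir(tmp_path_factory, synth_config):
    """Complete file-backed dataset at the session config."""
    from woundchrom.simulate import write_dataset

    d = tmp_path_factory.mktemp("dataset")
    write_dataset(synth_config, d)
    return d


@pytest.fixture(scope="session")
def pipeline_results(synth_dataset_dir, tmp_path_factory, synth_config):
    """One full pipeline run shared by the tests that inspect outputs."""
    from woundchrom.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("results")
    cfg = PipelineConfig(data_dir=str(synth_dataset_dir), out_dir=str(out),
                         seed=synth_config.seed)
    manifest = run_pipeline(cfg)
    return cfg, out, manifest
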