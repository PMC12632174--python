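"""Shared fixtures: all test data is generated programmatically."""

import warnings

import numpy as np
import pytest

from circuitscan import qc
from circuitscan.simulate import PlantedCircuit, SimConfig, generate_atlas

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


PLANTED = (
    PlantedCircuit("CNP", "AT2", "Il33", "Lipofibroblast", "Il1rl1"),
    PlantedCircuit("MWCNT", "Alveolar_macrophage", "Cxcl1", "AT2", "Cxcr2"),
)


@pytest.fixture(scope="session")
def planted_config():
    return SimConfig(seed=7, circuits=PLANTED)


@pytest.fixture(scope="session")
def planted_atlas(planted_config):
    """A QC'd, log-normalized atlas with two planted circuits and its truth.

    ``adata.obs['cell_type']`` holds the planted (true) labels; tests that
    annotate must copy them first.
    """
    adata, truth = generate_atlas(planted_config)
    adata = qc.filter_genes(adata)
    adata = qc.filter_cells(adata)
    adata = qc.lognormalize(adata)
    adata.obs["true_cell_type"] = adata.obs["cell_type"].copy()
    return adata, truth


@pytest.fixture(scope="session")
def sham_atlas():
    """Sham-only single-type atlas for null calibrations."""
    config = SimConfig(
        n_cell_types=1,
        n_genes=800,
        cells_per_sample_per_type=100,
        samples_per_treatment=2,
        treatments=("sham",),
        seed=11,
    )
    adata, truth = generate_atlas(config)
    adata = qc.filter_genes(adata)
    adata = qc.filter_cells(adata)
    adata = qc.lognormalize(adata)
    return adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
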