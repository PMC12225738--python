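import warnings

import numpy as np
import pytest

from planaxis.simulate import SimulationConfig, generate_bulk, generate_cells
from planaxis.single_cell import QCThresholds, qc_filter

# degenerate-margin warnings are an expected part of several fixtures
warnings.filterwarnings("ignore", message="degenerate 2x2 margins")


@pytest.fixture(scope="session")
def planted_bulk():
    """Planted aboral/oral bulk simulation at the study design size."""
    cfg = SimulationConfig(seed=1, n_genes=2000, n_enriched_aboral=100,
                           n_enriched_oral=100, bulk_lfc=2.0)
    bc, truth = generate_bulk(cfg)
    return cfg, bc, truth


@pytest.fixture(scope="session")
def null_bulk():
    """Null bulk simulation (no planted effects)."""
    cfg = SimulationConfig(seed=7, n_genes=2000, n_enriched_aboral=0,
                           n_enriched_oral=0, bulk_lfc=0.0)
    bc, truth = generate_bulk(cfg)
    return cfg, bc, truth


@pytest.fixture(scope="session")
def clustered_cells():
    """Clustered UMI matrix with three planted aboral clusters of twelve."""
    cfg = SimulationConfig(seed=2, n_genes=2000, n_cells=1200, n_clusters=12,
                           n_aboral_clusters=3, aboral_score_shift=3.0)
    bc, truth = generate_bulk(cfg)
    cm = generate_cells(cfg, truth)
    filtered = qc_filter(cm, QCThresholds(min_genes_per_cell=50))
    return cfg, filtered, truth


@pytest.fixture(scope="session")
def calibration_cells():
    """Null single-cell matrix sized so discrete p-values are near-continuous."""
    cfg = SimulationConfig(seed=11, n_genes=500, n_cells=6000, n_clusters=6,
                           n_aboral_clusters=0, aboral_score_shift=1.0)
    bc, truth = generate_bulk(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm = generate_cells(cfg, truth)
    filtered = qc_filter(cm, QCThresholds(min_genes_per_cell=50))
    return cfg, filtered, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
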