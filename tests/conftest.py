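import numpy as np
import pandas as pd
import pytest

from recessivescan.synthgen import (
    SimConfig,
    simulate_panel,
    simulate_pedigree,
    simulate_records,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A small but structurally complete simulation configuration."""
    return SimConfig(
        seed=7,
        n_bulls=60,
        n_snps_per_chrom=(200,),
        qtl_window_index=2,
        records_per_bull=(10, 20),
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    panel, status, truth = simulate_panel(small_cfg)
    return panel, status, truth


@pytest.fixture(scope="session")
def small_pedigree(small_cfg):
    return simulate_pedigree(small_cfg)


@pytest.fixture(scope="session")
def small_records(small_cfg, small_sim, small_pedigree):
    _, status, _ = small_sim
    records, manifest = simulate_records(small_cfg, status, small_pedigree)
    return records, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
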