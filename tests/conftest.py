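import numpy as np
import pandas as pd
import pytest

from langnet import (
    RegionSet,
    SynthConfig,
    build_region_expression,
    collapse_probes,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """Small but fully structured study: 8 regions, 30 genes, 3 donors."""
    return SynthConfig(
        n_regions=8,
        n_genes=30,
        n_driver_genes=6,
        n_donors=3,
        sites_per_region_range=(2, 3),
        n_subjects=5,
        n_cohorts=2,
        n_timepoints=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_expression(tiny_dataset):
    """(pooled regions x genes matrix, per-donor matrices) for the tiny set."""
    gene_level = collapse_probes(tiny_dataset.sites)
    rs = RegionSet("all", tuple(tiny_dataset.atlas.region_ids))
    return build_region_expression(gene_level, rs)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


def random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric matrix with zero diagonal, for matrix-correlation tests."""
    a = rng.standard_normal((n, n))
    m = (a + a.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
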