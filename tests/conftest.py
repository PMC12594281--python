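import numpy as np
import pandas as pd
import pytest

from scduplex.config import published_preset
from scduplex.synthetic import (
    IndelPlacer,
    build_genome_fixture,
    simulate_cohort_burdens,
    simulate_expression_accessibility,
)


def small_config(seed=1, **kw):
    cfg = published_preset(seed=seed, **kw)
    cfg.chrom_lengths = {"chr1": 200_000, "chr2": 200_000}
    cfg.n_population_variants = 600
    cfg.n_genes = 80
    cfg.n_het_snps = 300
    return cfg


@pytest.fixture(scope="session")
def cfg():
    return small_config()


@pytest.fixture(scope="session")
def fixture(cfg):
    fx = build_genome_fixture(cfg)
    simulate_expression_accessibility(fx, cfg)
    return fx


@pytest.fixture(scope="session")
def placer(fixture):
    return IndelPlacer(fixture, seed=1)


@pytest.fixture(scope="session")
def cells(cfg, fixture):
    return simulate_cohort_burdens(cfg, fixture)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
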