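import numpy as np
import pandas as pd
import pytest

from pathgwas.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-study benchmark with two planted categories."""
    cfg = SimulationConfig(
        n_genes=80,
        n_categories=20,
        n_planted=2,
        n_studies=2,
        snps_per_gene=(2, 5),
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_snps(records):
    """records: (snp, chrom, pos, p) tuples."""
    return pd.DataFrame(records, columns=["snp", "chrom", "pos", "p"])


def make_genes(records):
    """records: (gene, chrom, start, end) tuples."""
    return pd.DataFrame(records, columns=["gene", "chrom", "start", "end"])
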