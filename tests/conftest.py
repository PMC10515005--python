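import numpy as np
import pandas as pd
import pytest

from thermomethyl.config import SimulationConfig
from thermomethyl import simulate as sim


def make_sites(rows) -> pd.DataFrame:
    """Site table from (chrom, pos, strand, mc, total, context) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc", "total", "context"])
    df["trinucleotide"] = "CGA"
    return df


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A very small but feasible design for fast unit tests."""
    return SimulationConfig(
        n_chroms=1, chrom_length_bp=40_000, n_genes=5, gene_length_bp=1500,
        n_fcg=2, seed=42,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    genome, genes = sim.generate_genome(tiny_config)
    return genome, genes


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulation shared by the slower tests."""
    cfg = SimulationConfig(seed=7)
    genome, genes = sim.generate_genome(cfg)
    reports, truth = sim.simulate_methylome(genome, genes, cfg)
    counts, truth = sim.simulate_expression(genes, truth, cfg)
    return cfg, genome, genes, reports, truth, counts


@pytest.fixture
def rng():
    return np.random.default_rng(0)
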