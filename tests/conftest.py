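import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from climagea import gea
from climagea.io import GenotypeMatrix
from climagea.simulate import SimConfig, simulate_dataset

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_gm(G, chrom=None, sex=None, pops=None, z_chrom=None, pos=None):
    """Small GenotypeMatrix builder for hand-crafted fixtures."""
    G = np.asarray(G, dtype=np.int8)
    n, s = G.shape
    samples = pd.DataFrame({
        "id": [f"ind{k:03d}" for k in range(n)],
        "population": pops if pops is not None else ["popA"] * n,
        "sex": sex if sex is not None else ["M"] * n,
    })
    snps = pd.DataFrame({
        "id": [f"snp{i:04d}" for i in range(s)],
        "chrom": chrom if chrom is not None else ["chr1"] * s,
        "pos": pos if pos is not None else np.arange(1, s + 1) * 100,
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(samples=samples, snps=snps, G=G, z_chrom=z_chrom)


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic simulated dataset shared across tests."""
    cfg = SimConfig(
        n_populations=6, n_individuals_per_pop=16, n_snps=1500,
        n_selected_snps=10, seed=11,
    )
    gm, climate, truth = simulate_dataset(cfg)
    return cfg, gm, climate, truth


@pytest.fixture(scope="session")
def small_counts_model(small_sim):
    _, gm, _, _ = small_sim
    counts = gea.pop_allele_frequencies(gm)
    model = gea.estimate_omega(counts)
    return counts, model
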