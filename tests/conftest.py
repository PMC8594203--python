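import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from hetscan.core import GenotypeMatrix


def make_matrix(genotypes, chroms=None, positions=None, pop_classes=None,
                sample_ids=None):
    """Build a GenotypeMatrix from a (samples x sites) code array."""
    G = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = G.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if chroms is None:
        chroms = ["chr1"] * n_sites
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    if pop_classes is None:
        pop_classes = ["breeding"] * n_samples
    sites = pd.DataFrame({"chrom": chroms, "pos": positions,
                          "ref": ["A"] * n_sites, "alt": ["G"] * n_sites,
                          "id": None})
    samples = pd.DataFrame({"sample_id": sample_ids,
                            "pop_class": pop_classes, "country": None})
    return GenotypeMatrix(sites=sites, samples=samples, genotypes=G)


def random_matrix(rng, n_samples, n_sites, missing_rate=0.1, chrom="chr1",
                  span=None):
    """Random dosage matrix with unique sorted positions."""
    G = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate:
        G[rng.random(G.shape) < missing_rate] = -1
    span = span or n_sites * 50
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n_sites,
                             replace=False))
    return make_matrix(G, positions=pos, chroms=[chrom] * n_sites)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, down-scaled domestication cohort shared across tests:
    1 x 2 Mb chromosome, 2 planted sweeps, 1 planted balancing block."""
    from hetscan.simulate import PlantedRegion, SimConfig, simulate_cohort
    cfg = SimConfig(
        n_chrom=1, chrom_length_bp=2_000_000, n_wild=10, n_cultivar=80,
        sweep_regions=(PlantedRegion("chr1", 400_000, 600_000, 0.98),
                       PlantedRegion("chr1", 1_400_000, 1_600_000, 0.98)),
        balancing_blocks=(PlantedRegion("chr1", 900_000, 1_080_000, 0.9),),
        causal_snps=(),
        seed=7,
    )
    matrix, traits, truth = simulate_cohort(cfg)
    return cfg, matrix, traits, truth
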