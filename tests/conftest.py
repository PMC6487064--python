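import numpy as np
import pandas as pd
import pytest

from gfblup_kit.genotypes import GenotypeMatrix
from gfblup_kit.simdata import SimulationConfig, simulate_dataset


def make_geno(counts, chroms=None, positions=None, populations=None, sires=None, dams=None):
    """Hand-built GenotypeMatrix from a small counts array."""
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    if chroms is None:
        chroms = ["chr1"] * m
    if positions is None:
        positions = list(range(1000, 1000 + 1000 * m, 1000))
    snp_map = pd.DataFrame(
        {"snp_id": [f"snp{j + 1}" for j in range(m)], "chrom": chroms, "pos": positions}
    )
    return GenotypeMatrix(
        allele_counts=counts,
        snp_map=snp_map,
        individual_ids=np.array([f"ind{i + 1}" for i in range(n)], dtype=object),
        population_labels=np.array(
            populations if populations is not None else ["pop1"] * n, dtype=object
        ),
        sire_ids=None if sires is None else np.array(sires, dtype=object),
        dam_ids=None if dams is None else np.array(dams, dtype=object),
    )


SMALL_CONFIG = SimulationConfig(
    n_populations=2,
    n_per_population=(60, 60),
    n_sires_per_population=6,
    chromosomes=(
        ("chr1", 80, 10_000_000),
        ("chr2", 80, 10_000_000),
        ("chr3", 80, 10_000_000),
    ),
    feature_chromosomes=("chr1",),
    feature_variance_fractions=(0.5,),
    n_qtl=60,
    seed=42,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small simulated dataset (2 populations x 60 cows, 240 SNPs)."""
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def medium_dataset():
    """One population, 200 cows, 10 sire groups, 2500 SNPs — used where
    relationship structure needs room to show."""
    cfg = SimulationConfig(
        n_populations=1,
        n_per_population=(200,),
        n_sires_per_population=10,
        chromosomes=tuple((f"chr{i}", 500, 50_000_000) for i in range(1, 6)),
        feature_chromosomes=("chr1", "chr2", "chr3"),
        feature_variance_fractions=(0.3, 0.2, 0.1),
        n_qtl=150,
        seed=7,
    )
    return cfg, simulate_dataset(cfg)
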