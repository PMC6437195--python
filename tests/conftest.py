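import numpy as np
import pytest

from poekit import relmat, simulate as sim


@pytest.fixture(scope="session")
def family_dataset():
    """150 two-offspring families with genotypes and all relationship matrices.

    Shared across tests that need a realistic family structure; treat as
    read-only.
    """
    spec = sim.PedigreeSpec(n_families=150, offspring_per_family=2, seed=11)
    ped = sim.simulate_pedigree(spec)
    geno = sim.simulate_genotypes(ped, 300, (0.1, 0.5), seed=12)
    mats = relmat.build_all_matrices(ped, geno)
    factors = sim.CovarianceFactors(ped, geno, g_matrix=mats["G"].values,
                                    k_matrix=mats["K"].values)
    return ped, geno, mats, factors


@pytest.fixture(scope="session")
def trio_dataset():
    """60 trios (single offspring) with phased genotypes over 5 chromosomes."""
    spec = sim.PedigreeSpec(n_families=60, offspring_per_family=1, seed=21)
    ped = sim.simulate_pedigree(spec)
    geno = sim.simulate_genotypes(ped, 200, (0.05, 0.5), seed=22,
                                  n_chromosomes=5)
    return ped, geno


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
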