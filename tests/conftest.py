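import numpy as np
import pandas as pd
import pytest

from bxdprio import SimulationConfig, default_map, simulate_cohort, simulate_ri_genotypes


@pytest.fixture(scope="session")
def small_map():
    return default_map(n_chromosomes=3, markers_per_chromosome=5, spacing_mb=10.0)


@pytest.fixture(scope="session")
def small_config(small_map):
    return SimulationConfig(
        n_strains=40,
        genetic_map=small_map,
        focal_gene="Focal1",
        focal_chromosome="2",
        focal_position_mb=30.0,
        cis_effect=0.6,
        noise_sd=0.3,
        n_background_genes=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_ri_genotypes(small_config)


def planted_cohort(seed: int, n_strains: int = 60, n_background: int = 40):
    """Cohort with a fully evidenced candidate gene (Cand1): primary
    interactor with degree 2, correlated at r = 0.8 in every tissue,
    autism-annotated, and shifted 2 SD in the case/control sets."""
    cfg = SimulationConfig(
        n_strains=n_strains,
        focal_gene="Focal1",
        planted_correlates=[("Cand1", 0.8), ("Helper1", 0.6), ("Bystander1", 0.1)],
        de_genes=[("Cand1", 2.0)],
        n_background_genes=n_background,
        seed=seed,
    )
    return simulate_cohort(
        cfg, planted_primary=["Cand1", "Helper1"], autism_genes=["Cand1"]
    )
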