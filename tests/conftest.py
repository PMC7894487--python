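import numpy as np
import pandas as pd
import pytest

from natdiv.metrics import RegionTable, SpeciesData
from natdiv.phylo import read_newick


@pytest.fixture
def small_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return read_newick("(A:1,B:1,C:1);")


@pytest.fixture
def toy_regions():
    return RegionTable(pd.DataFrame({
        "region_id": ["r1", "r2", "r3"],
        "area_km2": [100.0, 250.5, 100.0],
        "tropical_km2": [60.0, 0.0, 100.0],
        "temperate_km2": [40.0, 250.5, 0.0],
    }))


@pytest.fixture
def toy_species(toy_regions):
    """Two families: fam1 with 2 ranged species, fam2 with 1."""
    species = pd.DataFrame({
        "species_id": ["s1", "s2", "s3", "s4"],
        "family": ["fam1", "fam1", "fam2", "fam1"],
        "order": ["ord1", "ord1", "ord2", "ord1"],
        "accepted": [True, True, True, False],
        "horticultural": [True, False, False, False],
        "coverage_flag": ["complete", "partial", "complete", "complete"],
    })
    occurrences = pd.DataFrame({
        "species_id": ["s1", "s2", "s2", "s3", "s1", "s1"],
        "region_id": ["r1", "r1", "r2", "r3", "r2", "r3"],
        "status": ["native", "native", "native", "native",
                   "naturalized", "naturalized"],
    })
    return SpeciesData(species=species, occurrences=occurrences)


@pytest.fixture(scope="session")
def small_bundle():
    """Session-wide 60-family synthetic bundle for integration tests."""
    from natdiv.simulate import SimulationConfig, simulate_bundle

    cfg = SimulationConfig(n_families=60)
    return simulate_bundle(cfg, seed=202)


@pytest.fixture(scope="session")
def latent_fit_problem():
    """Small latent-scale PGLMM problem with known truth, shared across tests."""
    from natdiv.phylo import phylo_covariance
    from natdiv.simulate import brownian_effects, simulate_tree

    rng = np.random.default_rng(77)
    n = 80
    tree = simulate_tree(n, 0.06, 0.03, rng)
    A = phylo_covariance(tree).matrix
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    beta = np.array([1.0, 0.5, -0.4])
    u = brownian_effects(tree, 1.0, rng).to_numpy()
    y = X @ beta + u + rng.normal(0, 1.0, n)
    return {"tree": tree, "A": A, "X": X, "y": y, "beta": beta}
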