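import numpy as np
import pytest

from minecoast.io import GenotypeMatrix, PopulationMap
from minecoast.synth import GeneratorConfig, PlantedOutliers, generate_dataset


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """6 individuals (2 pops x 3), 6 sites on 2 scaffolds, no missing data."""
    dosages = np.array(
        [
            [0, 1, 2, 0, 1, 0],
            [1, 1, 2, 0, 0, 0],
            [0, 0, 2, 1, 1, 0],
            [2, 2, 2, 1, 0, 0],
            [2, 1, 2, 2, 1, 0],
            [1, 2, 2, 2, 0, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        dosages,
        np.array(["sc1", "sc1", "sc1", "sc2", "sc2", "sc2"], dtype=object),
        np.array([100, 250, 900, 50, 120, 400]),
        [f"ind{i}" for i in range(6)],
    ).validate()


@pytest.fixture
def tiny_pm() -> PopulationMap:
    return PopulationMap(
        individual_population={
            "ind0": "A", "ind1": "A", "ind2": "A",
            "ind3": "B", "ind4": "B", "ind5": "B",
        },
        population_habitat={"A": "coast", "B": "mine"},
        population_region={"A": "R1", "B": "R1"},
        population_coords={"A": (51.0, -4.0), "B": (51.1, -4.0)},
    ).validate()


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic 8-population dataset, small but structured (session-scoped)."""
    cfg = GeneratorConfig(n_per_pop=15, n_snps=3000, n_scaffolds=300, seed=11)
    gm, pm, truth = generate_dataset(cfg)
    return cfg, gm, pm, truth


@pytest.fixture(scope="session")
def planted_dataset():
    """Dataset with outliers planted across three comparisons plus admixture."""
    cfg = GeneratorConfig(
        n_per_pop=20,
        n_snps=4000,
        n_scaffolds=400,
        seed=5,
        planted_outliers=(
            PlantedOutliers(comparisons=("WWA", "SWA", "IRE"), effect=0.95, n_snps=60),
        ),
        # cross-cherry coastal edge, recipient outside the planted comparisons:
        # visible to the four-coast f4 test, invisible to planted-outlier recall
        admixture_edges=(("WWA-C", "ENG-C", 0.2),),
    )
    gm, pm, truth = generate_dataset(cfg)
    return cfg, gm, pm, truth
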