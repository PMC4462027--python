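import numpy as np
import pandas as pd
import pytest

from ssrpop.core_data import MISSING, NULL_ALLELE, GenotypeMatrix
from ssrpop import synthetic_data as sd


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """Five accessions, three loci, with a missing and a null cell."""
    calls = np.array([
        [150, 200, 90],
        [150, 205, 95],
        [155, 200, 90],
        [MISSING, 205, 95],
        [155, NULL_ALLELE, 90],
    ])
    return GenotypeMatrix(
        ["A1", "A2", "A3", "A4", "A5"], ["L1", "L2", "L3"], calls
    )


@pytest.fixture(scope="session")
def two_pop_panel():
    """A strongly diverged two-subpopulation panel (seeded)."""
    cfg = sd.SimConfig(
        n_accessions=60, n_subpops=2, subpop_proportions=None,
        n_loci=50, mean_alleles=6, divergence_F=0.3,
        missing_rate=0.0, null_allele_freq=0.0, seed=42,
    )
    g, marker_map, truth = sd.simulate_genotypes(cfg)
    return g, marker_map, truth, cfg


@pytest.fixture(scope="session")
def three_pop_panel():
    cfg = sd.SimConfig(
        n_accessions=90, n_subpops=3, subpop_proportions=None,
        n_loci=60, mean_alleles=6, divergence_F=0.3,
        missing_rate=0.02, null_allele_freq=0.03, seed=7,
    )
    g, marker_map, truth = sd.simulate_genotypes(cfg)
    return g, marker_map, truth, cfg


def make_phenotypes(values: dict[str, float], trait: str = "GL",
                    environments=("2010",), replicates=2) -> pd.DataFrame:
    """Helper: constant phenotype per accession replicated over env/rep."""
    rows = []
    for acc, v in values.items():
        for env in environments:
            for rep in range(1, replicates + 1):
                rows.append({"accession": acc, "environment": env,
                             "replicate": rep, "trait": trait, "value": v})
    return pd.DataFrame(rows)
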