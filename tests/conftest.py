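import numpy as np
import pandas as pd
import pytest

import pathgrs as pg
from pathgrs.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def panel():
    return pg.load_default_panel()


@pytest.fixture(scope="session")
def study_config(panel):
    return pg.default_study_config(panel, n_individuals=580, seed=11)


@pytest.fixture(scope="session")
def cohort(study_config):
    """One simulated study-scale cohort shared across tests."""
    genotypes, aims, phenotypes = pg.simulate_cohort(study_config)
    return {"genotypes": genotypes, "aims": aims, "phenotypes": phenotypes}


@pytest.fixture(scope="session")
def base_covariates(cohort):
    return cohort["phenotypes"][["age", "sex"]]


def make_matrix(columns: dict, panel=None) -> GenotypeMatrix:
    """Small helper: genotype matrix from {snp_id: list of codes}."""
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in columns.items()},
        index=[f"i{j:04d}" for j in range(n)],
    )
    return GenotypeMatrix(frame, panel=panel)
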