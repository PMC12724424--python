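import numpy as np
import pandas as pd
import pytest

from frailmeth.core_data import filter_probes
from frailmeth.simulate import (
    CohortPlan,
    RegionPlan,
    SimConfig,
    VmpPlan,
    XciPlan,
    simulate_cohort,
)

SEED = 11


def small_config(**kwargs) -> SimConfig:
    base = dict(
        regions=RegionPlan(n_ai=8, n_ad=8, n_dual=8, n_null=8,
                           n_sex_f=3, n_sex_m=3, n_opposite=2),
        n_background=500,
        xci=XciPlan(n_subject=25, n_escape=10, n_variable=10,
                    n_variable_frailty=4),
        vmp=VmpPlan(n_vmp=15),
        n_chry=8,
    )
    base.update(kwargs)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """A small two-cohort simulation shared across the suite."""
    return simulate_cohort(small_config(), seed=SEED)


@pytest.fixture(scope="session")
def filtered(cohort):
    mat, report = filter_probes(cohort.matrix)
    return mat, report


@pytest.fixture(scope="session")
def discovery(filtered):
    mat, _ = filtered
    return mat.subset_samples(
        mat.samples.index[mat.samples["cohort"] == "discovery"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
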