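import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import metsynkit as mk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 40 subjects, 60 metabolites, effects on known columns."""
    return mk.SimConfig(
        n_subjects=40, n_metabolites=60, seed=3,
        ir_effect_metabolites=(0, 1, 2), ir_effect_size=1.5,
        fram_effect_metabolites=(3, 4, 5), fram_effect_size=0.6,
        supp_effect_metabolites=(6,), supp_effect_size=0.6,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    records, truth, table, clamps = mk.generate_cohort(small_config)
    return records, truth, table, clamps


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort[2]


@pytest.fixture(scope="session")
def small_pre(small_table):
    return mk.preprocess(small_table)


@pytest.fixture()
def tiny_table():
    """3 samples × 3 metabolites with one missing cell."""
    ab = pd.DataFrame(
        {"m1": [2.0, 4.0, 6.0], "m2": [1.0, np.nan, 3.0], "m3": [5.0, 5.0, 5.0]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    ann = pd.DataFrame(
        {"biochemical_name": ["a", "b", "c"],
         "subpathway": ["p", "p", "q"],
         "superpathway": ["Lipid", "Lipid", "Amino Acid"]},
        index=pd.Index(["m1", "m2", "m3"], name="metabolite_id"),
    )
    return mk.MetaboliteTable(ab, ann)


def noise_free_config(suppression, *, n=3, times=None, seed=1):
    """Cohort config for exact clamp-recovery checks (no noise, no spread)."""
    return mk.SimConfig(
        n_subjects=n, n_metabolites=5, seed=seed,
        ir_effect_metabolites=(), fram_effect_metabolites=(),
        supp_effect_metabolites=(),
        clamp_true_suppression=suppression, clamp_suppression_sd=0.0,
        suppression_homa_rho=0.0, clamp_noise_cv=0.0,
        clamp_sample_times=times,
    )
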