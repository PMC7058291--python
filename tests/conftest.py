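import numpy as np
import pandas as pd
import pytest

from clustomics import CohortTable, default_config, generate_phenotypes


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-subject default-config cohort (no disease flags)."""
    cfg = default_config(n_subjects=2000, seed=123)
    return cfg, generate_phenotypes(cfg)


def make_cohort(traits: dict, age=None, sex=None, stage="raw", diseases=None) -> CohortTable:
    """Hand-built cohort table for unit fixtures."""
    n = len(next(iter(traits.values())))
    data = pd.DataFrame({k: np.asarray(v, float) for k, v in traits.items()})
    data.insert(0, "SEX", np.asarray(sex if sex is not None else np.ones(n), int))
    data.insert(0, "AGE", np.asarray(age if age is not None else np.full(n, 50.0), float))
    disease_cols = []
    if diseases:
        for name, flags in diseases.items():
            data[name] = np.asarray(flags, bool)
            disease_cols.append(name)
    data.index = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
    return CohortTable(data=data, trait_columns=list(traits), disease_columns=disease_cols, stage=stage)
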