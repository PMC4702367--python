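import logging

import numpy as np
import pandas as pd
import pytest

from tvcc import PeriodGrid, SimulationConfig

# control-eligibility logging is exercised explicitly where needed
logging.getLogger("tvcc").setLevel(logging.ERROR)


@pytest.fixture
def grid():
    """The 5-year age grid 0-19 used throughout the study design."""
    return PeriodGrid((0, 5, 10, 15, 20))


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled generator (~5% cohort sizes, ~30 cases) for fast tests."""
    cfg = SimulationConfig()
    return cfg.with_sizes(np.round(np.array(cfg.cohort_sizes) * 0.05))


@pytest.fixture(scope="session")
def midsize_config():
    """~20% cohort sizes (~115 cases), enough for stable joint fits."""
    cfg = SimulationConfig()
    return cfg.with_sizes(np.round(np.array(cfg.cohort_sizes) * 0.2))


def make_subjects(rows, covariates=()):
    """Build a subject table from (id, is_case, T_E, T_I, x, x_time, stratum)
    tuples plus optional covariate columns."""
    df = pd.DataFrame(rows, columns=["id", "is_case", "entry_time", "index_time",
                                     "exposure", "exposure_time", "stratum"])
    for name, vals in covariates:
        df[name] = vals
    return df
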