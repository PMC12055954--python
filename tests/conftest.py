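import warnings

import numpy as np
import pandas as pd
import pytest

from oralpipe import synthetic, tables

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)

#: one fixed simulation shared by the recovery-style tests
SIM_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    cfg = synthetic.SimulationConfig(seed=SIM_SEED)
    counts, meta, tax, truth = synthetic.generate(cfg)
    return counts, meta, tax, truth


@pytest.fixture(scope="session")
def species_rel(default_sim):
    counts, meta, tax, truth = default_sim
    sp = tables.aggregate(counts, tax, "species")
    return tables.to_relative(sp), sp


@pytest.fixture
def tiny_counts():
    return tables.CountTable(pd.DataFrame(
        {"s1": [5, 1], "s2": [0, 3]}, index=["taxA", "taxB"]))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
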