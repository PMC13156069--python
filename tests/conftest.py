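import numpy as np
import pandas as pd
import pytest

from ssep.core_data import ActivityRecord, aggregate_measurements


@pytest.fixture
def small_table():
    """Aggregated three-pair activity table with known values."""
    records = [
        ActivityRecord("OCT1", "p.F244A", "metformin", 80.0, smiles="CN(C)C(=N)N=C(N)N"),
        ActivityRecord("OCT1", "p.F244A", "metformin", 120.0, smiles="CN(C)C(=N)N=C(N)N"),
        ActivityRecord("OCT1", "p.F244A", "morphine", 37.0),
        ActivityRecord("OCT1", "p.M420del", "metformin", 25.0, smiles="CN(C)C(=N)N=C(N)N"),
    ]
    return aggregate_measurements(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
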