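import numpy as np
import pandas as pd
import pytest

from chosoft.core import CSV_COLUMNS, CultureTable
from chosoft.kinetics import DEFAULT_PARAMS, FeedSchedule, ModelState


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def params():
    return DEFAULT_PARAMS


@pytest.fixture
def batch_schedule():
    """Plain batch culture: no feeds, no sampling removal."""
    return FeedSchedule()


@pytest.fixture
def init_state():
    return ModelState()


def make_table(rows):
    return CultureTable(pd.DataFrame(rows, columns=CSV_COLUMNS), validate=False)


@pytest.fixture
def random_table(rng):
    """50 rows of random observations over a few channels/times."""
    channels = ["VCD", "GLC", "GLN", "G0F", "UDP_GAL"]
    rows = []
    for i in range(50):
        rows.append((f"b{i % 3}", "Control", 1 + i % 2, float(12 * (i % 9)),
                     channels[i % 5], float(abs(rng.normal(5, 2)))))
    return make_table(rows)
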