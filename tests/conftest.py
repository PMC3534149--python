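import numpy as np
import pandas as pd
import pytest

from celstain import ProbeGrid, ProbesetMap


@pytest.fixture
def grid_2x2():
    return ProbeGrid([[10.0, 20.0], [30.0, 40.0]], label="tiny")


@pytest.fixture
def small_map():
    """One probeset of three probes on a 2x3 grid, plus one unmapped probe."""
    entries = pd.DataFrame({
        "probeset_id": ["PS1", "PS1", "PS1"],
        "probe_id": [1, 2, 3],
        "x": [0, 1, 2],
        "y": [0, 0, 0],
        "is_core": [True, True, True],
    })
    return ProbesetMap(entries)


def make_grid(values, **kw):
    return ProbeGrid(np.asarray(values, dtype=float), **kw)
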