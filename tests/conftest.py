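import numpy as np
import pandas as pd
import pytest

from meioco import simulate
from meioco.io_types import COLUMNS, FocusTable


def make_rows(spec):
    """Helper: spec is a list of (cell, rank, sc_len, positions or None)."""
    rows = []
    for cell, rank, sc, positions in spec:
        base = dict(cell_id=cell, genotype="wild-type", stage="pachynema",
                    chromosome_rank=rank, sc_length_um=sc, marker="MLH1")
        if not positions:
            rows.append({**base, "focus_position_frac": np.nan})
        else:
            for p in positions:
                rows.append({**base, "focus_position_frac": p})
    return rows


@pytest.fixture
def tiny_table():
    return FocusTable.from_rows(make_rows([
        ("c1", 1, 12.0, [0.2, 0.8]),
        ("c1", 2, 10.0, [0.5]),
        ("c1", 3, 8.0, None),
    ]))


@pytest.fixture(scope="session")
def wt_small():
    """Small simulated wild-type dataset shared across read-only tests."""
    return simulate.simulate_dataset(simulate.wild_type_params(seed=11, n_cells=6))


@pytest.fixture(scope="session")
def wt_medium():
    return simulate.simulate_dataset(simulate.wild_type_params(seed=23, n_cells=32))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
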