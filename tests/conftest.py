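import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracles

from mfxduet.io import MFX_CSV_COLUMNS, LocalisationTable


def make_table(rows: list[tuple]) -> LocalisationTable:
    """Build a LocalisationTable from raw MFX-CSV tuples
    (trace_id, event_index, iter_index, x_nm, y_nm, efo_khz, dcr, ech)."""
    return LocalisationTable(pd.DataFrame(rows, columns=list(MFX_CSV_COLUMNS)))


@pytest.fixture
def small_table() -> LocalisationTable:
    """Two traces, two events each, two iterations per event."""
    rows = []
    for t, (x, y, efo) in enumerate([(10.0, 20.0, 50.0), (100.0, 200.0, 70.0)]):
        for e in range(2):
            for it in range(2):
                rows.append(
                    (f"T{t}", e, it, x + e, y + e, efo, 0.3 + 0.1 * it, 100 + it)
                )
    return make_table(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
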