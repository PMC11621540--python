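import numpy as np
import pandas as pd
import pytest

from tmeland.config import default_signatures
from tmeland.grid import SpotGrid, full_lattice


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture()
def small_grid():
    """8×8 hex lattice with two cluster labels split left/right."""
    table = full_lattice(8, 8)
    js = (table["array_col"].to_numpy() - table["array_row"].to_numpy() % 2) // 2
    table["cluster"] = np.where(js < 4, "left", "right")
    return SpotGrid(table)


@pytest.fixture()
def toy_counts():
    """4-spot × 6-gene integer matrix with distinct library sizes."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 30, size=(4, 6))
    return pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(4)],
        columns=[f"g{i}" for i in range(6)],
    )
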