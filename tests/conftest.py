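import numpy as np
import pandas as pd
import pytest

from slidenorm import CellQuantTable, SimConfig, fixture_small, simulate_table


@pytest.fixture(scope="session")
def small_table():
    table, truth = fixture_small()
    return table, truth


@pytest.fixture(scope="session")
def batch_table():
    """Mid-size table with clear slide effects for recovery-style tests."""
    return simulate_table(SimConfig(n_slides=8, cells_per_slide=400, tau=0.5, seed=11))


def make_table(slide_values: dict[str, dict[str, list[float]]], scale_tag: str = "raw"):
    """Build a CellQuantTable from {channel: {slide: [values...]}}."""
    channels = list(slide_values)
    slides = list(slide_values[channels[0]])
    rows = {"slide_id": [], "cell_id": []}
    for ch in channels:
        rows[ch] = []
    j = 0
    for slide in slides:
        n = len(slide_values[channels[0]][slide])
        for i in range(n):
            rows["slide_id"].append(slide)
            rows["cell_id"].append(f"c{j}")
            j += 1
            for ch in channels:
                rows[ch].append(slide_values[ch][slide][i])
    return CellQuantTable(pd.DataFrame(rows), tuple(channels), scale_tag=scale_tag).validate()


@pytest.fixture
def two_slide_table():
    """The hand-computable two-slide toy: values {0,2} and {4,6}."""
    return make_table({"m": {"s1": [0.0, 2.0], "s2": [4.0, 6.0]}})
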