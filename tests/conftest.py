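import numpy as np
import pandas as pd
import pytest

from nichegrad.model import OtuTable, RelativeAbundanceTable
from nichegrad.simulate import SimulationParams, simulate_community


@pytest.fixture
def tiny_table() -> OtuTable:
    """2 samples x 3 OTUs with easy hand-checkable counts."""
    return OtuTable(
        pd.DataFrame(
            [[3, 0, 1], [1, 2, 1]],
            index=["s1", "s2"],
            columns=["o1", "o2", "o3"],
        )
    )


def fractions_table(rows: dict[str, list[float]], sample_ids=None):
    """Build a RelativeAbundanceTable from per-OTU fraction columns.

    A filler OTU absorbs the remainder so every row sums to 1.
    """
    frame = pd.DataFrame(rows)
    filler = 1.0 - frame.sum(axis=1)
    assert (filler >= -1e-12).all(), "fractions exceed 1"
    frame["_filler"] = filler.clip(lower=0)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(len(frame))]
    frame.index = sample_ids
    return RelativeAbundanceTable(frame)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic community shared across tests (seed 1)."""
    return simulate_community(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def topsoil(default_sim):
    """(layer table with empty OTUs dropped, layer metadata, truth)."""
    meta = default_sim.metadata
    samples = meta.samples_in_layer("topsoil")
    sub, _ = default_sim.table.subset_samples(samples).drop_empty_otus()
    return sub, meta.subset(samples), default_sim.truth


@pytest.fixture(scope="session")
def small_params():
    """A reduced design for speed-sensitive tests: one layer's worth of
    structure with the default class geometry."""
    return SimulationParams(seed=3, n_layers=1)
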