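import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tribune as tb

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """1,000-cell draw of the standard 6-type benchmark."""
    return tb.simulate(tb.default_spec(n_cells=1000, seed=11))


@pytest.fixture(scope="session")
def default_benchmark():
    """The full standard benchmark: 6 types, 12 markers, 20,000 cells, seed 42."""
    return tb.simulate(tb.default_spec(n_cells=20_000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_logic():
    """Two cell types, three markers."""
    return tb.LogicTable(
        level_name="global",
        parent_label=tb.ROOT_PARENT,
        cell_types=["Tumor", "Immune"],
        markers=["PanCK", "CD45", "CD3"],
        entries=np.array([[1, -1, 0], [-1, 1, 1]]),
    )
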