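import numpy as np
import pandas as pd
import pytest

from simulelast import PanelDataset, SimulationConfig, generate_panel


def random_panel(seed: int, n_ent: int = 6, n_per: int = 5, missing: float = 0.0,
                 columns=("y", "x", "z")) -> PanelDataset:
    """Unstructured random panel for algebraic/oracle tests (no simultaneity)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ent):
        for t in range(n_per):
            if missing and rng.random() < missing:
                continue
            rows.append({"entity": f"E{i}", "period": 2000 + t,
                         **{c: rng.standard_normal() for c in columns}})
    frame = pd.DataFrame(rows)
    # correlate x with z so IV fits are well conditioned
    if {"x", "z"} <= set(columns):
        frame["x"] = frame["x"] + 0.8 * frame["z"]
    if {"y", "x"} <= set(columns):
        frame["y"] = frame["y"] + 0.5 * frame["x"]
    return PanelDataset(frame)


@pytest.fixture
def small_panel() -> PanelDataset:
    return random_panel(seed=11)


@pytest.fixture
def default_sim():
    data, truth = generate_panel(SimulationConfig(seed=314))
    return data, truth


@pytest.fixture
def sim_panel(default_sim):
    return default_sim[0]
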