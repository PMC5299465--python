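import numpy as np
import pandas as pd
import pytest

from assayrepeat import ReplicateTable, SimulationConfig, simulate_dataset


@pytest.fixture
def small_frame():
    """3 analytes x 2 samples x 2 replicates, hand-enumerable."""
    rows = []
    values = {
        ("m1", "s1"): (1.0, 1.2), ("m1", "s2"): (2.0, 2.2),
        ("m2", "s1"): (5.0, 5.1), ("m2", "s2"): (6.0, 6.3),
        ("m3", "s1"): (9.0, 9.0), ("m3", "s2"): (8.0, 8.5),
    }
    for (a, s), vs in values.items():
        for j, v in enumerate(vs, start=1):
            rows.append((a, s, j, v))
    return pd.DataFrame(rows, columns=["analyte_id", "sample_id", "replicate_id", "value"])


@pytest.fixture
def small_table(small_frame):
    return ReplicateTable.from_frame(small_frame)


@pytest.fixture
def pilot_table():
    """Simulated pilot with known components (p=50, 40 samples, 20 duplicated)."""
    config = SimulationConfig(
        p=50, n_samples=40, n_replicated=20, v_d=2.0,
        v_b_law=0.05, v_e_law=0.05, mu=10.0, seed=42,
    )
    table, truth = simulate_dataset(config)
    return table, truth


def identical_replicate_table(p=20, seed=0):
    """Table where replicate 2 copies replicate 1 exactly (zero noise)."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(10, 2, size=p)
    rows = []
    for k in range(p):
        for s in ("s1", "s2"):
            base = vals[k] + (0.5 if s == "s2" else 0.0)
            rows.append((f"a{k}", s, 1, base))
            rows.append((f"a{k}", s, 2, base))
    return ReplicateTable.from_frame(
        pd.DataFrame(rows, columns=["analyte_id", "sample_id", "replicate_id", "value"])
    )
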