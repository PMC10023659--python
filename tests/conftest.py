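import numpy as np
import pandas as pd
import pytest

from sigconfound.io import CountMatrix, SampleTable


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        ["g1", "g2", "g3"], ["s1", "s2"],
        np.array([[10, 0], [5, 8], [0, 2]]),
    )


def make_metadata(n, diagnosis=None, tox_group=None, seed=0, **overrides) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    if diagnosis is None:
        diagnosis = ["control"] * (n // 2) + ["case"] * (n - n // 2)
    if tox_group is None:
        tox_group = ["none" if d == "control" else "neg" for d in diagnosis]
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "diagnosis": diagnosis,
        "tox_group": tox_group,
        "sex": rng.choice(["f", "m"], n),
        "age": rng.uniform(20, 80, n).round(1),
        "rin": rng.uniform(5, 9, n).round(2),
        "pmi": rng.uniform(10, 60, n).round(1),
        "ph": rng.uniform(6.0, 7.0, n).round(2),
        "batch": rng.choice(["b0", "b1"], n),
        "effective_mapping_rate": rng.uniform(0.7, 0.95, n).round(3),
        "intergenic_rate": rng.uniform(0.03, 0.15, n).round(3),
    })
    for key, val in overrides.items():
        df[key] = val
    return df


@pytest.fixture
def sample_table_10() -> SampleTable:
    return SampleTable(make_metadata(10))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
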