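import numpy as np
import pandas as pd
import pytest

from b12traits import (AbundanceTable, SampleMetadata, ScenarioSpec,
                       generate_scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def count_table(rng):
    """12 samples x 30 features of moderately sparse counts."""
    vals = rng.poisson(4.0, size=(12, 30))
    vals[rng.random(vals.shape) < 0.35] = 0
    vals[:, 0] += 1  # keep every sample non-empty
    df = pd.DataFrame(vals, index=[f"S{i:02d}" for i in range(12)],
                      columns=[f"f{j:02d}" for j in range(30)])
    return AbundanceTable(df, kind="gene")


@pytest.fixture
def small_metadata():
    ids = [f"S{i:02d}" for i in range(12)]
    rng = np.random.default_rng(7)
    df = pd.DataFrame({
        "latitude": rng.uniform(-60, 60, 12),
        "longitude": rng.uniform(-180, 180, 12),
        "layer": ["SRF"] * 4 + ["DCM"] * 4 + ["MES"] * 4,
        "depth": np.r_[rng.uniform(5, 10, 4), rng.uniform(17, 180, 4),
                       rng.uniform(250, 1000, 4)],
        "temperature": rng.uniform(2, 28, 12),
        "oxygen": rng.uniform(150, 280, 12),
        "nitrates": rng.uniform(0, 15, 12),
        "NO2NO3": rng.uniform(0, 18, 12),
        "PO4": rng.uniform(0, 1.6, 12),
        "salinity": rng.uniform(33, 37, 12),
        "Si": rng.uniform(0, 25, 12),
    }, index=pd.Index(ids, name="sample_id"))
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def demo_dataset():
    """One mixed-assembly scenario reused by read-only tests."""
    spec = ScenarioSpec(determinism_w=0.5, n_profiles=30, redundancy_R=5,
                        community_size=10000,
                        n_samples_per_layer={"SRF": 10, "DCM": 8, "MES": 8},
                        seed=1234)
    return generate_scenario(spec)
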