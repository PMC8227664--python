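import numpy as np
import pandas as pd
import pytest

from phytocommune import synthetic as syn
from phytocommune.feature_table import FeatureTable


@pytest.fixture(scope="session")
def small_hierarchy():
    cfg = syn.HierarchyConfig(seed=7)
    return syn.make_hierarchy(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    return syn.make_dataset(seed=11)


@pytest.fixture()
def toy_table():
    """Four features, six samples; two co-eluting correlated pairs."""
    rng = np.random.default_rng(42)
    base = rng.normal(10, 1, size=6)
    features = pd.DataFrame(
        {"rt_s": [100.0, 100.5, 300.0, 300.2],
         "mz": [273.0757, 290.1022, 401.2, 521.3]},
        index=["A", "B", "C", "D"])
    abundance = pd.DataFrame(
        {"A": base * 2, "B": base, "C": rng.normal(5, 1, 6), "D": rng.normal(5, 1, 6)},
        index=[f"s{i}" for i in range(6)])
    return FeatureTable(features=features, abundance=abundance)


def make_metadata(n_samples, n_batches=2, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n_samples)]
    batches = np.repeat([f"batch{b+1}" for b in range(n_batches)],
                        int(np.ceil(n_samples / n_batches)))[:n_samples]
    return pd.DataFrame({
        "batch": batches,
        "dry_mass_g": np.clip(rng.normal(0.020, 0.002, n_samples), 0.01, None),
    }, index=pd.Index(idx, name="sample_id"))
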