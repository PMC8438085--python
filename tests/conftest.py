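import numpy as np
import pandas as pd
import pytest

from milktrace.io_tables import GenusCountTable, SampleMetadata
from milktrace.synthetic import ScenarioConfig, generate_dataset


@pytest.fixture
def small_counts() -> GenusCountTable:
    df = pd.DataFrame(
        [[5, 5, 0], [10, 0, 30]],
        index=["s1", "s2"],
        columns=["g1", "g2", "g3"],
    )
    return GenusCountTable(df, domain="prokaryote")


@pytest.fixture
def small_metadata() -> SampleMetadata:
    rows = []
    for farm in ("F01", "F02"):
        for comp in ("soil", "phyllosphere", "cow-teat", "milk"):
            for dom in ("prokaryote", "fungal"):
                rows.append(
                    {
                        "sample": f"{farm}:{comp}",
                        "farm": farm,
                        "compartment": comp,
                        "domain": dom,
                    }
                )
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced synthetic dataset shared by integration-style tests."""
    cfg = ScenarioConfig(
        seed=42,
        n_farms=12,
        n_genera={"prokaryote": 400, "fungal": 250},
        reads=4000,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
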