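import numpy as np
import pytest

from sparsetrack import CountTable, SampleMetadata, SimulationConfig, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_501)


@pytest.fixture
def toy_table():
    """2 taxa x 3 samples with known column sums (6, 3, 6)."""
    return CountTable(
        taxa_ids=["tA", "tB"],
        sample_ids=["s1", "s2", "s3"],
        counts=np.array([[5, 0, 2], [1, 3, 4]]),
    )


@pytest.fixture
def toy_metadata():
    return [
        SampleMetadata("s1", "gut", "Source"),
        SampleMetadata("s2", "soil", "Source"),
        SampleMetadata("s3", "mix", "Sink"),
    ]


@pytest.fixture(scope="session")
def small_panel():
    """Small simulated panel shared by slower tests: M=10, K=3, 40% unknown."""
    config = SimulationConfig(
        n_taxa=300,
        n_candidates=10,
        n_contributing=3,
        source_depth=10_000,
        sink_depth=10_000,
        unknown_prop=0.4,
        n_sinks=4,
        seed=101,
    )
    return build_dataset(config)
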