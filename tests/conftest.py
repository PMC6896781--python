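import pytest

from tseen.pipeline import run_pipeline
from tseen.simulate import simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default-configuration synthetic dataset."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full pipeline runs at the default study conditions over three seeds;
    shared by the orthology-recovery and TSEEN-recovery checks."""
    return {seed: run_pipeline(seed=seed) for seed in (1, 2, 3)}
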