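import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Jitter-free 300-promoter dataset with planted truth (shared, read-only)."""
    from nucleoshift.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(n_genes=300, jitter_sd=0.0, seed=101))


@pytest.fixture(scope="session")
def small_windows(small_dataset):
    from nucleoshift.phasing import promoter_windows_frame

    return promoter_windows_frame(small_dataset.annotation)
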