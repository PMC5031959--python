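import pytest

from srnapipe.config import RunConfig, SimulationConfig


@pytest.fixture
def run_cfg() -> RunConfig:
    return RunConfig(seed=1)


@pytest.fixture
def small_sim() -> SimulationConfig:
    """A desk-scale simulation: 10 precursors, 20 transcripts, 20k reads."""
    return SimulationConfig(seed=1, n_precursors=10, n_transcripts=20,
                            library_depth=20_000)


@pytest.fixture
def noise_free_sim() -> SimulationConfig:
    """No contaminants, no junk, adapter on every read."""
    return SimulationConfig(seed=1, n_precursors=10, n_transcripts=20,
                            library_depth=20_000, contaminant_fraction={},
                            junk_fraction=0.0, no_adapter_fraction=0.0)
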