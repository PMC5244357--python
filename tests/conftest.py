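import pytest

from plasmacall import ErrorModel, SimulationParams, make_panel


@pytest.fixture(scope="session")
def small_panel():
    """A four-amplicon SNV panel with its reference contigs."""
    panel, refs = make_panel(4, seed=7)
    return panel, refs


@pytest.fixture()
def clean_error():
    return ErrorModel(substitution_rate=0.0)


@pytest.fixture()
def shallow_params():
    return SimulationParams(depth_per_amplicon=200, ctdna_fraction=0.05, seed=11)
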