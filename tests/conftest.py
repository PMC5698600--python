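import pytest

from enorthern import load_milk_fat_table, load_synthetic_network, run_enorthern


@pytest.fixture(scope="session")
def panel():
    """The bundled 45-gene milk-fat expression panel."""
    return load_milk_fat_table()


@pytest.fixture(scope="session")
def panel_results(panel):
    """Full e-Northern results for the bundled panel, default thresholds."""
    return run_enorthern(panel)


@pytest.fixture(scope="session")
def synthetic_network():
    """Illustrative interaction network over the 45 panel genes."""
    return load_synthetic_network()
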