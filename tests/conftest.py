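import numpy as np
import pytest

import transelect as ts


@pytest.fixture(scope="session")
def default_panel() -> ts.SyntheticPanel:
    """One default-size synthetic screen (42 substrates x 8 enzymes)."""
    return ts.generate_panel(ts.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def toy_methyl_ketone():
    return ts.generate_toy_geometries("methyl_ketone")


@pytest.fixture(scope="session")
def toy_symmetric_ketone():
    return ts.generate_toy_geometries("symmetric_ketone")


@pytest.fixture(scope="session")
def toy_single_substituent():
    return ts.generate_toy_geometries("single_substituent")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
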