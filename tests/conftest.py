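import pytest

from termd.fixtures import strain_panel, wt_genome


@pytest.fixture(scope="session")
def wt():
    return wt_genome()


@pytest.fixture(scope="session")
def panel():
    return strain_panel()
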