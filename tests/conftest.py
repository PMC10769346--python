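import pytest

import spikefdr as sf


@pytest.fixture(scope="session")
def cfg():
    """Default mouse-cortex refractory configuration (2.5 ms, no censoring)."""
    return sf.effective_refractory(0.0025)


@pytest.fixture(scope="session")
def library():
    return sf.default_psth_library()
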