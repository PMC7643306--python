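import pytest

from gsfutility import DesignSpec


@pytest.fixture(scope="session")
def d188() -> DesignSpec:
    """N=188 Pocock design: delta=0.5, one-sided alpha=0.025, interim at 50%."""
    return DesignSpec.from_total(0.5, 0.025, 188)


@pytest.fixture(scope="session")
def d140() -> DesignSpec:
    """N=140 Pocock design (power 0.80 without futility)."""
    return DesignSpec.from_total(0.5, 0.025, 140)


@pytest.fixture(scope="session")
def d172() -> DesignSpec:
    """N=172 Pocock design (fixed-design t-test sample size for power 0.90)."""
    return DesignSpec.from_total(0.5, 0.025, 172)
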