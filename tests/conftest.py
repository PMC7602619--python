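import numpy as np
import pytest

from bnctrbe import (
    ALPHA,
    LI7,
    PROTON,
    PhotonReference,
    TargetSphere,
    boron_capture_branches,
    constant_let_table,
    power_law_table,
)


@pytest.fixture(scope="session")
def sphere():
    """Default 5 µm unit-density nucleus."""
    return TargetSphere()


@pytest.fixture(scope="session")
def ref():
    """Generic photon reference with (α/β)_γ = 10 Gy."""
    return PhotonReference(alpha_gamma=0.3, beta_gamma=0.03)


@pytest.fixture(scope="session")
def tables():
    """Synthetic stopping-power tables for the three capture-product ions."""
    return {
        "1H": power_law_table(PROTON),
        "4He": power_law_table(ALPHA),
        "7Li": power_law_table(LI7),
    }


@pytest.fixture(scope="session")
def branches():
    return boron_capture_branches()


@pytest.fixture(scope="session")
def flat_proton_table():
    """Constant-LET table (range >> any cell) for the crosser limit."""
    return constant_let_table(PROTON, 38.03)
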