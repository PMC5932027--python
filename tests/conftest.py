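import numpy as np
import pytest

from ironforms import epr
from ironforms.synthetic import reference_from_template


@pytest.fixture(scope="session")
def template_spectrum():
    """One powder-averaged template shared by all EPR quantification tests."""
    return epr.simulate_spectrum()


@pytest.fixture(scope="session")
def reference(template_spectrum):
    return reference_from_template(template_spectrum)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
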