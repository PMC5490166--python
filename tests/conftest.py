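import numpy as np
import pytest

import cardiodense as cd


@pytest.fixture(scope="session")
def default_spec():
    return cd.PhantomSpec()


@pytest.fixture(scope="session")
def strain_phantom(default_spec):
    """Noiseless phantom with imposed -18% free-wall longitudinal strain."""
    field = cd.imposed_strain_field(default_spec, -0.18)
    return cd.make_phantom_pair(default_spec, field)


def decode_phantom(phantom):
    """Unwrap -> decode -> anchor, the standard decoding chain."""
    unwrapped = cd.unwrap_phase(phantom.pair, phantom.mask)
    return cd.anchor_component_offsets(cd.decode_displacement(unwrapped))
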