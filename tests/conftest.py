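import numpy as np
import pytest

from lcfsd import GridSpec, LcfsdParams, generate_julia_field


@pytest.fixture(scope="session")
def default_params():
    return LcfsdParams()


@pytest.fixture(scope="session")
def bimodal_field_512():
    """Julia field whose magnitude surface carries two height plateaus."""
    return generate_julia_field(-1.15 + 0.215j, 96, GridSpec(512, 512))


@pytest.fixture(scope="session")
def dendrite_field_512():
    """Dendrite Julia set (c = i), nearly flat magnitude surface."""
    return generate_julia_field(1j, 15, GridSpec(512, 512))
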