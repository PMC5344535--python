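import numpy as np
import pytest

from lequant import ClosureSpec, EmbryoSpec, make_closure_series, make_embryo


@pytest.fixture(scope="session")
def noiseless_embryo():
    """Straight midline, uniform unit amplitude, zero background and noise."""
    spec = EmbryoSpec(
        shape=(256, 256),
        midline_shape="straight",
        midline_amplitude_um=0.0,
        anterior_amp=1.0,
        posterior_amp=1.0,
        background=0.0,
        noise_sigma=0.0,
        seed=1,
    )
    return spec, make_embryo(spec)


@pytest.fixture(scope="session")
def step_embryo():
    """Sinusoid midline with a noiseless 2:1 anterior:posterior step."""
    spec = EmbryoSpec(noise_sigma=0.0, seed=2)
    return spec, make_embryo(spec)


@pytest.fixture(scope="session")
def symmetric_closure():
    spec = ClosureSpec()
    return spec, make_closure_series(spec)
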