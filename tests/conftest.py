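import numpy as np
import pytest
from hypothesis import settings

from mesomux import IRFTrace, make_irf_trace, make_photon_kernel

settings.register_profile("repro", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def kernel():
    """Default single-photon kernel (1.875 ns FWHM, damped ringing tail)."""
    return make_photon_kernel()


@pytest.fixture(scope="session")
def fast_kernel():
    """Narrow ring-free kernel for channel-purity fixtures (fast detector)."""
    return make_photon_kernel(fwhm_ns=0.9375, ring_amplitude=0.0)


@pytest.fixture(scope="session")
def irf(kernel):
    """Realistic ringing IRF with its reference (peak) bin at 19."""
    return IRFTrace(make_irf_trace(kernel))


@pytest.fixture(scope="session")
def irf_shifted(irf):
    """The same IRF after the four-gate preprocessing shift (peak at 0)."""
    from mesomux import preprocess_four_gate

    return IRFTrace(
        np.maximum(preprocess_four_gate(irf.u, 19, subtract_baseline=False), 0.0)
    )
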