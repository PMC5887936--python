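import numpy as np
import pytest

from hp13c.spectral import Resonance, SpectralAxis, model_fid, fid_to_spectrum


@pytest.fixture(scope="session")
def mrsi_axis():
    from hp13c.simulate import MRSI_AXIS

    return MRSI_AXIS


@pytest.fixture(scope="session")
def bicarb_axis():
    from hp13c.simulate import BICARB_AXIS

    return BICARB_AXIS


@pytest.fixture
def lorentzian_spectrum(bicarb_axis):
    """Single-resonance absorption spectrum factory on the bicarbonate axis."""

    def make(shift_ppm=159.5, amplitude=1.0, linewidth_hz=8.0, phase_rad=0.0):
        fid = model_fid(
            [Resonance(shift_ppm, amplitude, linewidth_hz, phase_rad)], bicarb_axis
        )
        return fid_to_spectrum(fid)

    return make
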