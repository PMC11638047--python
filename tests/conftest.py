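import numpy as np
import pytest

from dcequant import AcquisitionProtocol, default_aif


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def aif(protocol):
    """Population AIF on a 1 s grid, bolus onset at the injection time."""
    return default_aif(protocol)


@pytest.fixture(scope="session")
def frame_times(protocol):
    return protocol.frame_times


@pytest.fixture(scope="session")
def boxcar_aif():
    """Unit-step plasma concentration from t = 0, for closed-form checks."""
    from dcequant import AIFCurve

    t = np.arange(0.0, 600.1, 1.0)
    return AIFCurve(t, np.ones_like(t))
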