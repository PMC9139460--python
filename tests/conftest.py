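import numpy as np
import pytest

from wmcircuit import FeedbackParams, StimulusProtocol


@pytest.fixture
def pulse_protocol():
    """100 ms pulse of unit amplitude followed by 900 ms of silence."""
    return StimulusProtocol(pulses=[(0.0, 100.0, 1.0)], total_duration=1000.0)


@pytest.fixture
def balanced_params():
    return FeedbackParams(tau=20.0, w_pos=1.0)


def closed_form_decay(r0: float, decay: float, tau: float, times: np.ndarray) -> np.ndarray:
    """Analytic solution of tau dr/dt = -decay * r with r(0) = r0."""
    return r0 * np.exp(-decay * times / tau)
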