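import numpy as np
import pytest

import ecochg_monitor as em


@pytest.fixture
def config():
    return em.RunConfig()


@pytest.fixture
def stimulus():
    return em.default_stimulus()


@pytest.fixture
def small_bundle():
    """Two-frequency, three-frame bundle with hand-set values."""
    t = np.array([0.5, 1.5, 2.5])
    return em.TracingBundle(
        (
            em.CMTracing(507.0, t, np.array([1.0, 2.0, 3.0]), np.zeros(3)),
            em.CMTracing(1015.0, t, np.array([4.0, 5.0, 6.0]), np.zeros(3)),
        )
    )


def make_tracing(freq, amplitudes, phases=None, dt=1.0):
    amplitudes = np.asarray(amplitudes, dtype=float)
    t = (np.arange(len(amplitudes)) + 0.5) * dt
    phases = np.zeros(len(amplitudes)) if phases is None else np.asarray(phases, float)
    return em.CMTracing(freq, t, amplitudes, em.wrap_phase(phases))
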