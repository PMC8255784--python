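import numpy as np
import pytest

import rabbitecg as r


@pytest.fixture(scope="session")
def yc_profile():
    return r.default_profiles()[0]


@pytest.fixture(scope="session")
def short_protocol():
    """Scaled-down four-phase protocol for fast end-to-end tests."""
    return r.PhaseProtocol((("baseline", 320.0), ("methoxamine", 60.0),
                            ("dofetilide_low", 60.0),
                            ("dofetilide_high", 240.0)))


@pytest.fixture(scope="session")
def baseline_protocol():
    return r.PhaseProtocol((("baseline", 600.0),))


@pytest.fixture(scope="session")
def flat_profile():
    """Deterministic profile: no variance, no modulation, no jitter."""
    return r.GroupProfile(name="flat", rr_mean_ms=400.0, qt_mean_ms=200.0)


@pytest.fixture(scope="session")
def yc_baseline_series(yc_profile, baseline_protocol):
    return r.make_beat_series(yc_profile, baseline_protocol, seed=1)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))
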