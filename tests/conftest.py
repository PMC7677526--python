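"""Shared fixtures: cohort configs and the closed-loop reference runs.

The long closed-loop simulations are session-scoped so the resting and
peak-exercise windows are integrated once and reused by the unit,
property and acceptance tests.
"""

import numpy as np
import pytest

from htxsim import build_healthy, build_htxr, integrate
from htxsim.protocols import Protocol, summarize_window

REST_DURATION = 300.0
TRANSIENT = 60.0
HOLD_LEAD = 120.0
HOLD = 300.0


@pytest.fixture(scope="session")
def healthy():
    return build_healthy()


@pytest.fixture(scope="session")
def htxr():
    return build_htxr()


@pytest.fixture(scope="session")
def healthy_rest(healthy):
    res = integrate(healthy, duration=REST_DURATION)
    assert not res.failed
    return res


@pytest.fixture(scope="session")
def htxr_rest(htxr):
    res = integrate(htxr, duration=REST_DURATION)
    assert not res.failed
    return res


def _hold(config, intensity):
    proto = Protocol.ramp_hold(intensity, hold=HOLD, lead=HOLD_LEAD)
    res = integrate(config, protocol=proto)
    assert not res.failed
    return res


@pytest.fixture(scope="session")
def healthy_peak(healthy):
    return _hold(healthy, 1.0)


@pytest.fixture(scope="session")
def htxr_peak(htxr):
    return _hold(htxr, 0.5)


@pytest.fixture(scope="session")
def htxr_echo(htxr):
    """HTxR at the exercise-echo workload (37% of healthy MTP)."""
    return _hold(htxr, 0.37)


def summarize_rest(res, config):
    win = res.window(TRANSIENT, REST_DURATION)
    return summarize_window(win, config.bsa, beats=res.beats)


def summarize_hold(res, config):
    win = res.window(HOLD_LEAD + TRANSIENT, HOLD_LEAD + HOLD)
    return summarize_window(win, config.bsa, beats=res.beats)


@pytest.fixture(scope="session")
def healthy_rest_summary(healthy_rest, healthy):
    return summarize_rest(healthy_rest, healthy)


@pytest.fixture(scope="session")
def htxr_rest_summary(htxr_rest, htxr):
    return summarize_rest(htxr_rest, htxr)


@pytest.fixture(scope="session")
def healthy_peak_summary(healthy_peak, healthy):
    return summarize_hold(healthy_peak, healthy)


@pytest.fixture(scope="session")
def htxr_peak_summary(htxr_peak, htxr):
    return summarize_hold(htxr_peak, htxr)


@pytest.fixture(scope="session")
def htxr_echo_summary(htxr_echo, htxr):
    return summarize_hold(htxr_echo, htxr)
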