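"""Shared fixtures: the default calibrated model and a cache of runs.

Equilibration and pulse runs are moderately expensive, and several tests
interrogate the same physiological scenarios, so they are computed once per
session and shared.
"""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from vasoreg import build_default_model, load_defaults, Protocol

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    return load_defaults()


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def ref(model):
    return model.ref


@pytest.fixture(scope="session")
def runs(model):
    """Cached equilibria and SNA-pulse runs keyed by (C_symp, M0, lock)."""
    cache = {}

    def equilibrium(c_symp, m0):
        key = ("eq", c_symp, m0)
        if key not in cache:
            state, steady = model.steady_state(c_symp, m0, t_max_s=600.0)
            assert steady, f"no steady state at C_symp={c_symp}, M0={m0}"
            cache[key] = state
        return cache[key]

    def pulse(c_symp, m0, lock=False, pre=5.0, width=30.0, post=0.0):
        key = ("pulse", c_symp, m0, lock, pre, width, post)
        if key not in cache:
            start = equilibrium(0.0, m0)
            protocol = Protocol.sna_pulse(level=c_symp, demand=m0, pre_s=pre,
                                          pulse_s=width, post_s=post,
                                          lock_metabolic=lock)
            cache[key] = (protocol, model.simulate(protocol, initial=start))
        return cache[key]

    return SimpleNamespace(equilibrium=equilibrium, pulse=pulse)
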