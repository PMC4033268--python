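"""Randomized scenario generation for property-based testing.

Produces parameter bundles jittered around the packaged defaults together
with random piecewise-constant stimulation protocols.  The core model is
deterministic; randomness only enters here, and every scenario is fully
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Tuple

import numpy as np

from .defaults import ParameterBundle, load_defaults
from .conducted import SignalParams
from .dynamics import Protocol
from .network import build_reference_state, CalibrationError
from .wall import WallParams, VasoactiveWallSet

__all__ = ["generate_scenario", "jittered_bundle", "random_protocol"]


def _jitter(rng, value, frac):
    return value * (1.0 + frac * rng.uniform(-1.0, 1.0))


def jittered_bundle(rng: np.random.Generator, jitter: float = 0.2) -> ParameterBundle:
    """Bundle with wall/transport parameters perturbed within +-jitter.

    Positivity is preserved by construction (multiplicative jitter); the
    saturation feedback R1 is additionally capped below 1 so the ATP
    release rate can never go negative.
    """
    bundle = load_defaults()
    walls = []
    for p in bundle.walls.params:
        walls.append(WallParams(
            compartment=p.compartment,
            D0_um=_jitter(rng, p.D0_um, jitter / 2),  # geometry: gentler jitter
            C_myo=_jitter(rng, p.C_myo, jitter),
            C_shear=_jitter(rng, p.C_shear, jitter),
            C_pass=_jitter(rng, p.C_pass, jitter),
            C_pass_prime=_jitter(rng, p.C_pass_prime, jitter),
            C_act=_jitter(rng, p.C_act, jitter),
            C_act_prime=_jitter(rng, p.C_act_prime, jitter),
            C_act_dprime=_jitter(rng, p.C_act_dprime, jitter),
            tau_d_s=p.tau_d_s, tau_a_s=p.tau_a_s))
    oxygen = replace(
        bundle.oxygen,
        R0=_jitter(rng, bundle.oxygen.R0, jitter),
        R1=min(_jitter(rng, bundle.oxygen.R1, jitter), 0.99),
        k_d=_jitter(rng, bundle.oxygen.k_d, jitter),
        C_atp_in=_jitter(rng, bundle.oxygen.C_atp_in, jitter))
    signal = SignalParams(
        L_met_cm=_jitter(rng, bundle.signal.L_met_cm, jitter),
        C_meta=_jitter(rng, bundle.signal.C_meta, jitter))
    return replace(bundle, walls=VasoactiveWallSet(walls), oxygen=oxygen,
                   signal=signal, checksum=None)


def random_protocol(rng: np.random.Generator,
                    max_epochs: int = 4) -> Protocol:
    """Random piecewise-constant SNA/demand protocol (10-40 s epochs)."""
    n_epochs = int(rng.integers(2, max_epochs + 1))
    t = 0.0
    epochs = []
    for i in range(n_epochs):
        cs = float(rng.uniform(0.0, 4.0)) if rng.uniform() < 0.7 else 0.0
        m0 = float(rng.uniform(1.0, 8.28))
        epochs.append((t, cs, m0))
        t += float(rng.uniform(10.0, 40.0))
    return Protocol(epochs=tuple(epochs), duration_s=t)


def generate_scenario(seed: int, jitter: float = 0.2
                      ) -> Tuple[ParameterBundle, Protocol]:
    """Reproducible jittered bundle + random protocol for one seed.

    ``jitter=0`` returns the packaged defaults exactly.  Bundles whose
    jittered wall parameters are inconsistent with the reference state
    (calibration would fail) are rejected and redrawn deterministically.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        bundle = (load_defaults() if jitter == 0
                  else jittered_bundle(rng, jitter))
        protocol = random_protocol(rng)
        try:
            build_reference_state(bundle.network_specs, bundle.walls,
                                  bundle.oxygen, bundle.signal, bundle.tissue)
        except CalibrationError:
            continue
        return bundle, protocol
    raise RuntimeError(f"no calibratable scenario found for seed {seed}")
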