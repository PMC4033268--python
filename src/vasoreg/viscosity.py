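"""Apparent blood viscosity in microvessels.

Blood behaves as a non-Newtonian suspension in vessels below ~300 um: the
apparent viscosity falls with decreasing diameter (Fahraeus-Lindqvist
effect), passes through a minimum, and rises steeply in capillary-sized
vessels.  The empirical in-vivo parametrization of Pries et al. (1994)
captures this as a function of luminal diameter and discharge hematocrit.

The network model treats viscosity as a fixed per-compartment property of
the reference state; this law is used to fill in viscosities that are not
specified explicitly in a network configuration.
"""

from __future__ import annotations

import numpy as np

__all__ = ["in_vivo_viscosity"]


def _eta_45(D):
    """Apparent in-vivo relative viscosity at discharge hematocrit 0.45."""
    return 6.0 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D ** 0.645)


def _shape_exponent(D):
    """Hematocrit-dependence shape exponent C(D)."""
    sig = 1.0 / (1.0 + 1e-11 * D ** 12)
    return (0.8 + np.exp(-0.075 * D)) * (sig - 1.0) + sig


def in_vivo_viscosity(diameter_um, discharge_hematocrit=0.4):
    """Apparent in-vivo viscosity of blood, in centipoise.

    Parameters
    ----------
    diameter_um : float or array
        Luminal diameter in micrometres.  Must exceed 1.1 um (the effective
        width of the cell-exclusion layer in the parametrization).
    discharge_hematocrit : float
        Discharge hematocrit H_D (red-cell volume fraction of the outflow).

    Returns
    -------
    float or ndarray
        Apparent viscosity in cP (relative viscosity times the plasma
        viscosity of 1 cP assumed by the parametrization).
    """
    D = np.asarray(diameter_um, dtype=float)
    if np.any(D <= 1.1):
        raise ValueError("in-vivo viscosity law requires diameter > 1.1 um")
    Hd = float(discharge_hematocrit)
    if not 0.0 < Hd < 1.0:
        raise ValueError("discharge hematocrit must lie in (0, 1)")
    C = _shape_exponent(D)
    wall = (D / (D - 1.1)) ** 2
    hterm = ((1.0 - Hd) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    eta = (1.0 + (_eta_45(D) - 1.0) * hterm * wall) * wall
    return eta if eta.ndim else float(eta)
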