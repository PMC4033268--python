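"""Vessel wall mechanics of actively regulating arterioles.

Each vasoactive compartment carries a length-tension model of the vascular
smooth muscle in its wall.  The total circumferential tension generated by
the wall at diameter D is

    T_total = T_pass(D) + A * T_act_max(D),

the sum of a passive elastic component

    T_pass = C_pass * exp(C'_pass * (D/D_0 - 1))

and a maximally activated smooth-muscle component scaled by the activation
A in [0, 1],

    T_act_max = C_act * exp(-((D/D_0 - C'_act) / C''_act)^2),

where D_0 is the passive diameter at a transmural pressure of 100 torr.
The target activation is a sigmoidal function of the net vasoactive
stimulus,

    A_total = 1 / (1 + exp(-S_tone)),
    S_tone  = C_myo * T - C_shear * tau_wall + C_symp - S_CR + C''_tone,

which combines the myogenic response to wall tension T = P*D/2, the
shear-dependent dilation, the additive sympathetic stimulus C_symp, the
upstream-conducted metabolic signal S_CR (dilatory, hence negative sign),
and a calibrated tone offset C''_tone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .units import UM_TO_CM

__all__ = [
    "WallParams",
    "WallState",
    "VasoactiveWallSet",
    "passive_tension",
    "max_active_tension",
    "total_tension",
    "stimulus_signal",
    "target_activation",
    "inverse_target_activation",
]


@dataclass(frozen=True)
class WallParams:
    """Smooth-muscle mechanics constants for one vasoactive compartment.

    Tensions are in dyn/cm, C_myo in cm/dyn, C_shear in cm^2/dyn; D_0 is in
    micrometres.  ``C_tone`` (the additive offset C''_tone of the stimulus)
    is produced by reference-state calibration and may carry either sign.
    """

    compartment: str
    D0_um: float
    C_myo: float
    C_shear: float
    C_pass: float
    C_pass_prime: float
    C_act: float
    C_act_prime: float
    C_act_dprime: float
    tau_d_s: float = 1.0
    tau_a_s: float = 20.0
    C_tone: Optional[float] = None
    #: Optional pi r^2 area prefactor on the active tension (off by default;
    #: the tabulated C_act values carry tension units already).
    area_prefactor: bool = False

    def __post_init__(self):
        for name in ("D0_um", "C_myo", "C_shear", "C_pass", "C_pass_prime",
                     "C_act", "C_act_prime", "C_act_dprime", "tau_d_s", "tau_a_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"wall parameter {name} must be positive "
                                 f"({self.compartment})")
        if not self.tau_d_s < self.tau_a_s:
            raise ValueError("diameter time constant tau_d must be smaller "
                             "than activation time constant tau_a")

    def with_tone(self, c_tone: float) -> "WallParams":
        return replace(self, C_tone=c_tone)


@dataclass
class WallState:
    """Instantaneous mechanical state of one vasoactive compartment."""

    D_um: float
    A: float
    T: float = 0.0
    S_tone: float = 0.0
    A_total: float = 0.0

    def __post_init__(self):
        if self.D_um <= 0:
            raise ValueError("diameter must be positive")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError("activation must lie in [0, 1]")


class VasoactiveWallSet:
    """Stacked (vectorized) wall parameters for the vasoactive compartments.

    Wraps a sequence of :class:`WallParams` into aligned numpy arrays so the
    dynamics can evaluate all compartments at once.
    """

    _FIELDS = ("D0_um", "C_myo", "C_shear", "C_pass", "C_pass_prime",
               "C_act", "C_act_prime", "C_act_dprime", "tau_d_s", "tau_a_s")

    def __init__(self, params: Sequence[WallParams]):
        if not params:
            raise ValueError("at least one vasoactive compartment required")
        self.params = list(params)
        self.compartments = [p.compartment for p in params]
        for name in self._FIELDS:
            setattr(self, name, np.array([getattr(p, name) for p in params]))
        self.area_prefactor = np.array([p.area_prefactor for p in params])
        tones = [p.C_tone for p in params]
        self.C_tone = (None if any(t is None for t in tones)
                       else np.array(tones, dtype=float))

    def __len__(self):
        return len(self.params)

    def set_tone(self, c_tone):
        c_tone = np.asarray(c_tone, dtype=float)
        self.C_tone = c_tone
        self.params = [p.with_tone(c) for p, c in zip(self.params, c_tone)]


def passive_tension(D_um, p):
    """Passive wall tension T_pass(D), dyn/cm.

    Strictly increasing in D; equals C_pass at the passive diameter D_0.
    """
    D = np.asarray(D_um, dtype=float)
    return p.C_pass * np.exp(p.C_pass_prime * (D / p.D0_um - 1.0))


def max_active_tension(D_um, p):
    """Maximal active tension T_act_max(D), dyn/cm.

    A Gaussian in D/D_0, peaking at C'_act * D_0 with width C''_act: smooth
    muscle generates its greatest force at an optimal circumferential
    length.  If ``area_prefactor`` is set on the parameters, the value is
    additionally multiplied by pi r^2 (r in cm), a variant retained for
    sensitivity analysis.
    """
    D = np.asarray(D_um, dtype=float)
    t = p.C_act * np.exp(-(((D / p.D0_um) - p.C_act_prime) / p.C_act_dprime) ** 2)
    pref = np.asarray(getattr(p, "area_prefactor", False))
    if np.any(pref):
        area = np.pi * (D * UM_TO_CM / 2.0) ** 2
        t = np.where(pref, t * area, t)
    return t


def total_tension(D_um, A, p):
    """Total generated wall tension T_pass + A * T_act_max, dyn/cm."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0) or np.any(A > 1):
        raise ValueError("activation must lie in [0, 1]")
    return passive_tension(D_um, p) + A * max_active_tension(D_um, p)


def stimulus_signal(T, tau_wall, C_symp, S_CR, p, C_tone=None):
    """Net vasoactive stimulus S_tone (dimensionless).

    Increasing in wall tension T (myogenic constriction) and in the
    sympathetic drive C_symp; decreasing in wall shear stress tau_wall and
    in the conducted metabolic signal S_CR (both dilatory).
    """
    if C_tone is None:
        C_tone = p.C_tone
    if C_tone is None:
        raise ValueError("C''_tone has not been calibrated")
    return p.C_myo * np.asarray(T) - p.C_shear * np.asarray(tau_wall) \
        + C_symp - np.asarray(S_CR) + C_tone


def target_activation(S_tone):
    """Sigmoidal target activation A_total = 1/(1 + exp(-S_tone)).

    Bounded in (0, 1): 0 is the absence of tone, 1 maximal vasoconstriction.
    """
    return expit(np.asarray(S_tone, dtype=float))


def inverse_target_activation(A_total):
    """Stimulus level producing a given target activation (logit)."""
    A = np.asarray(A_total, dtype=float)
    if np.any(A <= 0) or np.any(A >= 1):
        raise ValueError("activation must lie strictly inside (0, 1)")
    return logit(A)
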