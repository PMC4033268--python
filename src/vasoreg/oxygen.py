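"""Axial oxygen transport and erythrocyte ATP signaling.

Oxygen is carried convectively along the single representative flow
pathway.  Each exchanging compartment (feed artery through capillaries)
supplies a coaxial tissue sleeve of fixed width with zero-order uptake
kinetics, so hemoglobin saturation falls linearly with distance,

    dS/dx = - M0 * A_sleeve / (Q_seg * C0_eff),

until oxygen is depleted (S is floored at zero); venous segments exchange
no oxygen.  A_sleeve is the annular sleeve cross-section
pi[(D/2 + w)^2 - (D/2)^2] and C0_eff = C0 * H_D / 0.45 the effective
carrying capacity of the blood at its discharge hematocrit.

Erythrocytes release ATP at a rate that increases as saturation falls;
ATP is degraded at the vessel wall.  Along every compartment (venous
included) the plasma ATP concentration obeys

    v * dC/dx = H_T * R0 * (1 - R1 * S(x)) - (4 k_d / D) * C,

with the surface-to-volume ratio 4/D converting the wall degradation rate
(cm/s) into a volumetric sink.  Because S(x) is piecewise linear, this
linear ODE has an exact piecewise solution, which is what the profile
stores; no numerical integration is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .units import UM_TO_CM, MIN_TO_S

__all__ = ["OxygenParams", "AxialProfile", "hill_saturation", "hill_tension",
           "saturation_profile", "atp_profile"]


@dataclass(frozen=True)
class OxygenParams:
    """Oxygen transport and metabolic signaling parameters.

    ``M0`` is the volumetric oxygen demand of the tissue in
    cm^3 O2 (100 cm^3)^-1 min^-1 — the conventional physiological unit;
    resting skeletal muscle sits near 1 and heavy rhythmic contraction near
    8.  ``R0`` is the maximal ATP release rate, expressed in uM/s (1 uM/s
    corresponds to 1e-9 mol s^-1 cm^-3).
    """

    M0: float = 1.0
    C0: float = 0.5                 # O2 carrying capacity, cm3 O2 / cm3 blood
    HT: float = 0.3                 # tube hematocrit
    HD: float = 0.4                 # discharge hematocrit
    hill_n: float = 2.7             # Hill exponent
    P50: float = 26.0               # half-saturation tension, torr
    S_in: float = 0.97              # inlet oxyhemoglobin saturation
    R0: float = 1.4                 # maximal ATP release rate, uM/s
    R1: float = 0.891               # saturation feedback on ATP release
    C_atp_in: float = 0.5           # inlet plasma ATP, uM
    k_d: float = 2e-4               # wall ATP degradation rate, cm/s
    normalization_hematocrit: float = 0.45  # hematocrit at which C0 applies

    # alias used by network construction
    @property
    def hematocrit_discharge(self):
        return self.HD

    def __post_init__(self):
        if not 0.0 <= self.S_in <= 1.0:
            raise ValueError("inlet saturation must lie in [0, 1]")
        if not 0.0 < self.HT < self.HD < 1.0:
            raise ValueError("hematocrits must satisfy 0 < H_T < H_D < 1")
        for f in ("M0", "C0", "R0", "R1", "k_d", "hill_n", "P50", "C_atp_in"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def effective_capacity(self) -> float:
        """Convective O2 capacity C0 * H_D / 0.45, cm3 O2 / cm3 blood."""
        return self.C0 * self.HD / self.normalization_hematocrit


def hill_saturation(P_torr, params: OxygenParams):
    """Oxyhemoglobin saturation from oxygen tension (Hill equation)."""
    P = np.asarray(P_torr, dtype=float)
    if np.any(P < 0):
        raise ValueError("oxygen tension must be non-negative")
    Pn = P ** params.hill_n
    return Pn / (Pn + params.P50 ** params.hill_n)


def hill_tension(S, params: OxygenParams):
    """Oxygen tension from saturation (inverse Hill equation), torr."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0) or np.any(S >= 1):
        raise ValueError("saturation must lie in [0, 1)")
    return params.P50 * (S / (1.0 - S)) ** (1.0 / params.hill_n)


@dataclass
class _AtpPiece:
    """Exact ATP solution C(u) = c0 + c1 u + c2 u^2 + amp e^(-beta u)."""
    x_abs: float      # absolute pathway coordinate of the piece start
    length: float
    c0: float
    c1: float
    amp: float
    beta: float
    c2: float = 0.0   # only used in the degradation-free (beta = 0) case

    def value(self, u):
        return (self.c0 + self.c1 * u + self.c2 * u ** 2
                + self.amp * np.exp(-self.beta * u))

    def mean(self) -> float:
        el = self.length
        if el <= 0:
            return float(self.value(0.0))
        bl = self.beta * el
        exp_term = self.amp * (-math.expm1(-bl)) / bl if bl > 0 else self.amp
        return self.c0 + 0.5 * self.c1 * el + self.c2 * el ** 2 / 3.0 + exp_term


@dataclass
class AxialProfile:
    """Piecewise-exact saturation and ATP fields along the flow pathway."""

    boundaries: np.ndarray            # compartment boundaries, cm (len 14)
    S_start: np.ndarray               # saturation entering each compartment
    S_slope: np.ndarray               # dS/dx in the non-depleted part
    depletion_x: np.ndarray           # absolute x where S reaches 0 (nan if never)
    S_end: np.ndarray
    atp_pieces: Optional[List[List[_AtpPiece]]] = None
    atp_mean_uM: Optional[np.ndarray] = None
    atp_end_uM: Optional[np.ndarray] = None

    def saturation(self, x):
        """Saturation at absolute pathway coordinate(s) x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.clip(np.searchsorted(self.boundaries, x, side="right") - 1,
                      0, len(self.S_start) - 1)
        rel = x - self.boundaries[idx]
        s = self.S_start[idx] + self.S_slope[idx] * rel
        dep = self.depletion_x[idx]
        s = np.where(np.isfinite(dep) & (x >= dep), 0.0, s)
        return np.clip(s, 0.0, 1.0)

    def atp(self, x):
        """Plasma ATP concentration (uM) at absolute coordinate(s) x."""
        if self.atp_pieces is None:
            raise ValueError("ATP profile has not been computed")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty_like(x)
        for k, xi in enumerate(x):
            i = min(max(np.searchsorted(self.boundaries, xi, side="right") - 1, 0),
                    len(self.S_start) - 1)
            pieces = self.atp_pieces[i]
            piece = pieces[-1]
            for p in pieces:
                if xi < p.x_abs + p.length or p is pieces[-1]:
                    piece = p
                    break
            out[k] = piece.value(min(max(xi - piece.x_abs, 0.0), piece.length))
        return out

    def sample(self, points_per_compartment: int = 25) -> pd.DataFrame:
        """Dense samples of S(x) and C_ATP(x) for export/plotting."""
        from .network import ORDER
        rows = []
        for i in range(len(self.S_start)):
            a, b = self.boundaries[i], self.boundaries[i + 1]
            xs = np.linspace(a, b, points_per_compartment)
            s = self.saturation(xs)
            c = self.atp(xs) if self.atp_pieces is not None else np.full_like(xs, np.nan)
            for x, sv, cv in zip(xs, s, c):
                rows.append((x, ORDER[i], sv, cv))
        return pd.DataFrame(rows, columns=["x_cm", "compartment",
                                           "saturation", "atp_uM"])


def saturation_profile(hemo, geom, params: OxygenParams, tissue) -> AxialProfile:
    """Axial saturation profile for the current hemodynamic state.

    Linear decline in exchanging compartments, floored at zero once
    depleted; constant through non-exchanging (artery and venous)
    compartments.
    """
    n = len(geom.segment_length_cm)
    bounds = np.concatenate([[0.0], np.cumsum(geom.segment_length_cm)])
    w = tissue.sleeve_width_um * UM_TO_CM
    m0_cgs = params.M0 / 100.0 / MIN_TO_S      # cm3 O2 / cm3 tissue / s
    cap = params.effective_capacity

    S_start = np.zeros(n)
    S_slope = np.zeros(n)
    S_end = np.zeros(n)
    dep_x = np.full(n, np.nan)
    s = params.S_in
    for i in range(n):
        L = geom.segment_length_cm[i]
        S_start[i] = s
        if geom.exchanges_oxygen[i] and m0_cgs > 0:
            D = geom.diameter_um[i] * UM_TO_CM
            sleeve = np.pi * w * (D + w)       # annulus area pi[(r+w)^2 - r^2]
            g = -m0_cgs * sleeve / (hemo.segment_flow_cm3_s[i] * cap)
        else:
            g = 0.0
        S_slope[i] = g
        if g < 0 and s + g * L < 0:
            dep_x[i] = bounds[i] + (-s / g)
            s = 0.0
        else:
            s = s + g * L
        S_end[i] = s
        if s <= 0.0:
            s = 0.0
    return AxialProfile(boundaries=bounds, S_start=S_start, S_slope=S_slope,
                        depletion_x=dep_x, S_end=S_end)


def atp_profile(profile: AxialProfile, hemo, geom,
                params: OxygenParams) -> AxialProfile:
    """Exact piecewise ATP solution along the pathway.

    Within each compartment the saturation is linear (possibly followed by
    a depleted piece at S = 0), so v C' = H_T R0 (1 - R1 S) - (4 k_d/D) C
    is linear with linear forcing and solves in closed form piece by piece;
    concentration is continuous at all junctions.
    """
    n = len(profile.S_start)
    pieces_all: List[List[_AtpPiece]] = []
    means = np.zeros(n)
    ends = np.zeros(n)
    c = params.C_atp_in
    for i in range(n):
        a, b = profile.boundaries[i], profile.boundaries[i + 1]
        L = b - a
        D = geom.diameter_um[i] * UM_TO_CM
        v = hemo.velocity_cm_s[i]
        alpha = params.HT * params.R0 / v          # uM / cm release scale
        beta = 4.0 * params.k_d / (v * D)          # 1/cm decay
        # split compartment at oxygen depletion if it occurs inside
        dep = profile.depletion_x[i]
        segs = []
        if np.isfinite(dep) and a < dep < b:
            segs.append((a, dep - a, profile.S_start[i], profile.S_slope[i]))
            segs.append((dep, b - dep, 0.0, 0.0))
        else:
            segs.append((a, L, profile.S_start[i], profile.S_slope[i]))
        comp_pieces = []
        accum = 0.0
        for (x_abs, el, s0, g) in segs:
            f0 = alpha * (1.0 - params.R1 * s0)
            f1 = alpha * params.R1 * g             # forcing f0 - f1*u
            if beta > 0:
                c1 = -f1 / beta
                c0 = (f0 - c1) / beta
                piece = _AtpPiece(x_abs, el, c0, c1, c - c0, beta)
            else:                                  # no degradation: pure integral
                piece = _AtpPiece(x_abs, el, c, f0, 0.0, 0.0, c2=-0.5 * f1)
            c_end = float(piece.value(el))
            comp_pieces.append(piece)
            if el > 0:
                accum += piece.mean() * el
            c = c_end
        pieces_all.append(comp_pieces)
        means[i] = accum / L if L > 0 else c
        ends[i] = c
    profile.atp_pieces = pieces_all
    profile.atp_mean_uM = means
    profile.atp_end_uM = ends
    return profile
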