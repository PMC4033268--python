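"""Quasi-steady network hemodynamics.

Flow through the serial network is resolved instantaneously for the current
diameters: each compartment is n identical Poiseuille resistors in
parallel, the thirteen compartments are in series, and a fixed pressure
drop is imposed from arteriolar inflow to venular outflow.  Inertia and
compliance are neglected — the wall time constants (seconds to tens of
seconds) dominate the dynamics, so the flow field is always in steady state
with respect to the instantaneous geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import MMHG_TO_DYN_CM2, CP_TO_POISE, UM_TO_CM

__all__ = ["HemodynamicState", "network_flow"]


@dataclass
class HemodynamicState:
    """Flow, pressure and shear fields for one network configuration."""

    total_flow_cm3_s: float
    segment_flow_cm3_s: np.ndarray
    inlet_pressure_mmHg: np.ndarray
    outlet_pressure_mmHg: np.ndarray
    midpoint_pressure_mmHg: np.ndarray
    wall_shear_dyn_cm2: np.ndarray
    velocity_cm_s: np.ndarray
    compartment_resistance: np.ndarray  # dyn s cm^-5


def network_flow(diameter_um, geom, p_in_mmHg=None, p_out_mmHg=None) -> HemodynamicState:
    """Solve the series network for the given compartment diameters.

    Parameters
    ----------
    diameter_um : array (13,)
        Current luminal diameters.  Non-vasoactive compartments are simply
        passed through at their (fixed) reference diameters by the caller.
    geom :
        Any object with ``viscosity_cP``, ``segment_length_cm`` and
        ``segment_count`` arrays (normally a ``ReferenceState``).
    p_in_mmHg, p_out_mmHg : float, optional
        Boundary pressures; default to the reference boundary pressures of
        ``geom`` (constant-pressure-drop boundary condition).
    """
    D = np.asarray(diameter_um, dtype=float) * UM_TO_CM
    if np.any(D <= 0):
        raise ValueError("all diameters must be positive for the flow solve")
    mu = geom.viscosity_cP * CP_TO_POISE
    L = geom.segment_length_cm
    n = geom.segment_count
    if p_in_mmHg is None:
        p_in_mmHg = geom.inlet_pressure_mmHg
    if p_out_mmHg is None:
        p_out_mmHg = geom.outlet_pressure_mmHg

    r_seg = 128.0 * mu * L / (np.pi * D ** 4)
    r_comp = r_seg / n
    dp_total = (p_in_mmHg - p_out_mmHg) * MMHG_TO_DYN_CM2
    q_total = dp_total / r_comp.sum()
    q_seg = q_total / n
    dp = q_total * r_comp / MMHG_TO_DYN_CM2
    p_nodes = p_in_mmHg - np.concatenate([[0.0], np.cumsum(dp)])
    tau_wall = 32.0 * mu * q_seg / (np.pi * D ** 3)
    v = q_seg / (np.pi / 4.0 * D ** 2)
    return HemodynamicState(
        total_flow_cm3_s=float(q_total),
        segment_flow_cm3_s=q_seg,
        inlet_pressure_mmHg=p_nodes[:-1],
        outlet_pressure_mmHg=p_nodes[1:],
        midpoint_pressure_mmHg=0.5 * (p_nodes[:-1] + p_nodes[1:]),
        wall_shear_dyn_cm2=tau_wall,
        velocity_cm_s=v,
        compartment_resistance=r_comp,
    )
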