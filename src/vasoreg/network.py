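"""Reference network construction and calibration.

The vasculature of a skeletal-muscle region is abstracted as thirteen
compartments in series — artery (A), feed artery (FA), three arteriolar
orders (1A, 2A, 3A), terminal arterioles (TA), capillaries (C), and the
mirrored venous orders (TV, 1V, 2V, 3V, DV, V).  Each compartment stands
for n identical parallel segments, so the whole network is a single
"representative" flow pathway with per-compartment parallel-conductance
multipliers.

The reference (resting) state is specified by a small set of primary
quantities — arteriolar diameters, wall shear stresses, pressure drops and
the artery segment length — from which everything else follows:

* mean velocity      v = tau * D / (8 mu)          (Poiseuille wall shear)
* segment length     L = dP * D / (4 tau)          (axial force balance)
* segment flow       Q_seg = (pi/4) D^2 v
* segment counts     n_i = n_FA * Q_FA / Q_seg_i   (flow conservation)

Venous compartments mirror the segment counts and lengths of their arterial
counterparts across the capillary bed and take their diameters from the
specified venous wall shear via Q_seg = pi tau D^3 / (32 mu).

Finally, the tone offsets C''_tone of the vasoactive compartments are
calibrated so that the resting network is an exact fixed point of the
diameter/activation dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .units import MMHG_TO_DYN_CM2, CP_TO_POISE, UM_TO_CM
from .viscosity import in_vivo_viscosity
from .wall import (VasoactiveWallSet, passive_tension, max_active_tension,
                   inverse_target_activation)

__all__ = [
    "ORDER", "VASOACTIVE", "MIRROR",
    "ConfigurationError", "NetworkValidationError", "CalibrationError",
    "CompartmentSpec", "TissueGeometry", "ReferenceState",
    "derive_geometry", "derive_venous_diameters", "compute_volumes",
    "calibrate_tone_constants", "build_reference_state",
]

#: Fixed serial order of the thirteen compartments.
ORDER = ("A", "FA", "1A", "2A", "3A", "TA", "C",
         "TV", "1V", "2V", "3V", "DV", "V")

#: Compartments with actively regulating smooth muscle.
VASOACTIVE = ("FA", "1A", "2A", "3A", "TA")

#: Venous compartments and the arterial counterparts whose segment counts
#: and lengths they mirror across the capillary bed.
MIRROR = {"TV": "TA", "1V": "3A", "2V": "2A", "3V": "1A", "DV": "FA", "V": "A"}

_ARTERIAL = ("A", "FA", "1A", "2A", "3A", "TA", "C")
_VENOUS = ("TV", "1V", "2V", "3V", "DV", "V")


class ConfigurationError(ValueError):
    """A required field is missing or inconsistent in a network spec."""


class NetworkValidationError(ValueError):
    """A derived quantity violates a physical constraint."""


class CalibrationError(RuntimeError):
    """Reference-state calibration produced an inadmissible activation."""


@dataclass(frozen=True)
class CompartmentSpec:
    """Primary (specified) quantities for one vessel class.

    Only the fields that are primary for the given compartment need to be
    set; the rest are derived.  For the artery the segment length is
    specified and the diameter derived; for FA..C it is the reverse; venous
    compartments specify only wall shear and viscosity.
    """

    name: str
    wall_shear_dyn_cm2: float
    viscosity_cP: Optional[float] = None
    diameter_um: Optional[float] = None
    dp_mmHg: Optional[float] = None
    length_cm: Optional[float] = None
    vasoactive: bool = False
    exchanges_oxygen: bool = False

    def __post_init__(self):
        if self.wall_shear_dyn_cm2 <= 0:
            raise NetworkValidationError(f"{self.name}: wall shear must be positive")
        if self.viscosity_cP is not None and self.viscosity_cP <= 0:
            raise NetworkValidationError(f"{self.name}: viscosity must be positive")
        if self.diameter_um is not None and self.diameter_um <= 0:
            raise NetworkValidationError(f"{self.name}: diameter must be positive")


@dataclass(frozen=True)
class TissueGeometry:
    """Geometry of the oxygen-consuming tissue.

    ``sleeve_width_um`` is the thickness of the tissue sleeve supplied by
    each exchanging vessel; ``capillary_density_mm2`` the number of
    capillaries per mm^2 of tissue cross-section, which converts total
    capillary length into tissue volume.
    """

    sleeve_width_um: float = 18.8
    capillary_density_mm2: float = 500.0

    def __post_init__(self):
        if self.sleeve_width_um <= 0 or self.capillary_density_mm2 <= 0:
            raise NetworkValidationError("tissue geometry values must be positive")


@dataclass
class ReferenceState:
    """Fully derived resting network, plus calibration results.

    Per-compartment arrays are aligned with :data:`ORDER`.  The calibration
    block (A_ref, C_tone, T_c, D_c) is aligned with :data:`VASOACTIVE` and
    populated by :func:`calibrate_tone_constants`.
    """

    names: tuple = ORDER
    vasoactive: np.ndarray = None
    exchanges_oxygen: np.ndarray = None
    diameter_um: np.ndarray = None
    wall_shear_dyn_cm2: np.ndarray = None
    dp_mmHg: np.ndarray = None
    viscosity_cP: np.ndarray = None
    segment_count: np.ndarray = None
    segment_length_cm: np.ndarray = None
    velocity_cm_s: np.ndarray = None
    segment_flow_cm3_s: np.ndarray = None
    volume_fraction_pct: np.ndarray = None
    total_flow_cm3_s: float = None
    total_pressure_drop_mmHg: float = None
    pathway_length_cm: float = None
    tissue_volume_cm3: float = None
    inlet_pressure_mmHg: float = 100.0
    # calibration block (per vasoactive compartment)
    A_ref: np.ndarray = None
    C_tone: np.ndarray = None
    T_c_dyn_cm: np.ndarray = None
    D_c_um: np.ndarray = None
    midpoint_pressure_mmHg: np.ndarray = None
    S_CR_ref: np.ndarray = None
    S_tone_ref: np.ndarray = None

    @property
    def outlet_pressure_mmHg(self) -> float:
        return self.inlet_pressure_mmHg - self.total_pressure_drop_mmHg

    @property
    def vaso_indices(self) -> np.ndarray:
        return np.flatnonzero(self.vasoactive)

    def boundaries(self) -> np.ndarray:
        """Axial coordinates of compartment boundaries along the pathway (cm)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_length_cm)])

    def midpoints(self) -> np.ndarray:
        b = self.boundaries()
        return 0.5 * (b[:-1] + b[1:])

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        """The derived network as a table (one row per compartment)."""
        return pd.DataFrame({
            "compartment": list(self.names),
            "diameter_um": self.diameter_um,
            "wall_shear_dyn_cm2": self.wall_shear_dyn_cm2,
            "dp_mmHg": self.dp_mmHg,
            "segment_count": self.segment_count,
            "segment_length_cm": self.segment_length_cm,
            "velocity_cm_s": self.velocity_cm_s,
            "viscosity_cP": self.viscosity_cP,
            "segment_flow_cm3_s": self.segment_flow_cm3_s,
            "volume_fraction_pct": self.volume_fraction_pct,
            "vasoactive": self.vasoactive,
        })

    def summary(self) -> dict:
        out = {
            "total_flow_cm3_s": float(self.total_flow_cm3_s),
            "total_pressure_drop_mmHg": float(self.total_pressure_drop_mmHg),
            "pathway_length_cm": float(self.pathway_length_cm),
            "tissue_volume_cm3": float(self.tissue_volume_cm3),
            "total_volume_pct": float(np.sum(self.volume_fraction_pct)),
            "inlet_pressure_mmHg": float(self.inlet_pressure_mmHg),
            "outlet_pressure_mmHg": float(self.outlet_pressure_mmHg),
        }
        if self.C_tone is not None:
            out["C_tone"] = {c: float(v) for c, v in zip(VASOACTIVE, self.C_tone)}
            out["A_ref"] = {c: float(v) for c, v in zip(VASOACTIVE, self.A_ref)}
        return out


def _require(spec: CompartmentSpec, fname: str):
    val = getattr(spec, fname)
    if val is None:
        raise ConfigurationError(
            f"compartment {spec.name}: required field {fname!r} is missing")
    return val


def _check_specs(specs: Sequence[CompartmentSpec]):
    names = tuple(s.name for s in specs)
    if names != ORDER:
        raise ConfigurationError(
            f"expected the 13 compartments in order {ORDER}, got {names}")
    for s in specs:
        if s.vasoactive != (s.name in VASOACTIVE):
            raise ConfigurationError(
                f"compartment {s.name}: vasoactive flag must be "
                f"{s.name in VASOACTIVE} in the serial network")


def derive_geometry(specs: Sequence[CompartmentSpec],
                    discharge_hematocrit: float = 0.4) -> ReferenceState:
    """Derive arterial/capillary geometry and hemodynamics from a spec list.

    Viscosities left unspecified are taken from the in-vivo viscosity law at
    the compartment diameter and the given discharge hematocrit.  Returns a
    partially filled :class:`ReferenceState` (venous diameters, volumes and
    calibration still absent).
    """
    _check_specs(specs)
    by_name = {s.name: s for s in specs}
    n13 = len(ORDER)
    ref = ReferenceState(
        vasoactive=np.array([s.vasoactive for s in specs]),
        exchanges_oxygen=np.array([s.exchanges_oxygen for s in specs]),
        diameter_um=np.full(n13, np.nan),
        wall_shear_dyn_cm2=np.array([s.wall_shear_dyn_cm2 for s in specs]),
        dp_mmHg=np.full(n13, np.nan),
        viscosity_cP=np.full(n13, np.nan),
        segment_count=np.full(n13, np.nan),
        segment_length_cm=np.full(n13, np.nan),
        velocity_cm_s=np.full(n13, np.nan),
        segment_flow_cm3_s=np.full(n13, np.nan),
    )

    # Artery: diameter follows from its specified length, shear and drop.
    a = by_name["A"]
    L_A = _require(a, "length_cm")
    dp_A = _require(a, "dp_mmHg")
    if dp_A <= 0:
        raise NetworkValidationError("A: pressure drop must be positive")
    D_A_cm = 4.0 * a.wall_shear_dyn_cm2 * L_A / (dp_A * MMHG_TO_DYN_CM2)

    for i, name in enumerate(_ARTERIAL):
        s = by_name[name]
        if name == "A":
            D_cm = D_A_cm
        else:
            D_cm = _require(s, "diameter_um") * UM_TO_CM
        dp = _require(s, "dp_mmHg")
        mu_cP = s.viscosity_cP
        if mu_cP is None:
            mu_cP = in_vivo_viscosity(D_cm / UM_TO_CM, discharge_hematocrit)
        mu = mu_cP * CP_TO_POISE
        tau = s.wall_shear_dyn_cm2
        v = tau * D_cm / (8.0 * mu)
        L = L_A if name == "A" else dp * MMHG_TO_DYN_CM2 * D_cm / (4.0 * tau)
        if L <= 0 or v <= 0 or D_cm <= 0:
            raise NetworkValidationError(
                f"compartment {name}: non-positive derived geometry "
                f"(L={L:.4g} cm, v={v:.4g} cm/s, D={D_cm:.4g} cm)")
        q = np.pi / 4.0 * D_cm ** 2 * v
        ref.diameter_um[i] = D_cm / UM_TO_CM
        ref.dp_mmHg[i] = dp
        ref.viscosity_cP[i] = mu_cP
        ref.velocity_cm_s[i] = v
        ref.segment_length_cm[i] = L
        ref.segment_flow_cm3_s[i] = q

    # Segment counts from flow conservation, FA as the unit reference.
    i_FA = ORDER.index("FA")
    q_FA = ref.segment_flow_cm3_s[i_FA]
    for i, name in enumerate(_ARTERIAL):
        ref.segment_count[i] = q_FA / ref.segment_flow_cm3_s[i]
    ref.total_flow_cm3_s = q_FA  # n_FA = 1 by construction
    return ref


def derive_venous_diameters(ref: ReferenceState,
                            specs: Sequence[CompartmentSpec]) -> ReferenceState:
    """Fill in the venous side of a partially derived reference state.

    Venous segment counts and lengths mirror their arterial counterparts;
    diameters solve the Poiseuille shear identity Q_seg = pi tau D^3/(32 mu)
    for the specified venous wall shear and viscosity, and pressure drops
    follow from the axial force balance dP = 4 tau L / D.
    """
    by_name = {s.name: s for s in specs}
    for name in _VENOUS:
        i = ORDER.index(name)
        j = ORDER.index(MIRROR[name])
        s = by_name[name]
        n = ref.segment_count[j]
        L = ref.segment_length_cm[j]
        q = ref.total_flow_cm3_s / n
        mu_cP = _require(s, "viscosity_cP")
        mu = mu_cP * CP_TO_POISE
        tau = s.wall_shear_dyn_cm2
        arg = 32.0 * mu * q / (np.pi * tau)
        if arg <= 0:
            raise NetworkValidationError(
                f"compartment {name}: non-physical cube-root argument {arg:.4g}")
        D_cm = arg ** (1.0 / 3.0)
        ref.segment_count[i] = n
        ref.segment_length_cm[i] = L
        ref.segment_flow_cm3_s[i] = q
        ref.viscosity_cP[i] = mu_cP
        ref.diameter_um[i] = D_cm / UM_TO_CM
        ref.velocity_cm_s[i] = q / (np.pi / 4.0 * D_cm ** 2)
        ref.dp_mmHg[i] = 4.0 * tau * L / D_cm / MMHG_TO_DYN_CM2
    ref.total_pressure_drop_mmHg = float(np.sum(ref.dp_mmHg))
    ref.pathway_length_cm = float(np.sum(ref.segment_length_cm))
    return ref


def compute_volumes(ref: ReferenceState, tissue: TissueGeometry) -> ReferenceState:
    """Tissue volume and per-compartment vascular volume fractions (%).

    The tissue volume follows from total capillary length and the areal
    capillary density; each compartment's luminal volume n*L*(pi/4)*D^2 is
    then expressed as a percentage of it.
    """
    i_C = ORDER.index("C")
    density_cm2 = tissue.capillary_density_mm2 * 100.0  # mm^-2 -> cm^-2
    ref.tissue_volume_cm3 = float(
        ref.segment_count[i_C] * ref.segment_length_cm[i_C] / density_cm2)
    lumen = (ref.segment_count * ref.segment_length_cm
             * np.pi / 4.0 * (ref.diameter_um * UM_TO_CM) ** 2)
    ref.volume_fraction_pct = 100.0 * lumen / ref.tissue_volume_cm3
    return ref


def calibrate_tone_constants(ref: ReferenceState,
                             walls: VasoactiveWallSet,
                             oxygen_params,
                             signal_params,
                             tissue: TissueGeometry,
                             rest_demand: float = 1.0) -> ReferenceState:
    """Calibrate C''_tone so the resting network is an exact fixed point.

    At the reference diameters, the activation that balances the wall
    tension T = P*D/2 is A_ref = (T - T_pass)/T_act_max; the stimulus that
    targets exactly that activation is S_tone_ref = logit(A_ref); and the
    tone offset absorbs whatever the resting myogenic, shear and conducted
    metabolic signals do not account for:

        C''_tone = S_tone_ref - C_myo T + C_shear tau_wall - C_symp + S_CR

    evaluated at rest (C_symp = 0, resting oxygen demand).
    """
    from . import hemodynamics as hemo_mod
    from . import oxygen as oxy_mod
    from . import conducted as cr_mod
    from dataclasses import replace as dc_replace

    hemo = hemo_mod.network_flow(ref.diameter_um, ref)
    oxy_rest = dc_replace(oxygen_params, M0=rest_demand)
    profile = oxy_mod.saturation_profile(hemo, ref, oxy_rest, tissue)
    profile = oxy_mod.atp_profile(profile, hemo, ref, oxy_rest)
    s_loc = cr_mod.local_signal(profile, signal_params)
    response = cr_mod.ConductedResponse(ref, signal_params)
    field = response.compute(s_loc)
    scr = field.at_evaluation_points

    vi = ref.vaso_indices
    D_um = ref.diameter_um[vi]
    p_mid = hemo.midpoint_pressure_mmHg[vi]
    tau_w = hemo.wall_shear_dyn_cm2[vi]
    T_ref = p_mid * MMHG_TO_DYN_CM2 * (D_um * UM_TO_CM) / 2.0

    t_pass = passive_tension(D_um, walls)
    t_act = max_active_tension(D_um, walls)
    A_ref = (T_ref - t_pass) / t_act
    bad = (A_ref <= 0.0) | (A_ref >= 1.0)
    if np.any(bad):
        names = [c for c, b in zip(walls.compartments, bad) if b]
        raise CalibrationError(
            f"reference activation outside (0, 1) for {names}: "
            f"{A_ref[bad]} — wall parameters inconsistent with the reference state")
    s_tone_ref = inverse_target_activation(A_ref)
    c_tone = s_tone_ref - walls.C_myo * T_ref + walls.C_shear * tau_w + scr

    walls.set_tone(c_tone)
    ref.A_ref = A_ref
    ref.C_tone = c_tone
    ref.T_c_dyn_cm = T_ref
    ref.D_c_um = D_um.copy()
    ref.midpoint_pressure_mmHg = p_mid
    ref.S_CR_ref = scr
    ref.S_tone_ref = s_tone_ref
    return ref


def build_reference_state(specs: Sequence[CompartmentSpec],
                          walls: VasoactiveWallSet,
                          oxygen_params,
                          signal_params,
                          tissue: Optional[TissueGeometry] = None,
                          rest_demand: float = 1.0) -> ReferenceState:
    """Run the full derivation + calibration pipeline for a network spec."""
    tissue = tissue or TissueGeometry()
    hd = getattr(oxygen_params, "hematocrit_discharge", 0.4)
    ref = derive_geometry(specs, discharge_hematocrit=hd)
    ref = derive_venous_diameters(ref, specs)
    ref = compute_volumes(ref, tissue)
    ref = calibrate_tone_constants(ref, walls, oxygen_params, signal_params,
                                   tissue, rest_demand=rest_demand)
    return ref
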