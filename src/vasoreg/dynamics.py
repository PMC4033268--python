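"""Time-dependent diameter and activation dynamics.

The five vasoactive compartments evolve under

    dD/dt = (1/tau_d) * (D_c/T_c) * (T - T_total),
    dA/dt = (A_total - A) / tau_a,

where T = P*D/2 is the wall tension imposed by the (midpoint) transmural
pressure, T_total the tension the wall currently generates, A_total the
sigmoidal target activation set by the net stimulus S_tone, and the
subscript c marks the calibrated reference (control) state.  A vessel
whose imposed tension exceeds its generated tension distends; one that is
targeted to more activation than it has slowly constricts, with tau_d = 1 s
(diameter) fast relative to tau_a = 20 s (activation).

At every time step the hemodynamic, oxygen/ATP and conducted-signal fields
are re-solved for the instantaneous diameters (quasi-steady closure:
metabolic signal generation and conduction are treated as instantaneous).
Protocols are piecewise-constant time courses of the sympathetic stimulus
C_symp and the oxygen demand M0, with an optional directive to lock the
conducted metabolic signal for sympatholysis control experiments.

Integration is explicit fixed-step Euler (default dt = 10 ms) — the
dynamics are mildly stiff at worst, and a fixed step makes runs exactly
reproducible; halve ``dt`` to verify convergence of any result.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .units import MMHG_TO_DYN_CM2, UM_TO_CM
from .network import ReferenceState, TissueGeometry, VASOACTIVE
from .wall import (VasoactiveWallSet, passive_tension, max_active_tension,
                   target_activation)
from .hemodynamics import network_flow
from .oxygen import OxygenParams, saturation_profile, atp_profile
from .conducted import SignalParams, ConductedResponse, local_signal

__all__ = ["Protocol", "NetworkState", "SimulationResult", "NetworkModel",
           "IntegrationError", "SNA_LEVELS", "DEMAND_LEVELS", "simulate"]

#: Named sympathetic stimulation levels: low, intermediate, high.
SNA_LEVELS = {"L": 1.0, "I": 2.0, "H": 4.0}

#: Named oxygen-demand levels: rest and three duty cycles of rhythmic
#: contraction (cm^3 O2 / 100 cm^3 / min).
DEMAND_LEVELS = {"rest": 1.0, "DC2.5": 1.91, "DC10": 4.64, "DC20": 8.28}


class IntegrationError(RuntimeError):
    """The explicit integrator produced a non-physical state."""


@dataclass(frozen=True)
class Protocol:
    """Piecewise-constant stimulus/demand time course.

    ``epochs`` is an ordered list of (start_time_s, C_symp, M0); each epoch
    holds until the next start time or the end of the protocol.  If
    ``lock_metabolic_at_s`` is set, the conducted metabolic signal is
    frozen at its value immediately prior to that time for the remainder of
    the run.
    """

    epochs: Tuple[Tuple[float, float, float], ...]
    duration_s: float
    lock_metabolic_at_s: Optional[float] = None

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("protocol must contain at least one epoch")
        times = [e[0] for e in self.epochs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if times[0] > 0:
            raise ValueError("first epoch must start at t <= 0")
        for t, cs, m0 in self.epochs:
            if cs < 0:
                raise ValueError("C_symp must be non-negative")
            if m0 <= 0:
                raise ValueError("M0 must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    def values_at(self, t: float) -> Tuple[float, float]:
        """(C_symp, M0) active at time t."""
        idx = bisect.bisect_right([e[0] for e in self.epochs], t) - 1
        _, cs, m0 = self.epochs[max(idx, 0)]
        return cs, m0

    @classmethod
    def constant(cls, C_symp: float = 0.0, M0: float = 1.0,
                 duration_s: float = 60.0, **kw) -> "Protocol":
        return cls(epochs=((0.0, C_symp, M0),), duration_s=duration_s, **kw)

    @classmethod
    def sna_pulse(cls, level="I", demand="rest", pre_s: float = 30.0,
                  pulse_s: float = 30.0, post_s: float = 60.0,
                  lock_metabolic: bool = False) -> "Protocol":
        """Pre-pulse baseline, a square SNA pulse, and recovery.

        ``level`` is a named SNA level (L/I/H) or a numeric C_symp;
        ``demand`` a named duty-cycle level or a numeric M0, held constant
        throughout.
        """
        cs = SNA_LEVELS.get(level, level)
        m0 = DEMAND_LEVELS.get(demand, demand)
        epochs = [(0.0, 0.0, float(m0)),
                  (float(pre_s), float(cs), float(m0)),
                  (float(pre_s + pulse_s), 0.0, float(m0))]
        if pre_s == 0:
            epochs = epochs[1:]
            epochs[0] = (0.0, float(cs), float(m0))
        return cls(epochs=tuple(epochs), duration_s=pre_s + pulse_s + post_s,
                   lock_metabolic_at_s=pre_s if lock_metabolic else None)

    @property
    def sna_window(self) -> Optional[Tuple[float, float]]:
        """(start, end) of the first epoch with elevated C_symp, if any."""
        start = None
        for (t, cs, _m0) in self.epochs:
            if start is None and cs > 0:
                start = t
            elif start is not None and cs == 0:
                return (start, t)
        return (start, self.duration_s) if start is not None else None


@dataclass
class NetworkState:
    """Instantaneous state of the vasoactive compartments."""

    t: float
    D_um: np.ndarray
    A: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(self.t, self.D_um.copy(), self.A.copy())


@dataclass
class SimulationResult:
    """Recorded time series of a protocol run.

    Per-compartment arrays have shape (n_times, n_vasoactive) and are
    aligned with ``compartments``.  The four stimulus components satisfy
    S_tone = S_myo + S_shear + S_symp + S_meta + C''_tone at every sample.
    """

    time: np.ndarray
    compartments: Tuple[str, ...]
    D_um: np.ndarray
    A: np.ndarray
    A_total: np.ndarray
    S_tone: np.ndarray
    S_myo: np.ndarray
    S_shear: np.ndarray
    S_symp: np.ndarray
    S_meta: np.ndarray
    total_flow_cm3_s: np.ndarray
    C_symp: np.ndarray
    M0: np.ndarray
    max_drift_um_s: np.ndarray
    steady_epochs: List[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def index(self, compartment: str) -> int:
        return self.compartments.index(compartment)

    def final_state(self) -> NetworkState:
        return NetworkState(float(self.time[-1]), self.D_um[-1].copy(),
                            self.A[-1].copy())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimulationResult":
        """Rebuild a result from its long-format export (metadata absent)."""
        comp_vars = ("D_um", "A", "A_total", "S_tone", "S_myo", "S_shear",
                     "S_symp", "S_meta")
        comps = tuple(c for c in VASOACTIVE
                      if c in set(df["compartment"].unique()))
        time = np.sort(df["time_s"].unique())
        arrays = {}
        for var in comp_vars:
            sub = df[df["variable"] == var].pivot(
                index="time_s", columns="compartment", values="value")
            arrays[var] = sub[list(comps)].to_numpy()
        net = {v: df[(df["variable"] == v) & (df["compartment"] == "network")]
               .sort_values("time_s")["value"].to_numpy()
               for v in ("Q_cm3_s", "C_symp", "M0")}
        return cls(time=time, compartments=comps,
                   D_um=arrays["D_um"], A=arrays["A"],
                   A_total=arrays["A_total"], S_tone=arrays["S_tone"],
                   S_myo=arrays["S_myo"], S_shear=arrays["S_shear"],
                   S_symp=arrays["S_symp"], S_meta=arrays["S_meta"],
                   total_flow_cm3_s=net["Q_cm3_s"], C_symp=net["C_symp"],
                   M0=net["M0"],
                   max_drift_um_s=np.full(len(time), np.nan))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, compartment, variable, value."""
        per_comp = {"D_um": self.D_um, "A": self.A, "A_total": self.A_total,
                    "S_tone": self.S_tone, "S_myo": self.S_myo,
                    "S_shear": self.S_shear, "S_symp": self.S_symp,
                    "S_meta": self.S_meta}
        frames = []
        for var, arr in per_comp.items():
            for j, comp in enumerate(self.compartments):
                frames.append(pd.DataFrame({
                    "time_s": self.time, "compartment": comp,
                    "variable": var, "value": arr[:, j]}))
        for var, arr in (("Q_cm3_s", self.total_flow_cm3_s),
                         ("C_symp", self.C_symp), ("M0", self.M0)):
            frames.append(pd.DataFrame({
                "time_s": self.time, "compartment": "network",
                "variable": var, "value": arr}))
        return pd.concat(frames, ignore_index=True)


class NetworkModel:
    """The calibrated network with its quasi-steady field closure.

    Couples wall mechanics, series hemodynamics, axial oxygen/ATP transport
    and the upstream-conducted metabolic signal into the diameter and
    activation ODEs, starting from a calibrated reference state.
    """

    def __init__(self, ref: ReferenceState, walls: VasoactiveWallSet,
                 oxygen: OxygenParams, signal: SignalParams,
                 tissue: Optional[TissueGeometry] = None,
                 dt_s: float = 0.01, record_dt_s: float = 0.1,
                 steady_tol_um_s: float = 1e-6, eval_at: str = "midpoint"):
        if ref.C_tone is None or walls.C_tone is None:
            raise ValueError("reference state must be calibrated before simulation")
        self.ref = ref
        self.walls = walls
        self.oxygen = oxygen
        self.signal = signal
        self.tissue = tissue or TissueGeometry()
        self.dt_s = float(dt_s)
        self.record_dt_s = float(record_dt_s)
        self.steady_tol_um_s = float(steady_tol_um_s)
        self.response = ConductedResponse(ref, signal, eval_at=eval_at)
        self._vi = ref.vaso_indices
        self._D_full = ref.diameter_um.copy()

    # -- field closure ----------------------------------------------------
    def compute_fields(self, D_vaso_um, M0: float):
        """Quasi-steady hemodynamic + metabolic fields for given diameters.

        Returns (hemo, profile, conducted_field); respects an active lock
        on the conducted response.
        """
        D = self._D_full.copy()
        D[self._vi] = D_vaso_um
        hemo = network_flow(D, self.ref)
        geom = _GeomView(self.ref, D)
        oxy = self.oxygen if self.oxygen.M0 == M0 else replace(self.oxygen, M0=M0)
        profile = saturation_profile(hemo, geom, oxy, self.tissue)
        profile = atp_profile(profile, hemo, geom, oxy)
        s_loc = local_signal(profile, self.signal)
        cr = self.response.compute(s_loc)
        return hemo, profile, cr

    def stimulus_components(self, D_vaso_um, A, C_symp: float, M0: float):
        """All wall-model quantities for one state; used by step and output."""
        hemo, profile, cr = self.compute_fields(D_vaso_um, M0)
        vi = self._vi
        p_mid = hemo.midpoint_pressure_mmHg[vi]
        tau_w = hemo.wall_shear_dyn_cm2[vi]
        T = p_mid * MMHG_TO_DYN_CM2 * (D_vaso_um * UM_TO_CM) / 2.0
        s_myo = self.walls.C_myo * T
        s_shear = -self.walls.C_shear * tau_w
        s_meta = -cr.at_evaluation_points
        s_tone = s_myo + s_shear + C_symp + s_meta + self.walls.C_tone
        a_total = target_activation(s_tone)
        t_total = (passive_tension(D_vaso_um, self.walls)
                   + A * max_active_tension(D_vaso_um, self.walls))
        return dict(hemo=hemo, profile=profile, conducted=cr, T=T,
                    T_total=t_total, S_myo=s_myo, S_shear=s_shear,
                    S_symp=C_symp, S_meta=s_meta, S_tone=s_tone,
                    A_total=a_total)

    # -- integration ------------------------------------------------------
    def derivatives(self, state: NetworkState, C_symp: float, M0: float):
        f = self.stimulus_components(state.D_um, state.A, C_symp, M0)
        dD = (self.ref.D_c_um / self.ref.T_c_dyn_cm) \
            * (f["T"] - f["T_total"]) / self.walls.tau_d_s
        dA = (f["A_total"] - state.A) / self.walls.tau_a_s
        return dD, dA, f

    def step(self, state: NetworkState, dt: float,
             C_symp: float, M0: float) -> NetworkState:
        """Advance one explicit Euler step; activation clamped to [0, 1]."""
        dD, dA, _ = self.derivatives(state, C_symp, M0)
        D = state.D_um + dt * dD
        if np.any(D <= 0):
            raise IntegrationError(
                f"diameter became non-positive at t={state.t:.3f} s; "
                "reduce the time step")
        A = np.clip(state.A + dt * dA, 0.0, 1.0)
        return NetworkState(state.t + dt, D, A)

    def reference_state_vector(self) -> NetworkState:
        return NetworkState(0.0, self.ref.D_c_um.copy(), self.ref.A_ref.copy())

    def simulate(self, protocol: Protocol,
                 initial: Optional[NetworkState] = None) -> SimulationResult:
        """Integrate a protocol from the calibrated reference state.

        Fields are re-solved every step; the state is recorded at the
        output cadence; steady-state attainment (max |dD/dt| below the
        tolerance) is reported for every protocol epoch.
        """
        dt = self.dt_s
        n_steps = int(round(protocol.duration_s / dt))
        rec_every = max(int(round(self.record_dt_s / dt)), 1)
        state = (initial.copy() if initial is not None
                 else self.reference_state_vector())
        state.t = 0.0
        self.response.unlock()
        lock_t = protocol.lock_metabolic_at_s

        nv = len(self._vi)
        rec: dict = {k: [] for k in ("t", "D", "A", "A_total", "S_tone",
                                     "S_myo", "S_shear", "S_symp", "S_meta",
                                     "Q", "C_symp", "M0", "drift")}
        epoch_starts = [e[0] for e in protocol.epochs]
        epoch_rate = np.full(len(epoch_starts), np.nan)

        def record(f, dD, cs, m0, t):
            rec["t"].append(t)
            rec["D"].append(state.D_um.copy())
            rec["A"].append(state.A.copy())
            rec["A_total"].append(f["A_total"].copy())
            rec["S_tone"].append(f["S_tone"].copy())
            rec["S_myo"].append(f["S_myo"].copy())
            rec["S_shear"].append(f["S_shear"].copy())
            rec["S_symp"].append(np.full(nv, f["S_symp"]))
            rec["S_meta"].append(f["S_meta"].copy())
            rec["Q"].append(f["hemo"].total_flow_cm3_s)
            rec["C_symp"].append(cs)
            rec["M0"].append(m0)
            rec["drift"].append(np.max(np.abs(dD)))

        for k in range(n_steps + 1):
            t = k * dt
            if lock_t is not None and not self.response.locked and t >= lock_t:
                cs_pre, m0_pre = protocol.values_at(min(lock_t, t) - 1e-9)
                _, _, cr = self.compute_fields(state.D_um, m0_pre)
                self.response.lock(cr)
            cs, m0 = protocol.values_at(t)
            dD, dA, f = self.derivatives(state, cs, m0)
            ei = bisect.bisect_right(epoch_starts, t) - 1
            epoch_rate[ei] = np.max(np.abs(dD))
            if k % rec_every == 0 or k == n_steps:
                record(f, dD, cs, m0, t)
            if k == n_steps:
                break
            D = state.D_um + dt * dD
            if np.any(D <= 0):
                raise IntegrationError(
                    f"diameter became non-positive at t={t:.3f} s; "
                    "reduce the time step")
            state = NetworkState(t + dt, D,
                                 np.clip(state.A + dt * dA, 0.0, 1.0))
        self.response.unlock()

        steady = [{"epoch": i, "t_start_s": epoch_starts[i],
                   "C_symp": protocol.epochs[i][1], "M0": protocol.epochs[i][2],
                   "final_drift_um_s": float(epoch_rate[i]),
                   "steady": bool(epoch_rate[i] < self.steady_tol_um_s)}
                  for i in range(len(epoch_starts))
                  if np.isfinite(epoch_rate[i])]
        return SimulationResult(
            time=np.array(rec["t"]),
            compartments=tuple(VASOACTIVE),
            D_um=np.array(rec["D"]), A=np.array(rec["A"]),
            A_total=np.array(rec["A_total"]), S_tone=np.array(rec["S_tone"]),
            S_myo=np.array(rec["S_myo"]), S_shear=np.array(rec["S_shear"]),
            S_symp=np.array(rec["S_symp"]), S_meta=np.array(rec["S_meta"]),
            total_flow_cm3_s=np.array(rec["Q"]),
            C_symp=np.array(rec["C_symp"]), M0=np.array(rec["M0"]),
            max_drift_um_s=np.array(rec["drift"]),
            steady_epochs=steady,
            metadata={"dt_s": dt, "record_dt_s": self.record_dt_s,
                      "lock_metabolic_at_s": lock_t,
                      "epochs": list(protocol.epochs)})

    def steady_state(self, C_symp: float = 0.0, M0: float = 1.0,
                     initial: Optional[NetworkState] = None,
                     t_max_s: float = 600.0,
                     check_every_s: float = 1.0) -> Tuple[NetworkState, bool]:
        """Integrate under constant inputs until the diameter drift falls
        below the steady tolerance (or ``t_max_s`` elapses).

        Returns the final state and whether steadiness was reached.
        """
        dt = self.dt_s
        state = (initial.copy() if initial is not None
                 else self.reference_state_vector())
        check_every = max(int(round(check_every_s / dt)), 1)
        n_max = int(round(t_max_s / dt))
        # the diameter drift alone is blind to a state whose tensions balance
        # while the activation is still moving, so require both to be settled
        tol_A = self.steady_tol_um_s / 10.0
        for k in range(n_max):
            dD, dA, _ = self.derivatives(state, C_symp, M0)
            if (k % check_every == 0
                    and np.max(np.abs(dD)) < self.steady_tol_um_s
                    and np.max(np.abs(dA)) < tol_A):
                return state, True
            D = state.D_um + dt * dD
            if np.any(D <= 0):
                raise IntegrationError("diameter became non-positive during "
                                       "equilibration; reduce the time step")
            state = NetworkState(state.t + dt, D,
                                 np.clip(state.A + dt * dA, 0.0, 1.0))
        dD, _, _ = self.derivatives(state, C_symp, M0)
        return state, bool(np.max(np.abs(dD)) < self.steady_tol_um_s)


class _GeomView:
    """Reference geometry with the current (time-varying) diameters."""

    def __init__(self, ref: ReferenceState, diameter_um: np.ndarray):
        self.diameter_um = diameter_um
        self.segment_length_cm = ref.segment_length_cm
        self.segment_count = ref.segment_count
        self.exchanges_oxygen = ref.exchanges_oxygen
        self.viscosity_cP = ref.viscosity_cP


def simulate(protocol: Protocol, ref: ReferenceState, walls: VasoactiveWallSet,
             oxygen: OxygenParams, signal: SignalParams,
             tissue: Optional[TissueGeometry] = None, **model_kw) -> SimulationResult:
    """Convenience wrapper: build a :class:`NetworkModel` and run one protocol."""
    model = NetworkModel(ref, walls, oxygen, signal, tissue, **model_kw)
    return model.simulate(protocol)
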