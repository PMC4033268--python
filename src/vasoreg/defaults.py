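"""Packaged parameter tables and configuration I/O.

The default parameter bundle transcribes the published reference tables:
the network's primary structural/hemodynamic quantities, the smooth-muscle
wall constants of the five vasoactive compartments, and the oxygen
transport / metabolic signaling constants.  A checksum over the packaged
files guards against accidental modification.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional

import yaml

from .network import CompartmentSpec, TissueGeometry, ORDER
from .wall import WallParams, VasoactiveWallSet
from .oxygen import OxygenParams
from .conducted import SignalParams
from .dynamics import Protocol

__all__ = ["ParameterBundle", "PackagingError", "load_defaults",
           "load_network_specs", "load_wall_params", "load_transport",
           "save_bundle", "load_bundle", "protocol_from_dict",
           "protocol_to_dict", "load_protocol", "save_protocol",
           "DEFAULT_CHECKSUM"]

_DATA_FILES = ("network.yaml", "wall.yaml", "transport.yaml")

#: SHA-256 over the packaged parameter files (concatenated, sorted order).
DEFAULT_CHECKSUM = "98e4c13f247b86a3c2d1fa41419016f32fc87d7c4971ef90407b21ffab2edebc"


class PackagingError(RuntimeError):
    """The packaged parameter files do not match their recorded checksum."""


@dataclass
class ParameterBundle:
    """Everything needed to build and simulate a network."""

    network_specs: List[CompartmentSpec]
    walls: VasoactiveWallSet
    oxygen: OxygenParams
    signal: SignalParams
    tissue: TissueGeometry
    inlet_pressure_mmHg: float = 100.0
    integrator: dict = field(default_factory=lambda: {
        "dt_s": 0.01, "record_dt_s": 0.1, "steady_tol_um_s": 1e-6})
    checksum: Optional[str] = None


def _read_packaged(name: str) -> bytes:
    return resources.files("vasoreg.data").joinpath(name).read_bytes()


def packaged_checksum() -> str:
    h = hashlib.sha256()
    for name in sorted(_DATA_FILES):
        h.update(_read_packaged(name))
    return h.hexdigest()


def _parse_network(doc: dict) -> tuple[List[CompartmentSpec], float]:
    specs = []
    for rec in doc["compartments"]:
        rec = dict(rec)
        name = str(rec.pop("name"))
        specs.append(CompartmentSpec(
            name=name,
            wall_shear_dyn_cm2=rec.pop("wall_shear_dyn_cm2"),
            viscosity_cP=rec.pop("viscosity_cP", None),
            diameter_um=rec.pop("diameter_um", None),
            dp_mmHg=rec.pop("dp_mmHg", None),
            length_cm=rec.pop("length_cm", None),
            vasoactive=bool(rec.pop("vasoactive", False)),
            exchanges_oxygen=bool(rec.pop("exchanges_oxygen", False)),
        ))
    return specs, float(doc.get("inlet_pressure_mmHg", 100.0))


def _parse_walls(doc: dict) -> VasoactiveWallSet:
    tc = doc.get("time_constants", {})
    params = []
    for comp, rec in doc["compartments"].items():
        params.append(WallParams(
            compartment=str(comp),
            tau_d_s=float(tc.get("tau_d_s", 1.0)),
            tau_a_s=float(tc.get("tau_a_s", 20.0)),
            **{k: float(v) for k, v in rec.items()}))
    return VasoactiveWallSet(params)


def load_network_specs(path=None):
    """Network spec list (and inlet pressure) from a config file or packaged default."""
    raw = Path(path).read_bytes() if path else _read_packaged("network.yaml")
    return _parse_network(yaml.safe_load(raw))


def load_wall_params(path=None) -> VasoactiveWallSet:
    raw = Path(path).read_bytes() if path else _read_packaged("wall.yaml")
    return _parse_walls(yaml.safe_load(raw))


def load_transport(path=None):
    raw = Path(path).read_bytes() if path else _read_packaged("transport.yaml")
    doc = yaml.safe_load(raw)
    oxygen = OxygenParams(**{k: float(v) for k, v in doc["oxygen"].items()})
    signal = SignalParams(**{k: float(v) for k, v in doc["signal"].items()})
    tissue = TissueGeometry(**{k: float(v) for k, v in doc["tissue"].items()})
    integrator = {k: float(v) for k, v in doc.get("integrator", {}).items()}
    return oxygen, signal, tissue, integrator


def load_defaults(verify_checksum: bool = True) -> ParameterBundle:
    """The packaged default parameter bundle.

    Raises :class:`PackagingError` if the packaged files have been altered
    relative to the recorded checksum.
    """
    digest = packaged_checksum()
    if verify_checksum and digest != DEFAULT_CHECKSUM:
        raise PackagingError(
            f"packaged parameter files have checksum {digest}, expected "
            f"{DEFAULT_CHECKSUM}")
    specs, p_in = load_network_specs()
    walls = load_wall_params()
    oxygen, signal, tissue, integrator = load_transport()
    return ParameterBundle(network_specs=specs, walls=walls, oxygen=oxygen,
                           signal=signal, tissue=tissue,
                           inlet_pressure_mmHg=p_in, integrator=integrator,
                           checksum=digest)


def load_bundle(network=None, wall=None, transport=None,
                verify_checksum: bool = False) -> ParameterBundle:
    """Bundle from explicit config paths, falling back to packaged defaults."""
    if network is None and wall is None and transport is None:
        return load_defaults(verify_checksum=verify_checksum or True)
    specs, p_in = load_network_specs(network)
    walls = load_wall_params(wall)
    oxygen, signal, tissue, integrator = load_transport(transport)
    return ParameterBundle(network_specs=specs, walls=walls, oxygen=oxygen,
                           signal=signal, tissue=tissue,
                           inlet_pressure_mmHg=p_in, integrator=integrator)


# -- bundle round-trip ----------------------------------------------------

def save_bundle(bundle: ParameterBundle, directory) -> dict:
    """Write a bundle back to the three config files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    net = {"inlet_pressure_mmHg": bundle.inlet_pressure_mmHg,
           "viscosity_law": "pries-invivo",
           "compartments": [
               {"name": s.name,
                "wall_shear_dyn_cm2": s.wall_shear_dyn_cm2,
                "dp_mmHg": s.dp_mmHg, "length_cm": s.length_cm,
                "diameter_um": s.diameter_um, "viscosity_cP": s.viscosity_cP,
                "vasoactive": s.vasoactive,
                "exchanges_oxygen": s.exchanges_oxygen}
               for s in bundle.network_specs]}
    walls = {"time_constants": {"tau_d_s": float(bundle.walls.tau_d_s[0]),
                                "tau_a_s": float(bundle.walls.tau_a_s[0])},
             "compartments": {
                 p.compartment: {"D0_um": p.D0_um, "C_myo": p.C_myo,
                                 "C_shear": p.C_shear, "C_pass": p.C_pass,
                                 "C_pass_prime": p.C_pass_prime,
                                 "C_act": p.C_act,
                                 "C_act_prime": p.C_act_prime,
                                 "C_act_dprime": p.C_act_dprime}
                 for p in bundle.walls.params}}
    ox = bundle.oxygen
    transport = {
        "oxygen": {k: getattr(ox, k) for k in
                   ("M0", "C0", "HT", "HD", "hill_n", "P50", "S_in",
                    "R0", "R1", "C_atp_in", "k_d")},
        "signal": {"L_met_cm": bundle.signal.L_met_cm,
                   "C_meta": bundle.signal.C_meta},
        "tissue": {"sleeve_width_um": bundle.tissue.sleeve_width_um,
                   "capillary_density_mm2": bundle.tissue.capillary_density_mm2},
        "integrator": bundle.integrator,
    }
    paths = {}
    for name, doc in (("network.yaml", net), ("wall.yaml", walls),
                      ("transport.yaml", transport)):
        p = directory / name
        p.write_text(yaml.safe_dump(doc, sort_keys=False))
        paths[name] = p
    return paths


# -- protocol I/O ---------------------------------------------------------

def protocol_to_dict(protocol: Protocol) -> dict:
    return {"duration_s": protocol.duration_s,
            "lock_metabolic_at_s": protocol.lock_metabolic_at_s,
            "epochs": [{"t_start_s": t, "C_symp": cs, "M0": m0}
                       for (t, cs, m0) in protocol.epochs]}


def protocol_from_dict(doc: dict) -> Protocol:
    epochs = tuple((float(e["t_start_s"]), float(e["C_symp"]), float(e["M0"]))
                   for e in doc["epochs"])
    lock = doc.get("lock_metabolic_at_s")
    return Protocol(epochs=epochs, duration_s=float(doc["duration_s"]),
                    lock_metabolic_at_s=None if lock is None else float(lock))


def load_protocol(path) -> Protocol:
    return protocol_from_dict(yaml.safe_load(Path(path).read_text()))


def save_protocol(protocol: Protocol, path) -> None:
    Path(path).write_text(yaml.safe_dump(protocol_to_dict(protocol),
                                         sort_keys=False))
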