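"""vasoreg: compartmental simulation of microvascular blood flow regulation.

A thirteen-compartment representative-segment network of the skeletal
muscle microcirculation, with five actively regulating arteriolar
compartments whose diameters respond to myogenic, shear-dependent,
sympathetic and upstream-conducted metabolic stimuli.  The package builds
and calibrates the resting reference network, integrates the
diameter/activation dynamics under protocols of sympathetic nerve activity
and oxygen demand, and post-processes the runs into summary measures such
as the escape index.
"""

from .units import MMHG_TO_DYN_CM2
from .viscosity import in_vivo_viscosity
from .network import (ORDER, VASOACTIVE, CompartmentSpec, TissueGeometry,
                      ReferenceState, derive_geometry, derive_venous_diameters,
                      compute_volumes, calibrate_tone_constants,
                      build_reference_state, ConfigurationError,
                      NetworkValidationError, CalibrationError)
from .wall import (WallParams, WallState, VasoactiveWallSet, passive_tension,
                   max_active_tension, total_tension, stimulus_signal,
                   target_activation, inverse_target_activation)
from .hemodynamics import HemodynamicState, network_flow
from .oxygen import (OxygenParams, AxialProfile, hill_saturation,
                     hill_tension, saturation_profile, atp_profile)
from .conducted import SignalParams, ConductedField, ConductedResponse, local_signal
from .dynamics import (Protocol, NetworkState, SimulationResult, NetworkModel,
                       IntegrationError, SNA_LEVELS, DEMAND_LEVELS, simulate)
from .analysis import escape_index, sna_response_summary, tone_decomposition
from .defaults import (ParameterBundle, load_defaults, load_bundle,
                       save_bundle, load_protocol, save_protocol,
                       PackagingError)
from .scenarios import generate_scenario

__version__ = "0.1.0"


def build_default_model(**model_kw) -> NetworkModel:
    """Calibrated :class:`NetworkModel` from the packaged default tables."""
    bundle = load_defaults()
    ref = build_reference_state(bundle.network_specs, bundle.walls,
                                bundle.oxygen, bundle.signal, bundle.tissue)
    kw = dict(bundle.integrator)
    kw.update(model_kw)
    return NetworkModel(ref, bundle.walls, bundle.oxygen, bundle.signal,
                        bundle.tissue, **kw)
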