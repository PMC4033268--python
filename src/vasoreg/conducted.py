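"""Upstream-conducted metabolic signal.

The ATP-derived metabolic signal behaves like an electrical potential in
the vessel wall: each point y of the flow pathway contributes a local
source density S_loc(y), and the signal reaching an upstream point x decays
exponentially with conduction distance over a length constant L_met,

    S_CR(x) = integral_x^x_end exp(-(y - x)/L_met) S_loc(y) dy,

where x_end is the distal terminus of the pathway (the venular outflow —
signals are conducted upstream from all segments, venules and capillaries
included).  The local source is proportional to the compartment-mean ATP
concentration, S_loc = C_meta * <C_ATP>, and hence piecewise constant per
compartment, so the integral has an exact per-segment closed form; no
quadrature is involved.

For sympatholysis control experiments the conducted field can be "locked":
while locked, the stored snapshot is returned regardless of the current
metabolic state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SignalParams", "ConductedField", "ConductedResponse",
           "local_signal"]


@dataclass(frozen=True)
class SignalParams:
    """Conducted-response parameters.

    ``L_met_cm`` — exponential decay length of upstream conduction (cm);
    ``C_meta`` — metabolic signal coefficient converting mean plasma ATP
    (uM) into local signal density (uM^-1 cm^-1).
    """

    L_met_cm: float = 1.0
    C_meta: float = 30.0

    def __post_init__(self):
        if self.L_met_cm <= 0 or self.C_meta <= 0:
            raise ValueError("signal parameters must be positive")


@dataclass
class ConductedField:
    """A computed conducted-response field along the pathway."""

    s_loc: np.ndarray                 # per-compartment source density, cm^-1
    x_eval: np.ndarray                # evaluation points (cm)
    at_evaluation_points: np.ndarray  # S_CR at those points
    locked: bool = False


def local_signal(profile, params: SignalParams) -> np.ndarray:
    """Local metabolic signal density per compartment, S_loc = C_meta <C_ATP>.

    Piecewise constant: each compartment's source density is set by its
    mean plasma ATP concentration.
    """
    if profile.atp_mean_uM is None:
        raise ValueError("ATP profile must be computed before the local signal")
    return params.C_meta * profile.atp_mean_uM


class ConductedResponse:
    """Closed-form evaluator of the upstream-conducted signal.

    Precomputes, for a fixed pathway geometry and set of evaluation points
    (by default the midpoints of the vasoactive compartments), the weight
    matrix W with

        W[k, i] = L_met * (e^(-(max(a_i, x_k) - x_k)/L_met)
                           - e^(-(b_i - x_k)/L_met))    for b_i > x_k,

    so that S_CR(x_k) = sum_i W[k, i] * s_loc_i.  Supports locking the
    field at its current values for sympatholysis control runs.
    """

    def __init__(self, geom, params: SignalParams,
                 eval_points: Optional[np.ndarray] = None,
                 eval_at: str = "midpoint"):
        self.params = params
        self.boundaries = np.asarray(geom.boundaries(), dtype=float)
        if eval_points is None:
            b = self.boundaries
            if eval_at == "midpoint":
                pts = 0.5 * (b[:-1] + b[1:])
            elif eval_at == "upstream_end":
                pts = b[:-1].copy()
            else:
                raise ValueError("eval_at must be 'midpoint' or 'upstream_end'")
            eval_points = pts[geom.vaso_indices]
        self.x_eval = np.asarray(eval_points, dtype=float)
        self._weights = self._weight_matrix(self.x_eval)
        self._snapshot: Optional[ConductedField] = None

    def _weight_matrix(self, x_eval: np.ndarray) -> np.ndarray:
        L = self.params.L_met_cm
        a = self.boundaries[:-1][None, :]
        b = self.boundaries[1:][None, :]
        x = np.asarray(x_eval, dtype=float)[:, None]
        lo = np.maximum(a, x)
        w = L * (np.exp(-(lo - x) / L) - np.exp(-(b - x) / L))
        return np.where(b > x, w, 0.0)

    # -- field computation ------------------------------------------------
    def compute(self, s_loc: np.ndarray) -> ConductedField:
        """Evaluate S_CR at the configured evaluation points.

        Returns the locked snapshot instead when locking is active.
        """
        if self._snapshot is not None:
            return self._snapshot
        s = np.asarray(s_loc, dtype=float)
        return ConductedField(s_loc=s, x_eval=self.x_eval,
                              at_evaluation_points=self._weights @ s)

    def signal_at(self, x, s_loc: np.ndarray) -> np.ndarray:
        """S_CR at arbitrary pathway coordinates (always live, never locked)."""
        W = self._weight_matrix(np.atleast_1d(np.asarray(x, dtype=float)))
        return W @ np.asarray(s_loc, dtype=float)

    # -- locking ----------------------------------------------------------
    @property
    def locked(self) -> bool:
        return self._snapshot is not None

    def lock(self, field: Optional[ConductedField] = None,
             s_loc: Optional[np.ndarray] = None) -> ConductedField:
        """Freeze the conducted signal at its current values.

        Either an already computed field or the current local-signal
        densities must be supplied.
        """
        if field is None:
            if s_loc is None:
                raise RuntimeError("cannot lock before any conducted field exists")
            field = self.compute(s_loc)
        self._snapshot = ConductedField(
            s_loc=field.s_loc.copy(), x_eval=field.x_eval,
            at_evaluation_points=field.at_evaluation_points.copy(), locked=True)
        return self._snapshot

    def unlock(self) -> None:
        self._snapshot = None
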