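"""Post-processing of simulation runs.

Summarizes the response to a sympathetic stimulation window: diameter
changes, flow changes, the escape index, and the decomposition of the
stimulus change into its myogenic, shear, sympathetic and metabolic
components.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .dynamics import SimulationResult

__all__ = ["escape_index", "sna_response_summary", "tone_decomposition"]


def escape_index(D_0: float, D_m: float, D_e: float) -> float:
    """Escape index EI = (D_m - D_e) / (D_m - D_0).

    D_0 is the diameter prior to SNA, D_m the minimum during SNA, D_e the
    diameter at the end of SNA.  EI = 0 means the constriction was fully
    sustained, EI = 1 that the vessel escaped back to its pre-SNA
    diameter.  Undefined (NaN) when no constriction occurred (D_m = D_0).
    """
    if D_m == D_0:
        return float("nan")
    return (D_m - D_e) / (D_m - D_0)


def _window_indices(result: SimulationResult,
                    window: Tuple[float, float]) -> Tuple[int, int, slice]:
    """(pre, end, during) sample indices for an SNA window (t0, t1).

    "Prior" is the last sample before t0.  "End of SNA" is the last sample
    inside the window at which the stepped (elevated) C_symp is still
    active — the sample recorded exactly at t1 already carries the
    post-step stimulus, so it is excluded when stimulus values are known.
    """
    t0, t1 = window
    t = result.time
    if t0 < t[0] or t1 > t[-1] + 1e-9 or t1 < t0:
        raise ValueError(f"SNA window ({t0}, {t1}) lies outside the "
                         f"simulated range [{t[0]}, {t[-1]}]")
    pre = max(int(np.searchsorted(t, t0, side="left")) - 1, 0)
    first = int(np.searchsorted(t, t0, side="left"))
    last = int(np.searchsorted(t, t1, side="right")) - 1
    if last < first:  # zero-length window: no samples inside
        return pre, pre, slice(pre + 1, pre + 1)
    cs = result.C_symp
    end = last
    if np.isfinite(cs[first]):
        elevated = cs[first]
        while end > first and cs[end] != elevated:
            end -= 1
    return pre, end, slice(first, end + 1)


def sna_response_summary(result: SimulationResult,
                         window: Tuple[float, float]) -> pd.DataFrame:
    """Per-compartment response table for one SNA window.

    "Prior to SNA" is the last sample before the stimulus step and "end of
    SNA" the last sample with the stimulus active; the minimum is taken
    over the recorded samples inside the window.  Relative change is
    100*(D_end - D_pre)/D_pre; the escape index is NaN for a zero-length
    window or when no constriction occurred.
    """
    pre, end, during = _window_indices(result, window)
    rows = []
    for j, comp in enumerate(result.compartments):
        d_pre = result.D_um[pre, j]
        d_end = result.D_um[end, j]
        d_series = result.D_um[during, j]
        d_min = float(d_series.min()) if d_series.size else d_pre
        rows.append({
            "compartment": comp,
            "D_pre_um": d_pre,
            "D_min_um": d_min,
            "D_end_um": d_end,
            "delta_abs_um": d_end - d_pre,
            "delta_pct": 100.0 * (d_end - d_pre) / d_pre,
            "escape_index": escape_index(d_pre, d_min, d_end),
            "flow_ratio": result.total_flow_cm3_s[end]
            / result.total_flow_cm3_s[pre],
        })
    return pd.DataFrame(rows)


def tone_decomposition(result: SimulationResult,
                       window: Tuple[float, float]) -> pd.DataFrame:
    """Change of each stimulus component over an SNA window.

    Reports dS_myo, dS_shear, dS_symp, dS_meta and -dS_tone per vasoactive
    compartment (end of SNA minus prior to SNA).  Because the calibrated
    offset C''_tone is constant, -dS_tone equals minus the sum of the four
    component changes identically; positive values of -dS_tone indicate net
    vasodilation, negative values net vasoconstriction.
    """
    pre, end, _ = _window_indices(result, window)
    rows = []
    for j, comp in enumerate(result.compartments):
        d_myo = result.S_myo[end, j] - result.S_myo[pre, j]
        d_shear = result.S_shear[end, j] - result.S_shear[pre, j]
        d_symp = result.S_symp[end, j] - result.S_symp[pre, j]
        d_meta = result.S_meta[end, j] - result.S_meta[pre, j]
        d_tone = result.S_tone[end, j] - result.S_tone[pre, j]
        rows.append({
            "compartment": comp,
            "dS_myo": d_myo, "dS_shear": d_shear,
            "dS_symp": d_symp, "dS_meta": d_meta,
            "minus_dS_tone": -d_tone,
        })
    return pd.DataFrame(rows)
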