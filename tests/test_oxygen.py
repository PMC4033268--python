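"""Oxygen saturation profiles, Hill conversions, and ATP transport."""

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vasoreg import (OxygenParams, TissueGeometry, hill_saturation,
                     hill_tension, saturation_profile, atp_profile,
                     network_flow)
from vasoreg.units import UM_TO_CM


def single_compartment(D_um=10.0, L_cm=0.5, v_cm_s=0.2, exchanges=True):
    """Minimal one-compartment geometry + hemodynamics for closed-form tests."""
    q = np.pi / 4.0 * (D_um * UM_TO_CM) ** 2 * v_cm_s
    geom = SimpleNamespace(
        diameter_um=np.array([D_um]), segment_length_cm=np.array([L_cm]),
        segment_count=np.array([1.0]), exchanges_oxygen=np.array([exchanges]),
        viscosity_cP=np.array([2.0]))
    hemo = SimpleNamespace(segment_flow_cm3_s=np.array([q]),
                           velocity_cm_s=np.array([v_cm_s]))
    return geom, hemo


class TestHill:
    def test_half_saturation(self):
        op = OxygenParams()
        assert hill_saturation(op.P50, op) == pytest.approx(0.5)

    def test_inlet_saturation_tension(self):
        op = OxygenParams()
        # closed-form inverse at the arterial inlet saturation
        assert hill_tension(0.97, op) == pytest.approx(94.2, abs=0.05)

    def test_round_trip(self):
        op = OxygenParams()
        for s in np.arange(0.1, 0.95, 0.1):
            assert hill_saturation(hill_tension(s, op), op) \
                == pytest.approx(s, abs=1e-12)

    def test_full_saturation_rejected_in_inverse(self):
        with pytest.raises(ValueError):
            hill_tension(1.0, OxygenParams())


class TestSaturationProfile:
    def test_no_demand_keeps_inlet_saturation(self, ref, model):
        hemo = network_flow(ref.diameter_um, ref)
        op = replace(model.oxygen, M0=0.0)
        prof = saturation_profile(hemo, ref, op, model.tissue)
        x = np.linspace(0, ref.pathway_length_cm, 200)
        assert np.allclose(prof.saturation(x), op.S_in)

    def test_halving_flow_doubles_slope(self):
        geom, hemo = single_compartment()
        op = OxygenParams(M0=4.0)
        tg = TissueGeometry()
        slow = SimpleNamespace(
            segment_flow_cm3_s=hemo.segment_flow_cm3_s / 2.0,
            velocity_cm_s=hemo.velocity_cm_s / 2.0)
        g1 = saturation_profile(hemo, geom, op, tg).S_slope[0]
        g2 = saturation_profile(slow, geom, op, tg).S_slope[0]
        assert g2 / g1 == pytest.approx(2.0, rel=1e-12)

    def test_rest_profile_monotone_and_bounded(self, ref, model):
        hemo = network_flow(ref.diameter_um, ref)
        prof = saturation_profile(hemo, ref, model.oxygen, model.tissue)
        s_bounds = prof.saturation(prof.boundaries)
        i_c = ref.index("C")
        assert 0.0 < prof.S_end[i_c] < model.oxygen.S_in
        # monotone decreasing from FA inlet to capillary outlet
        assert np.all(np.diff(s_bounds[1:i_c + 2]) <= 0)
        # venous saturation constant (no exchange)
        assert np.all(prof.S_slope[i_c + 1:] == 0.0)

    def test_depletion_floors_at_zero(self):
        geom, hemo = single_compartment(v_cm_s=0.01, L_cm=2.0)
        op = OxygenParams(M0=8.28)
        prof = saturation_profile(hemo, geom, op, TissueGeometry())
        assert np.isfinite(prof.depletion_x[0])
        assert prof.S_end[0] == 0.0
        assert np.all(prof.saturation(np.linspace(0, 2.0, 50)) >= 0.0)

    def test_oxygen_mass_balance(self, ref, model):
        """Convected O2 lost by each compartment equals sleeve consumption."""
        hemo = network_flow(ref.diameter_um, ref)
        op = replace(model.oxygen, M0=4.64)
        prof = saturation_profile(hemo, ref, op, model.tissue)
        w = model.tissue.sleeve_width_um * UM_TO_CM
        m0 = op.M0 / 100.0 / 60.0
        for i in range(13):
            if not ref.exchanges_oxygen[i]:
                continue
            a, b = prof.boundaries[i], prof.boundaries[i + 1]
            dep = prof.depletion_x[i]
            L_active = (min(dep, b) - a) if np.isfinite(dep) else (b - a)
            lost = (hemo.segment_flow_cm3_s[i] * op.effective_capacity
                    * (prof.S_start[i] - prof.S_end[i]))
            D = ref.diameter_um[i] * UM_TO_CM
            consumed = m0 * np.pi * w * (D + w) * L_active
            assert lost == pytest.approx(consumed, rel=1e-8)

    def test_end_capillary_saturation_monotone_in_demand(self, ref, model):
        hemo = network_flow(ref.diameter_um, ref)
        i_c = ref.index("C")
        ends = []
        for m0 in (1.0, 1.91, 4.64, 8.28):
            prof = saturation_profile(hemo, ref, replace(model.oxygen, M0=m0),
                                      model.tissue)
            ends.append(prof.S_end[i_c])
        assert all(b < a for a, b in zip(ends, ends[1:]))


class TestAtpProfile:
    def test_no_sources_or_sinks_is_constant(self):
        geom, hemo = single_compartment()
        op = OxygenParams(M0=0.0, R0=0.0, k_d=0.0)
        prof = saturation_profile(hemo, geom, op, TissueGeometry())
        prof = atp_profile(prof, hemo, geom, op)
        x = np.linspace(0, 0.5, 40)
        assert np.allclose(prof.atp(x), op.C_atp_in, rtol=1e-14)

    def test_pure_decay_when_release_balances(self):
        """S = 1/R1 zeroes the release term: exponential decay with the
        advective length constant v*D/(4 k_d)."""
        op = OxygenParams(M0=0.0, S_in=0.9, R1=1.0 / 0.9)
        geom, hemo = single_compartment(D_um=20.0, v_cm_s=0.1, L_cm=0.3)
        prof = saturation_profile(hemo, geom, op, TissueGeometry())
        prof = atp_profile(prof, hemo, geom, op)
        lam = hemo.velocity_cm_s[0] * geom.diameter_um[0] * UM_TO_CM \
            / (4.0 * op.k_d)
        x = np.linspace(0, 0.3, 20)
        assert np.allclose(prof.atp(x), op.C_atp_in * np.exp(-x / lam),
                           rtol=1e-10)

    def test_constant_saturation_closed_form_and_ivp_oracle(self):
        """Piecewise solution matches C_eq + (C_in-C_eq)exp(-4k_d x/(vD))
        and an independent high-accuracy ODE integration."""
        op = OxygenParams(M0=0.0, S_in=0.6)
        D_um, v, L = 12.0, 0.15, 0.4
        geom, hemo = single_compartment(D_um=D_um, v_cm_s=v, L_cm=L)
        prof = saturation_profile(hemo, geom, op, TissueGeometry())
        prof = atp_profile(prof, hemo, geom, op)
        D = D_um * UM_TO_CM
        c_eq = op.HT * op.R0 * (1 - op.R1 * 0.6) * D / (4 * op.k_d)
        x = np.linspace(0, L, 30)
        analytic = c_eq + (op.C_atp_in - c_eq) * np.exp(-4 * op.k_d * x / (v * D))
        assert np.allclose(prof.atp(x), analytic, rtol=1e-10)

        def rhs(xx, c):
            return (op.HT * op.R0 * (1 - op.R1 * 0.6) - 4 * op.k_d / D * c) / v

        sol = solve_ivp(rhs, (0, L), [op.C_atp_in], t_eval=x,
                        rtol=1e-11, atol=1e-14)
        assert np.allclose(prof.atp(x), sol.y[0], rtol=1e-8)

    def test_network_atp_nonnegative_and_continuous(self, ref, model):
        hemo = network_flow(ref.diameter_um, ref)
        for m0 in (1.0, 8.28):
            prof = saturation_profile(hemo, ref, replace(model.oxygen, M0=m0),
                                      model.tissue)
            prof = atp_profile(prof, hemo, ref, replace(model.oxygen, M0=m0))
            x = np.linspace(0, ref.pathway_length_cm * 0.999, 400)
            c = prof.atp(x)
            assert np.all(c >= 0.0)
            # continuity at compartment junctions
            for xb in prof.boundaries[1:-1]:
                left = prof.atp([xb - 1e-9])[0]
                right = prof.atp([xb + 1e-9])[0]
                assert left == pytest.approx(right, rel=1e-6, abs=1e-9)


class TestParamValidation:
    def test_hematocrit_ordering_enforced(self):
        with pytest.raises(ValueError):
            OxygenParams(HT=0.5, HD=0.4)

    def test_saturation_bounds_enforced(self):
        with pytest.raises(ValueError):
            OxygenParams(S_in=1.2)
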