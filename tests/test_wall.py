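"""Wall mechanics: tension curves, stimulus, and target activation."""

import mpmath
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from vasoreg import load_defaults
from vasoreg.units import MMHG_TO_DYN_CM2, UM_TO_CM
from vasoreg.wall import (WallParams, passive_tension, max_active_tension,
                          total_tension, stimulus_signal, target_activation,
                          inverse_target_activation)


@pytest.fixture(scope="module")
def walls():
    return load_defaults().walls


@pytest.fixture(scope="module")
def fa(walls):
    return walls.params[walls.compartments.index("FA")]


class TestPassiveTension:
    def test_equals_c_pass_at_passive_diameter(self, walls):
        for p in walls.params:
            assert passive_tension(p.D0_um, p) == pytest.approx(p.C_pass)

    def test_unit_exponent_point(self, walls):
        for p in walls.params:
            d = p.D0_um * (1.0 + 1.0 / p.C_pass_prime)
            assert passive_tension(d, p) == pytest.approx(p.C_pass * np.e)

    def test_fa_at_reference_diameter(self, fa):
        # direct evaluation of the exponential at D = 60 um
        assert passive_tension(60.0, fa) == pytest.approx(6.850, abs=5e-3)

    def test_strictly_increasing(self, fa):
        d = np.linspace(0.3, 1.5, 200) * fa.D0_um
        t = passive_tension(d, fa)
        assert np.all(np.diff(t) > 0)

    def test_matches_multiprecision_oracle(self, walls):
        """Both tension curves agree with 30-digit arithmetic to 12 digits."""
        mpmath.mp.dps = 30
        for p in walls.params:
            for ratio in np.linspace(0.3, 1.5, 25):
                d = ratio * p.D0_um
                exact_pass = mpmath.mpf(p.C_pass) * mpmath.exp(
                    mpmath.mpf(p.C_pass_prime) * (mpmath.mpf(d) / mpmath.mpf(p.D0_um) - 1))
                exact_act = mpmath.mpf(p.C_act) * mpmath.exp(
                    -((mpmath.mpf(d) / mpmath.mpf(p.D0_um) - mpmath.mpf(p.C_act_prime))
                      / mpmath.mpf(p.C_act_dprime)) ** 2)
                assert abs(passive_tension(d, p) - float(exact_pass)) \
                    <= 1e-12 * float(exact_pass)
                assert abs(max_active_tension(d, p) - float(exact_act)) \
                    <= 1e-12 * float(exact_act)


class TestActiveTension:
    def test_peak_at_optimal_length(self, walls):
        for p in walls.params:
            peak = max_active_tension(p.C_act_prime * p.D0_um, p)
            assert peak == pytest.approx(p.C_act)
            # symmetric unit-exponent points on either flank
            for sign in (-1, +1):
                d = (p.C_act_prime + sign * p.C_act_dprime) * p.D0_um
                assert max_active_tension(d, p) == pytest.approx(p.C_act / np.e)

    def test_fa_at_reference_diameter(self, fa):
        assert max_active_tension(60.0, fa) == pytest.approx(675.0, rel=1e-3)

    def test_area_prefactor_variant(self, fa):
        import dataclasses
        fa_pref = dataclasses.replace(fa, area_prefactor=True)
        area = np.pi * (60.0 * UM_TO_CM / 2.0) ** 2
        assert max_active_tension(60.0, fa_pref) \
            == pytest.approx(area * max_active_tension(60.0, fa))


class TestTotalTension:
    def test_limits_and_affinity(self, fa):
        d = 60.0
        assert total_tension(d, 0.0, fa) == pytest.approx(passive_tension(d, fa))
        d_pk = fa.C_act_prime * fa.D0_um
        assert total_tension(d_pk, 1.0, fa) \
            == pytest.approx(passive_tension(d_pk, fa) + fa.C_act)
        mid = 0.5 * (total_tension(d, 0.0, fa) + total_tension(d, 1.0, fa))
        assert total_tension(d, 0.5, fa) == pytest.approx(mid, rel=1e-14)

    def test_rejects_out_of_range_activation(self, fa):
        with pytest.raises(ValueError):
            total_tension(60.0, 1.5, fa)


class TestStimulusAndActivation:
    def test_zero_inputs_give_zero(self, fa):
        assert stimulus_signal(0.0, 0.0, 0.0, 0.0, fa, C_tone=0.0) == 0.0

    def test_sympathetic_additivity(self, fa):
        base = stimulus_signal(300.0, 55.0, 0.0, 5.0, fa, C_tone=1.0)
        high = stimulus_signal(300.0, 55.0, 4.0, 5.0, fa, C_tone=1.0)
        assert high - base == pytest.approx(4.0, abs=1e-14)

    def test_sigmoid_midpoint_and_closed_form(self):
        assert target_activation(0.0) == 0.5
        assert target_activation(-np.log(3.0)) == pytest.approx(0.25)
        assert target_activation(50.0) == pytest.approx(1.0)

    @given(st.floats(-30, 30))
    def test_sigmoid_symmetry(self, s):
        assert target_activation(s) + target_activation(-s) == pytest.approx(1.0)

    @given(st.floats(-20, 20), st.floats(1e-3, 5))
    def test_sigmoid_monotone(self, s, ds):
        assert target_activation(s + ds) > target_activation(s)

    @given(st.floats(0.001, 0.999))
    def test_logit_inverts_sigmoid(self, a):
        assert target_activation(inverse_target_activation(a)) \
            == pytest.approx(a, rel=1e-12)


class TestPressureDiameterEquilibrium:
    def test_passive_equilibrium_at_100_torr_is_d0(self, walls):
        """With no tone, the equilibrium diameter at 100 torr is D_0.

        The wall is in equilibrium where the generated tension equals the
        imposed tension P*D/2; with A = 0 that balance defines the passive
        pressure-diameter curve, which passes through D_0 at 100 torr.
        """
        p_cgs = 100.0 * MMHG_TO_DYN_CM2
        for p in walls.params:
            def excess(d_um):
                return passive_tension(d_um, p) - p_cgs * d_um * UM_TO_CM / 2.0
            d_eq = brentq(excess, 0.5 * p.D0_um, 1.5 * p.D0_um)
            assert abs(d_eq - p.D0_um) / p.D0_um < 1e-3


class TestValidation:
    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            WallParams(compartment="X", D0_um=-1, C_myo=0.01, C_shear=0.02,
                       C_pass=100, C_pass_prime=8, C_act=200,
                       C_act_prime=0.7, C_act_dprime=0.3)

    def test_requires_fast_diameter_slow_activation(self):
        with pytest.raises(ValueError):
            WallParams(compartment="X", D0_um=100, C_myo=0.01, C_shear=0.02,
                       C_pass=100, C_pass_prime=8, C_act=200,
                       C_act_prime=0.7, C_act_dprime=0.3,
                       tau_d_s=30.0, tau_a_s=20.0)
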