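"""Closed-form model components: ramps, sigmoidal dissolution, dilution peaks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import itcdissolve as itc
from itcdissolve import forward
from itcdissolve.errors import InvalidInputError


class TestConcentrationStep:
    @pytest.mark.parametrize(
        "c_inj, V_inj, V_cell, expected",
        [
            (30.0, 10.0, 1460.0, 0.2054794520547945),
            (0.0, 10.0, 1460.0, 0.0),
            (30.0, 1459.0, 1460.0, 30.0 * 1459.0 / 1460.0),
        ],
    )
    def test_step_concentration(self, c_inj, V_inj, V_cell, expected):
        s = itc.InjectionSchedule(c_inj_mM=c_inj, V_inj_uL=V_inj, V_cell_uL=V_cell)
        assert itc.step_concentration(s) == pytest.approx(expected, rel=1e-12)

    def test_reference_step_is_about_0_21_mM(self):
        assert itc.step_concentration(itc.EXPERIMENT_A) == pytest.approx(0.21, abs=0.005)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(InvalidInputError):
            itc.InjectionSchedule(c_inj_mM=30.0, V_inj_uL=-1.0)
        with pytest.raises(InvalidInputError):
            itc.InjectionSchedule(c_inj_mM=30.0, V_inj_uL=2000.0, V_cell_uL=1460.0)


class TestAggregateFraction:
    @pytest.mark.parametrize(
        "c_inj, c_s, expected",
        [(30.0, 5.0, 1 - 5 / 30), (30.0, 0.0, 1.0), (30.0, 30.0, 0.0)],
    )
    def test_values(self, c_inj, c_s, expected):
        assert itc.aggregate_fraction(c_inj, c_s) == pytest.approx(expected, rel=1e-12)

    def test_solubility_above_syringe_rejected(self):
        with pytest.raises(InvalidInputError):
            itc.aggregate_fraction(30.0, 31.0)


class TestInjectionRamps:
    def test_ideal_ramp_values(self):
        assert itc.delta_c_ideal(0.0, 0.21, 30.0) == 0.0
        assert itc.delta_c_ideal(30.0, 0.21, 30.0) == pytest.approx(0.21)
        assert itc.delta_c_ideal(15.0, 0.21, 30.0) == pytest.approx(0.105)
        assert itc.delta_c_ideal(1e6, 0.21, 30.0) == pytest.approx(0.21)

    def test_smooth_ramp_values(self):
        assert itc.delta_c_smooth(0.0, 0.21) == 0.0
        assert itc.delta_c_smooth(15.0, 1.0, 1 / 15) == pytest.approx(1 - math.exp(-1), rel=1e-12)
        assert itc.delta_c_smooth(1e7, 0.21) == pytest.approx(0.21, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            itc.delta_c_smooth(-1.0, 0.21)
        with pytest.raises(InvalidInputError):
            itc.delta_c_ideal(-1.0, 0.21)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.01, 1.0), st.floats(1e-3, 1.0))
    def test_smooth_ramp_monotone_and_bounded(self, dc0, k_inj):
        t = np.linspace(0.0, 200.0, 400)
        v = itc.delta_c_smooth(t, dc0, k_inj)
        assert np.all(np.diff(v) >= 0)  # saturates to dc0 in float arithmetic
        assert np.all(v <= dc0)


class TestMonomerProduction:
    def test_boundary_values(self, kinetics_default):
        k = kinetics_default
        assert itc.monomer_concentration(0.0, k) == pytest.approx(k.c_mon0_mM)
        assert itc.monomer_concentration(1e7, k) == pytest.approx(
            k.c_mon0_mM + k.delta_c0_mM, rel=1e-9
        )

    def test_no_aggregates_reduces_to_pure_dilution(self):
        k = itc.DissolutionKinetics(
            A_uJ_per_mM=-1.0, k_per_s=0.1, alpha=2.0, f_agg=0.0, delta_c0_mM=0.2, c_mon0_mM=1.0
        )
        t = np.linspace(0, 100, 50)
        np.testing.assert_allclose(
            itc.monomer_concentration(t, k),
            1.0 + itc.delta_c_smooth(t, 0.2, k.k_inj_per_s),
            rtol=1e-12,
        )

    @settings(deadline=None, derandomize=True)
    @given(st.floats(1.0, 15.0), st.floats(1e-3, 0.3))
    def test_monotone_nondecreasing(self, alpha, k_rate):
        kin = itc.DissolutionKinetics(
            A_uJ_per_mM=-1.0, k_per_s=k_rate, alpha=alpha, f_agg=0.8, delta_c0_mM=0.21
        )
        t = np.linspace(0.0, 10.0 / k_rate, 600)
        assert np.all(np.diff(itc.monomer_concentration(t, kin)) >= -1e-15)

    def test_alpha_below_one_rejected(self):
        with pytest.raises(InvalidInputError):
            itc.DissolutionKinetics(
                A_uJ_per_mM=-1.0, k_per_s=0.1, alpha=0.5, f_agg=0.5, delta_c0_mM=0.2
            )


class TestDissolutionPower:
    def test_zero_at_t0_for_alpha_above_one(self, kinetics_default):
        assert itc.dissolution_power(0.0, kinetics_default) == 0.0

    def test_is_derivative_of_dissolution_term(self, kinetics_default):
        """The power expression must equal A d/dt of the sigmoidal term."""
        kin = kinetics_default
        t = np.linspace(0.1, 10.0 / kin.k_per_s, 800)
        h = 0.02

        def term(tt):
            dc = itc.delta_c_smooth(tt, kin.delta_c0_mM, kin.k_inj_per_s)
            return kin.A_uJ_per_mM * kin.f_agg * dc * (-np.expm1(-kin.k_per_s * tt)) ** kin.alpha

        fd = (term(t + h) - term(t - h)) / (2 * h)
        num = itc.dissolution_power(t, kin)
        assert np.max(np.abs(fd - num)) / np.max(np.abs(num)) < 1e-6

    def test_integral_matches_closed_form_enthalpy(self, kinetics_default):
        from scipy.integrate import quad

        kin = kinetics_default
        T = 23.0 / min(kin.k_per_s, kin.k_inj_per_s)  # e^{-kT} < 1e-10
        val, _ = quad(lambda tt: itc.dissolution_power(float(tt), kin), 0, T, limit=500)
        assert val == pytest.approx(itc.dissolution_enthalpy(kin), rel=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(1.2, 15.0), st.floats(5.0, 300.0))
    def test_exothermic_minimum_is_delayed(self, alpha, k_inv):
        kin = itc.DissolutionKinetics(
            A_uJ_per_mM=-100.0, k_per_s=1.0 / k_inv, alpha=alpha, f_agg=0.8, delta_c0_mM=0.21
        )
        t = np.linspace(0.0, 20.0 * k_inv, 2000)
        p = itc.dissolution_power(t, kin)
        assert p[0] == 0.0
        assert t[np.argmin(p)] > 0.0

    def test_enthalpy_identities(self):
        kin = itc.DissolutionKinetics(
            A_uJ_per_mM=-7.0, k_per_s=0.1, alpha=2.0, f_agg=1.0, delta_c0_mM=1.0
        )
        assert itc.dissolution_enthalpy(kin) == pytest.approx(-7.0)


class TestDilutionPeaks:
    def test_half_sine_support_and_area(self):
        peak = itc.DilutionPeak.half_sine(B_uJ_per_s=-2.0, omega_per_s=0.1, delta_s=0.5)
        lo, hi = 0.5 / 0.1, (0.5 + math.pi) / 0.1
        assert itc.dilution_power(lo, peak) == pytest.approx(0.0, abs=1e-12)
        assert itc.dilution_power(lo - 1.0, peak) == 0.0
        assert itc.dilution_power(hi + 1.0, peak) == 0.0
        t = np.linspace(lo, hi, 20001)
        area = np.trapezoid(itc.dilution_power(t, peak), t)
        assert area == pytest.approx(2 * -2.0 / 0.1, rel=1e-6)
        assert peak.enthalpy_uJ == pytest.approx(2 * -2.0 / 0.1)

    def test_lorentzian_maximum_at_delay(self):
        peak = itc.DilutionPeak.lorentzian(C_uJ_per_s=1.5, w_per_s2=4e-3, delta_s=40.0)
        assert itc.dilution_power(40.0, peak) == pytest.approx(1.5)

    def test_unknown_shape_rejected(self):
        with pytest.raises(InvalidInputError):
            itc.DilutionPeak("triangle")


class TestInjectionPower:
    def test_empty_components_is_zero(self):
        assert itc.injection_power(10.0, None, []) == 0.0

    def test_additivity(self, kinetics_default):
        peaks = [
            itc.DilutionPeak.half_sine(-1.5, 0.05, 0.2),
            itc.DilutionPeak.lorentzian(0.3, 4e-3, 45.0),
        ]
        t = np.linspace(0, 500, 300)
        total = itc.injection_power(t, kinetics_default, peaks)
        parts = (
            itc.dilution_power(t, peaks[0])
            + itc.dilution_power(t, peaks[1])
            + itc.dissolution_power(t, kinetics_default)
        )
        np.testing.assert_allclose(total, parts, rtol=1e-12)


class TestMolarNormalisation:
    def test_units_cancel_to_kJ_per_mol(self):
        # -350 uJ from dissolving 0.8333*0.2055 mM in 1460 uL is -1.4 kJ/mol
        dH = -1.4 * (1 - 5 / 30) * (30 * 10 / 1460) * 1460.0
        val = itc.molar_enthalpy_per_dissolved(dH, 1 - 5 / 30, 30 * 10 / 1460, 1460.0)
        assert val == pytest.approx(-1.4, rel=1e-12)

    def test_per_injected_normalisation_is_smaller_in_magnitude(self):
        per_dis = itc.molar_enthalpy_per_dissolved(-350.0, 0.8, 0.2055, 1460.0)
        per_inj = itc.molar_enthalpy_per_injected(-350.0, 0.2055, 1460.0)
        assert abs(per_inj) < abs(per_dis)
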