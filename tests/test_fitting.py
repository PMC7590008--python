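"""Per-injection decomposition: calibration, recovery, enthalpies, assembly."""

import math

import numpy as np
import pandas as pd
import pytest

import itcdissolve as itc
from itcdissolve.errors import CalibrationError, InvalidInputError
from itcdissolve.fitting import DilutionShapeConstants, assemble_series, calibrate_dilution_shape
from itcdissolve.preprocess import detect_peak_bounds, correct_baseline, segment_injections


@pytest.fixture(scope="module")
def small_fit(small_sim, small_schedule):
    trace, truth = small_sim
    table, results = itc.fit_series(trace, small_schedule)
    return table, results, truth


class TestNoiselessRecovery:
    def test_dissolution_parameters_recovered(self, small_fit):
        """Noiseless windows must give back the generator's (A, k, alpha)."""
        _, results, truth = small_fit
        for r in results:
            kin = truth.injection(r.index).kinetics
            assert r.converged
            assert r.A_uJ_per_mM == pytest.approx(kin.A_uJ_per_mM, rel=1e-3)
            assert r.k_inv_s == pytest.approx(1.0 / kin.k_per_s, rel=1e-3)
            assert r.alpha == pytest.approx(kin.alpha, rel=1e-3)

    def test_molar_enthalpy_recovered(self, small_fit):
        _, results, _ = small_fit
        for r in results:
            assert r.enthalpy_dis_kJ_per_mol == pytest.approx(-1.4, rel=1e-3)

    def test_dilution_only_window_has_no_significant_dissolution(self):
        """Above the solubility a forced dissolution term must fit ~zero amplitude."""
        sched = itc.InjectionSchedule(
            c_inj_mM=30.0, c0_cell_mM=6.0, spacing_s=600.0, n_injections=2
        )
        trace, truth = itc.simulate_experiment(sched)
        cfg = itc.FitConfig(dissolution="always")
        table, results = itc.fit_series(trace, sched, cfg)
        # a genuine dissolution event at these conditions releases ~350 uJ
        typical_dis = abs(
            itc.GeneratorParams().A_scale_uJ_per_mM(sched) * (1 - 5 / 30) * itc.step_concentration(sched)
        )
        for r in results:
            assert truth.injection(r.index).kinetics is None
            dH_dis = abs(r.A_uJ_per_mM) * (1 - 5 / 30) * itc.step_concentration(sched)
            assert dH_dis < 0.01 * typical_dis


class TestCalibration:
    def test_omega_recovered_within_1pct(self, small_sim, small_schedule):
        trace, _ = small_sim
        bounds = detect_peak_bounds(trace)
        windows = segment_injections(correct_baseline(trace, bounds), small_schedule)
        cal = calibrate_dilution_shape(windows[0], small_schedule, itc.FitConfig())
        assert cal.omega_per_s == pytest.approx(math.pi / 60.0, rel=0.01)
        assert cal.delta_s == pytest.approx(math.pi / 12.0, rel=0.05)

    def test_flat_window_raises(self, small_schedule):
        flat = itc.PowerTrace(
            np.arange(600.0), np.zeros(600), {"injection_index": 1, "onset_s": 0.0}
        )
        with pytest.raises(CalibrationError):
            calibrate_dilution_shape(flat, small_schedule, itc.FitConfig())

    def test_constants_stable_across_noise_seeds(self, small_schedule, noise_sd_2pct):
        cals = []
        for seed in (11, 12):
            trace, _ = itc.simulate_experiment(
                small_schedule,
                noise=itc.NoiseDriftSpec(noise_sd_uJ_per_s=noise_sd_2pct, seed=seed),
            )
            cfg = itc.FitConfig(smooth_window=51)
            bounds = detect_peak_bounds(trace, smooth_window=51)
            windows = segment_injections(correct_baseline(trace, bounds), small_schedule)
            cals.append(calibrate_dilution_shape(windows[0], small_schedule, cfg))
        assert cals[0].omega_per_s == pytest.approx(cals[1].omega_per_s, rel=0.3)


class TestEnthalpies:
    def test_closed_form_matches_quadrature_of_fitted_power(self, small_fit, small_schedule):
        """Internal consistency: Eq-style closed form vs numerical integral."""
        _, results, _ = small_fit
        r = results[0]
        dc0 = itc.step_concentration(small_schedule)
        f_agg = itc.aggregate_fraction(small_schedule.c_inj_mM, 5.0)
        kin = itc.DissolutionKinetics(
            A_uJ_per_mM=r.A_uJ_per_mM, k_per_s=1.0 / r.k_inv_s, alpha=r.alpha,
            f_agg=f_agg, delta_c0_mM=dc0,
        )
        t = np.linspace(0.0, 30.0 * r.k_inv_s, 200001)
        quad = np.trapezoid(itc.dissolution_power(t, kin), t)
        assert quad == pytest.approx(r.enthalpy_dis_uJ, rel=1e-3)

    def test_zero_amplitude_gives_zero_enthalpy(self, small_schedule):
        from itcdissolve.fitting import InjectionResult, integrate_component_enthalpies

        r = InjectionResult(
            index=1, c_before_mM=0.0, c_after_mM=0.2, converged=True,
            has_dissolution=True, A_uJ_per_mM=0.0, dissolved_fraction=1.0,
        )
        enth = integrate_component_enthalpies(
            r, small_schedule, itc.FitConfig(), DilutionShapeConstants(0.05, 0.26)
        )
        assert enth["dis_uJ"] == 0.0


class TestNoisyRecovery:
    def test_single_noisy_fit_recovers_k_inv_within_10pct(self, small_schedule, noise_sd_2pct):
        trace, truth = itc.simulate_experiment(
            small_schedule,
            noise=itc.NoiseDriftSpec(noise_sd_uJ_per_s=noise_sd_2pct, seed=3),
        )
        _, results = itc.fit_series(trace, small_schedule, itc.FitConfig(smooth_window=51))
        for r in results:
            kin = truth.injection(r.index).kinetics
            assert r.k_inv_s == pytest.approx(1.0 / kin.k_per_s, rel=0.10)


class TestAssembleSeries:
    def test_rows_match_concentration_series(self, experiment_a_fit):
        table, _, _ = experiment_a_fit
        assert len(table) == 27
        series = itc.cell_concentration_series(itc.EXPERIMENT_A)
        np.testing.assert_allclose(
            np.sort(table["c_after_mM"].to_numpy()), [c for _, c in series], rtol=1e-12
        )

    def test_slow_injections_flagged_unreliable(self, experiment_a_fit):
        table, _, _ = experiment_a_fit
        spacing = itc.EXPERIMENT_A.spacing_s
        fitted = table.dropna(subset=["k_inv_s"])
        slow = fitted["k_inv_s"] > spacing / 3.0
        assert (~fitted.loc[slow, "reliable"]).all()
        assert fitted.loc[~slow, "reliable"].all()

    def test_above_solubility_rows_have_no_dissolution_enthalpy(self, experiment_a_fit):
        table, _, _ = experiment_a_fit
        above = table[table["c_before_mM"] >= 5.0]
        assert len(above) > 0
        assert above["enthalpy_dis_uJ"].isna().all()

    def test_flag_rule_on_constructed_input(self):
        from itcdissolve.fitting import InjectionResult

        rows = [
            InjectionResult(index=1, c_before_mM=0.0, c_after_mM=0.2, converged=True,
                            has_dissolution=True, k_inv_s=100.0),
            InjectionResult(index=2, c_before_mM=0.2, c_after_mM=0.4, converged=True,
                            has_dissolution=True, k_inv_s=500.0),
        ]
        table = assemble_series(rows, spacing_s=600.0)
        assert table.set_index("injection")["reliable"].to_dict() == {1: True, 2: False}

    def test_empty_results_rejected(self):
        with pytest.raises(InvalidInputError):
            assemble_series([], 600.0)
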