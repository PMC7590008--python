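"""Per-injection least-squares decomposition of baseline-corrected windows.

Each injection window is modelled as the sum of fast dilution peaks
(half-sine, plus an endothermic Lorentzian above the solubility) and, below
the solubility, the slow sigmoidal dissolution signal.  Following the
original analysis protocol, the dilution shape constants (ω, δ and, for the
Lorentzian, w, δ_L) are calibrated once on a suitable window and then held
fixed for the whole series; per injection only the amplitudes B, C and the
dissolution parameters (A, k, α) are free.  The by-eye fitting of the
source protocol is replaced by nonlinear least squares with a multi-start
over the lag exponent α.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidInputError
from .forward import (
    K_INJ_DEFAULT,
    DilutionPeak,
    DissolutionKinetics,
    InjectionSchedule,
    aggregate_fraction,
    dilution_power,
    dissolution_power,
    molar_enthalpy_per_dissolved,
    molar_enthalpy_per_injected,
    step_concentration,
)
from .preprocess import correct_baseline, detect_peak_bounds, segment_injections
from .synth import cell_concentration_series
from .trace import PowerTrace

__all__ = [
    "FitConfig",
    "DilutionShapeConstants",
    "InjectionResult",
    "calibrate_dilution_shape",
    "fit_injection",
    "integrate_component_enthalpies",
    "assemble_series",
    "fit_series",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilutionShapeConstants:
    """Experiment-level dilution shape constants, frozen across injections."""

    omega_per_s: float
    delta_s: float
    w_per_s2: Optional[float] = None
    delta_endo_s: Optional[float] = None


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the per-injection decomposition fit.

    c_s_estimate_mM decides whether the dissolution component enters the
    model (it does when c_before < c_s_estimate, unless
    ``dissolution="always"``/``"never"``).  alpha is bounded to [1, 20] and
    k⁻¹ to [1 s, 10 × spacing]; the multi-start runs over alpha_starts with
    best-RSS selection.
    """

    c_s_estimate_mM: float = 5.0
    k_inj_per_s: float = K_INJ_DEFAULT
    alpha_bounds: tuple[float, float] = (1.0, 20.0)
    k_inv_bounds_factor: tuple[float, float] = (1.0, 10.0)  # (s, × spacing)
    alpha_starts: tuple[float, ...] = (1.5, 3.0, 10.0)
    dissolution: str = "auto"  # "auto" | "always" | "never"
    threshold: float = 2e-3
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if self.dissolution not in ("auto", "always", "never"):
            raise InvalidInputError("dissolution must be 'auto', 'always' or 'never'")
        if self.c_s_estimate_mM <= 0:
            raise InvalidInputError("c_s_estimate must be positive")


@dataclass
class InjectionResult:
    """Fitted decomposition of one injection."""

    index: int
    c_before_mM: float
    c_after_mM: float
    converged: bool
    has_dissolution: bool
    A_uJ_per_mM: Optional[float] = None
    A_stderr: Optional[float] = None
    k_inv_s: Optional[float] = None
    alpha: Optional[float] = None
    B_uJ_per_s: Optional[float] = None
    C_uJ_per_s: Optional[float] = None
    enthalpy_dis_uJ: Optional[float] = None
    enthalpy_dis_kJ_per_mol: Optional[float] = None
    enthalpy_dis_kJ_per_mol_injected: Optional[float] = None
    enthalpy_dil_exo_uJ: Optional[float] = None
    enthalpy_dil_endo_uJ: Optional[float] = None
    dissolved_fraction: float = 1.0
    fit_rss: Optional[float] = None


def _window_times(window: PowerTrace) -> np.ndarray:
    onset = window.meta.get("onset_s", window.times[0])
    return window.times - onset


def _model_values(
    t: np.ndarray,
    pars: lmfit.Parameters,
    constants: DilutionShapeConstants,
    cfg: FitConfig,
    f_agg: float,
    delta_c0: float,
    include_dis: bool,
    include_endo: bool,
    free_shape: bool = False,
) -> np.ndarray:
    v = pars.valuesdict()
    omega = v["omega"] if free_shape else constants.omega_per_s
    delta = v["delta"] if free_shape else constants.delta_s
    out = dilution_power(t, DilutionPeak.half_sine(v["B"], omega, delta))
    if include_endo:
        w = v["w"] if free_shape else constants.w_per_s2
        d_endo = v["delta_endo"] if free_shape else constants.delta_endo_s
        out = out + dilution_power(t, DilutionPeak.lorentzian(v["C"], w, d_endo))
    if include_dis:
        kin = DissolutionKinetics(
            A_uJ_per_mM=v["A"],
            k_per_s=1.0 / v["k_inv"],
            alpha=v["alpha"],
            f_agg=f_agg,
            delta_c0_mM=delta_c0,
            k_inj_per_s=cfg.k_inj_per_s,
        )
        out = out + dissolution_power(t, kin)
    return out


def _initial_k_inv(t: np.ndarray, values: np.ndarray, t_inj: float, bounds: tuple[float, float]) -> float:
    # locate the delayed dissolution minimum past the dilution transient;
    # smooth first so a noise spike cannot hijack the starting point
    w = max(3, int(round(t_inj / (2.0 * (t[1] - t[0])))) | 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(np.pad(values, w // 2, mode="edge"), kernel, mode="valid")
    late = t > 2.0 * t_inj
    if not late.any():
        return float(np.clip(t_inj, *bounds))
    t_min = t[late][np.argmin(smooth[late])]
    return float(np.clip(t_min / 1.5, *bounds))


def fit_injection(
    window: PowerTrace,
    schedule: InjectionSchedule,
    config: FitConfig,
    constants: DilutionShapeConstants,
    c_before: Optional[float] = None,
    c_after: Optional[float] = None,
) -> InjectionResult:
    """Fit one baseline-corrected injection window.

    Returns the fitted amplitudes, dissolution parameters and component
    enthalpies; a fit that fails from every α start is returned with
    ``converged=False`` and parameters absent.
    """
    index = window.meta.get("injection_index")
    if c_before is None or c_after is None:
        if index is None:
            raise InvalidInputError("window lacks injection_index and no concentrations given")
        c_before, c_after = cell_concentration_series(schedule)[index - 1]
    t = _window_times(window)
    y = window.values
    dc0 = step_concentration(schedule)
    c_s = config.c_s_estimate_mM
    f_agg = aggregate_fraction(schedule.c_inj_mM, min(c_s, schedule.c_inj_mM))
    if config.dissolution == "always":
        include_dis = True
    elif config.dissolution == "never":
        include_dis = False
    else:
        include_dis = c_before < c_s
    include_endo = c_before >= c_s
    k_inv_bounds = (
        config.k_inv_bounds_factor[0],
        config.k_inv_bounds_factor[1] * schedule.spacing_s,
    )

    def make_params(alpha0: float) -> lmfit.Parameters:
        pars = lmfit.Parameters()
        dt = t[1] - t[0]
        B0 = float(y[t <= 3.0 * schedule.t_inj_s].min(initial=0.0))
        pars.add("B", value=B0 if B0 < 0 else -0.1)
        if include_endo:
            C0 = float(y[t <= 5.0 * schedule.t_inj_s].max(initial=0.1))
            pars.add("C", value=max(C0, 1e-3))
        if include_dis:
            A0 = float(np.trapezoid(y, t) / (f_agg * dc0))
            pars.add("A", value=A0 if A0 != 0 else -1.0)
            pars.add(
                "k_inv",
                value=_initial_k_inv(t, y, schedule.t_inj_s, k_inv_bounds),
                min=k_inv_bounds[0],
                max=k_inv_bounds[1],
            )
            pars.add("alpha", value=alpha0, min=config.alpha_bounds[0], max=config.alpha_bounds[1])
        return pars

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        return (
            _model_values(t, pars, constants, config, f_agg, dc0, include_dis, include_endo) - y
        )

    starts = config.alpha_starts if include_dis else (1.0,)
    best = None
    for alpha0 in starts:
        try:
            res = lmfit.minimize(
                residual, make_params(alpha0), method="leastsq", xtol=1e-12, ftol=1e-12
            )
        except Exception as exc:  # noqa: BLE001 - a failed start is not fatal
            logger.debug("fit start alpha=%s failed: %s", alpha0, exc)
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0]:
            best = (rss, res)

    result = InjectionResult(
        index=index if index is not None else -1,
        c_before_mM=c_before,
        c_after_mM=c_after,
        converged=best is not None,
        has_dissolution=include_dis,
    )
    if best is None:
        return result
    rss, res = best
    v = res.params.valuesdict()
    result.fit_rss = rss
    result.B_uJ_per_s = float(v["B"])
    if include_endo:
        result.C_uJ_per_s = float(v["C"])
    dissolved_fraction = float(np.clip((c_s - c_before) / dc0, 0.0, 1.0))
    result.dissolved_fraction = dissolved_fraction if include_dis else 0.0
    if include_dis:
        result.A_uJ_per_mM = float(v["A"])
        pA = res.params["A"]
        result.A_stderr = float(pA.stderr) if pA.stderr is not None else None
        result.k_inv_s = float(v["k_inv"])
        result.alpha = float(v["alpha"])
    enth = integrate_component_enthalpies(result, schedule, config, constants, t)
    result.enthalpy_dis_uJ = enth["dis_uJ"]
    result.enthalpy_dis_kJ_per_mol = enth["dis_kJ_per_mol"]
    result.enthalpy_dis_kJ_per_mol_injected = enth["dis_kJ_per_mol_injected"]
    result.enthalpy_dil_exo_uJ = enth["dil_exo_uJ"]
    result.enthalpy_dil_endo_uJ = enth["dil_endo_uJ"]
    return result


def integrate_component_enthalpies(
    result: InjectionResult,
    schedule: InjectionSchedule,
    config: FitConfig,
    constants: DilutionShapeConstants,
    t: Optional[np.ndarray] = None,
) -> dict:
    """Component enthalpies of a fitted injection (μJ and kJ/mol).

    The dissolution enthalpy uses the closed form A·f_agg·Δc₀; the dilution
    enthalpies are trapezoidal quadratures of the fitted shapes over the
    window.  Molar values are normalised per mole of dissolved aggregate
    (dissolved_fraction·f_agg·Δc₀·V_cell) and, alternatively, per mole of
    injected peptide.
    """
    dc0 = step_concentration(schedule)
    f_agg = aggregate_fraction(schedule.c_inj_mM, min(config.c_s_estimate_mM, schedule.c_inj_mM))
    if t is None:
        t = np.arange(0.0, schedule.spacing_s, 1.0)
    out = {
        "dis_uJ": None,
        "dis_kJ_per_mol": None,
        "dis_kJ_per_mol_injected": None,
        "dil_exo_uJ": None,
        "dil_endo_uJ": None,
    }
    if result.B_uJ_per_s is not None:
        exo = DilutionPeak.half_sine(result.B_uJ_per_s, constants.omega_per_s, constants.delta_s)
        out["dil_exo_uJ"] = float(np.trapezoid(dilution_power(t, exo), t))
    if result.C_uJ_per_s is not None:
        endo = DilutionPeak.lorentzian(result.C_uJ_per_s, constants.w_per_s2, constants.delta_endo_s)
        out["dil_endo_uJ"] = float(np.trapezoid(dilution_power(t, endo), t))
    if result.A_uJ_per_mM is not None:
        dH = result.A_uJ_per_mM * f_agg * dc0
        out["dis_uJ"] = dH
        out["dis_kJ_per_mol_injected"] = molar_enthalpy_per_injected(dH, dc0, schedule.V_cell_uL)
        if result.dissolved_fraction > 0:
            out["dis_kJ_per_mol"] = molar_enthalpy_per_dissolved(
                dH, f_agg, dc0, schedule.V_cell_uL, result.dissolved_fraction
            )
    return out


def calibrate_dilution_shape(
    window: PowerTrace,
    schedule: InjectionSchedule,
    config: FitConfig,
    include_dissolution: Optional[bool] = None,
    include_endo: Optional[bool] = None,
    c_before: Optional[float] = None,
) -> DilutionShapeConstants:
    """Calibrate the dilution shape constants on one window with a full fit.

    All shape parameters (ω, δ and, when the endothermic Lorentzian is
    present, w, δ_L) are free here; the returned constants are then frozen
    for the rest of the series.
    """
    index = window.meta.get("injection_index")
    if c_before is None:
        if index is None:
            raise InvalidInputError("window lacks injection_index and no concentration given")
        c_before = cell_concentration_series(schedule)[index - 1][0]
    t = _window_times(window)
    y = window.values
    if np.ptp(y) < 1e-9:
        raise CalibrationError(
            "window is flat: no resolvable dilution peak; supply shape constants manually"
        )
    c_s = config.c_s_estimate_mM
    if include_dissolution is None:
        include_dissolution = c_before < c_s
    if include_endo is None:
        include_endo = c_before >= c_s
    dc0 = step_concentration(schedule)
    f_agg = aggregate_fraction(schedule.c_inj_mM, min(c_s, schedule.c_inj_mM))
    k_inv_bounds = (
        config.k_inv_bounds_factor[0],
        config.k_inv_bounds_factor[1] * schedule.spacing_s,
    )
    omega0 = math.pi / (2.0 * schedule.t_inj_s)

    def make_params(alpha0: float) -> lmfit.Parameters:
        pars = lmfit.Parameters()
        B0 = float(y[t <= 3.0 * schedule.t_inj_s].min(initial=0.0))
        pars.add("B", value=B0 if B0 < 0 else -0.1)
        pars.add("omega", value=omega0, min=omega0 / 20.0, max=omega0 * 20.0)
        pars.add("delta", value=omega0 * 5.0, min=0.0, max=math.pi)
        if include_endo:
            C0 = float(y[t <= 5.0 * schedule.t_inj_s].max(initial=0.1))
            pars.add("C", value=max(C0, 1e-3))
            pars.add("w", value=(2.0 / schedule.t_inj_s) ** 2, min=1e-8)
            pars.add("delta_endo", value=1.5 * schedule.t_inj_s, min=0.0, max=10.0 * schedule.t_inj_s)
        if include_dissolution:
            A0 = float(np.trapezoid(y, t) / (f_agg * dc0))
            pars.add("A", value=A0 if A0 != 0 else -1.0)
            pars.add(
                "k_inv",
                value=_initial_k_inv(t, y, schedule.t_inj_s, k_inv_bounds),
                min=k_inv_bounds[0],
                max=k_inv_bounds[1],
            )
            pars.add("alpha", value=alpha0, min=config.alpha_bounds[0], max=config.alpha_bounds[1])
        return pars

    dummy = DilutionShapeConstants(omega0, omega0 * 5.0, (2.0 / schedule.t_inj_s) ** 2, 45.0)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        return (
            _model_values(
                t, pars, dummy, config, f_agg, dc0, include_dissolution, include_endo, free_shape=True
            )
            - y
        )

    starts = config.alpha_starts if include_dissolution else (1.0,)
    best = None
    for alpha0 in starts:
        try:
            res = lmfit.minimize(
                residual, make_params(alpha0), method="leastsq", xtol=1e-12, ftol=1e-12
            )
        except Exception:  # noqa: BLE001
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise CalibrationError("dilution-shape calibration did not converge on this window")
    v = best[1].params.valuesdict()
    return DilutionShapeConstants(
        omega_per_s=float(v["omega"]),
        delta_s=float(v["delta"]),
        w_per_s2=float(v["w"]) if include_endo else None,
        delta_endo_s=float(v["delta_endo"]) if include_endo else None,
    )


def assemble_series(results: Sequence[InjectionResult], spacing_s: float) -> pd.DataFrame:
    """Assemble per-injection results into an ordered table keyed by c_after.

    Injections whose fitted k⁻¹ exceeds spacing/3 are flagged unreliable:
    their dissolution is not complete before the next injection.
    """
    if len(results) == 0:
        raise InvalidInputError("no results to assemble")
    rows = []
    for r in results:
        k_inv = r.k_inv_s
        rows.append(
            {
                "injection": r.index,
                "c_before_mM": r.c_before_mM,
                "c_after_mM": r.c_after_mM,
                "has_dissolution": r.has_dissolution,
                "A_uJ_per_mM": r.A_uJ_per_mM,
                "k_inv_s": k_inv,
                "alpha": r.alpha,
                "B_uJ_per_s": r.B_uJ_per_s,
                "C_uJ_per_s": r.C_uJ_per_s,
                "enthalpy_dis_uJ": r.enthalpy_dis_uJ,
                "enthalpy_dis_kJ_per_mol": r.enthalpy_dis_kJ_per_mol,
                "enthalpy_dil_exo_uJ": r.enthalpy_dil_exo_uJ,
                "enthalpy_dil_endo_uJ": r.enthalpy_dil_endo_uJ,
                "fit_rss": r.fit_rss,
                "converged": r.converged,
                "reliable": bool(k_inv is None or k_inv <= spacing_s / 3.0),
            }
        )
    return pd.DataFrame(rows).sort_values("c_after_mM").reset_index(drop=True)


def _model_trace_values(
    trace: PowerTrace,
    schedule: InjectionSchedule,
    config: FitConfig,
    constants: DilutionShapeConstants,
    results: Sequence[InjectionResult],
) -> np.ndarray:
    """Evaluate the summed fitted models of all converged injections on the trace grid."""
    f_agg = aggregate_fraction(schedule.c_inj_mM, min(config.c_s_estimate_mM, schedule.c_inj_mM))
    dc0 = step_concentration(schedule)
    out = np.zeros_like(trace.values)
    onsets = schedule.onset_times()
    for r, t0 in zip(results, onsets):
        if not r.converged:
            continue
        mask = trace.times >= t0 - trace.dt / 2
        t = trace.times[mask] - t0
        if r.B_uJ_per_s is not None:
            out[mask] += dilution_power(
                t, DilutionPeak.half_sine(r.B_uJ_per_s, constants.omega_per_s, constants.delta_s)
            )
        if r.C_uJ_per_s is not None:
            out[mask] += dilution_power(
                t, DilutionPeak.lorentzian(r.C_uJ_per_s, constants.w_per_s2, constants.delta_endo_s)
            )
        if r.A_uJ_per_mM is not None:
            kin = DissolutionKinetics(
                A_uJ_per_mM=r.A_uJ_per_mM,
                k_per_s=1.0 / r.k_inv_s,
                alpha=r.alpha,
                f_agg=f_agg,
                delta_c0_mM=dc0,
                k_inj_per_s=config.k_inj_per_s,
            )
            out[mask] += dissolution_power(t, kin)
    return out


def _calibrate_constants(
    windows: Sequence[PowerTrace],
    schedule: InjectionSchedule,
    config: FitConfig,
    series: Sequence[tuple[float, float]],
    max_windows: int = 5,
) -> DilutionShapeConstants:
    """Experiment-level shape constants as the median over several windows.

    On windows containing a large dissolution signal the small dilution
    half-sine is weakly identified, so a single-window calibration is noisy;
    the median over up to ``max_windows`` windows per shape family keeps one
    badly-conditioned window from skewing the whole series.
    """
    omegas, deltas, ws, d_endos = [], [], [], []
    n_exo = n_endo = 0
    for w, (cb, _) in zip(windows, series):
        want_endo = cb >= config.c_s_estimate_mM
        if (n_exo >= max_windows and not want_endo) or (want_endo and n_endo >= max_windows):
            continue
        try:
            cal = calibrate_dilution_shape(w, schedule, config, c_before=cb)
        except CalibrationError:
            continue
        if want_endo:
            n_endo += 1
            ws.append(cal.w_per_s2)
            d_endos.append(cal.delta_endo_s)
        else:
            n_exo += 1
            omegas.append(cal.omega_per_s)
            deltas.append(cal.delta_s)
        if n_exo >= max_windows and (n_endo >= max_windows or all(cb < config.c_s_estimate_mM for cb, _ in series)):
            break
    if not omegas and not ws:
        raise CalibrationError("no window yielded a dilution-shape calibration")
    if not omegas:
        # series entirely above the solubility: calibrate the half-sine there too
        for w, (cb, _) in zip(windows, series):
            try:
                cal = calibrate_dilution_shape(w, schedule, config, c_before=cb)
            except CalibrationError:
                continue
            omegas.append(cal.omega_per_s)
            deltas.append(cal.delta_s)
            if len(omegas) >= max_windows:
                break
    return DilutionShapeConstants(
        omega_per_s=float(np.median(omegas)),
        delta_s=float(np.median(deltas)),
        w_per_s2=float(np.median(ws)) if ws else None,
        delta_endo_s=float(np.median(d_endos)) if d_endos else None,
    )


def fit_series(
    trace: PowerTrace,
    schedule: Optional[InjectionSchedule] = None,
    config: FitConfig = FitConfig(),
    n_baseline_passes: int = 3,
) -> tuple[pd.DataFrame, list[InjectionResult]]:
    """Run the full decomposition pipeline on a trace.

    Detects peak bounds, corrects the baseline, segments into injection
    windows, calibrates the dilution shape constants (half-sine on the
    first window; Lorentzian on the first window above the solubility
    estimate, if any) and fits every injection.

    With ``n_baseline_passes > 1`` the drift polynomial is re-estimated on
    the trace minus the fitted per-injection models and the windows are
    refitted: near the solubility the dissolution is slow enough to be
    indistinguishable from drift on a single pass, and the refinement stops
    those injections from biasing the shared baseline.
    """
    schedule = schedule or trace.schedule
    if schedule is None:
        raise InvalidInputError("fit_series requires an injection schedule")
    bounds = detect_peak_bounds(
        trace, threshold=config.threshold, smooth_window=config.smooth_window
    )
    corrected = correct_baseline(trace, bounds)
    series = cell_concentration_series(schedule)
    results: list[InjectionResult] = []
    constants: Optional[DilutionShapeConstants] = None

    for _ in range(max(1, n_baseline_passes)):
        windows = segment_injections(corrected, schedule)
        if constants is None:
            constants = _calibrate_constants(windows, schedule, config, series)
        results = [
            fit_injection(w, schedule, config, constants, c_before=cb, c_after=ca)
            for w, (cb, ca) in zip(windows, series)
        ]
        if len(results) < len(series) or not any(r.converged for r in results):
            break
        model = _model_trace_values(trace, schedule, config, constants, results)
        residual = PowerTrace(trace.times.copy(), trace.values - model, dict(trace.meta))
        resid_corr = correct_baseline(residual, bounds)
        corrected = PowerTrace(
            trace.times.copy(), resid_corr.values + model, dict(resid_corr.meta)
        )

    table = assemble_series(results, schedule.spacing_s)
    return table, results
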