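"""Synthetic multi-injection ITC experiments with known ground truth.

The generator emulates the two titration experiments the pipeline is built
for: 27 × 10 μL injections of a 30 mM peptide solution into a 1.46 mL cell
(initially peptide-free, experiment A, or at 4.4 mM, experiment B), 30 s
injections, exothermic slow dissolution governed by the sigmoidal lag-phase
model superposed on fast dilution peaks, plus slow polynomial baseline
drift and Gaussian instrument noise.

Defaults encode the study conditions: monomer solubility c_s = 5 mM,
infinite-dilution inverse rate k₀⁻¹ = 30 s, lag exponent falling from 10 at
infinite dilution toward 1 at c_s, and a molar dissolution enthalpy of
−1.4 kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .analysis import RateModelParams, reversible_rate_inverse
from .errors import ConfigurationError, InvalidInputError
from .forward import (
    K_INJ_DEFAULT,
    DilutionPeak,
    DissolutionKinetics,
    InjectionSchedule,
    aggregate_fraction,
    injection_power,
    step_concentration,
)
from .trace import PowerTrace

__all__ = [
    "NoiseDriftSpec",
    "GeneratorParams",
    "InjectionTruth",
    "SyntheticTruth",
    "cell_concentration_series",
    "first_injection_reaching",
    "kinetics_for_concentration",
    "simulate_experiment",
    "EXPERIMENT_A",
    "EXPERIMENT_B",
]

#: Schedules of the two reference titration experiments.
EXPERIMENT_A = InjectionSchedule(c_inj_mM=30.0, c0_cell_mM=0.0, null_injection=(2.0, 4.0))
EXPERIMENT_B = InjectionSchedule(c_inj_mM=30.0, c0_cell_mM=4.4, null_injection=(2.0, 4.0))


@dataclass(frozen=True)
class NoiseDriftSpec:
    """Instrument imperfections: Gaussian noise and slow polynomial drift.

    drift_coeffs are ascending polynomial coefficients (μJ/s per sᵏ),
    degree ≤ 3, evaluated on absolute time.
    """

    noise_sd_uJ_per_s: float = 0.0
    drift_coeffs: tuple[float, ...] = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_uJ_per_s < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if len(self.drift_coeffs) > 4:
            raise InvalidInputError("drift polynomial degree must be <= 3")


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth physical parameters of a simulated experiment.

    dH_dis_kJ_per_mol converts to the power-model amplitude as
    A = dH_dis·V_cell (μJ/mM), since μJ/(mM·μL) = kJ/mol.  The exothermic
    dilution mode is a half-sine of total heat dil_exo_dH_uJ completing
    within roughly two injection times; above c_s an endothermic Lorentzian
    of heat dil_endo_dH_uJ is added, mirroring the second fast mode resolved
    at high concentration.
    """

    c_s_mM: float = 5.0
    k0_inv_s: float = 30.0
    alpha_low: float = 10.0
    dH_dis_kJ_per_mol: float = -1.4
    dil_exo_dH_uJ: float = -30.0
    dil_endo_dH_uJ: float = 15.0
    omega_per_s: float = math.pi / 60.0
    delta_s: float = math.pi / 12.0  # half-sine starts at delta/omega = 5 s
    w_per_s2: float = (2.0 / 30.0) ** 2
    delta_endo_s: float = 45.0
    k_inj_per_s: float = K_INJ_DEFAULT

    def A_scale_uJ_per_mM(self, schedule: InjectionSchedule) -> float:
        return self.dH_dis_kJ_per_mol * schedule.V_cell_uL

    def exo_peak(self) -> DilutionPeak:
        B = self.dil_exo_dH_uJ * self.omega_per_s / 2.0
        return DilutionPeak.half_sine(B, self.omega_per_s, self.delta_s)

    def endo_peak(self) -> DilutionPeak:
        C = self.dil_endo_dH_uJ * math.sqrt(self.w_per_s2) / math.pi
        return DilutionPeak.lorentzian(C, self.w_per_s2, self.delta_endo_s)


@dataclass(frozen=True)
class InjectionTruth:
    """Ground-truth record of one injection."""

    index: int
    c_before_mM: float
    c_after_mM: float
    kinetics: Optional[DissolutionKinetics]
    peaks: tuple[DilutionPeak, ...]
    enthalpy_dis_uJ: float
    enthalpy_dil_exo_uJ: float
    enthalpy_dil_endo_uJ: float
    dissolved_fraction: float
    excluded: bool = False

    @property
    def enthalpy_total_uJ(self) -> float:
        return self.enthalpy_dis_uJ + self.enthalpy_dil_exo_uJ + self.enthalpy_dil_endo_uJ


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-injection ground truth of a simulated experiment."""

    schedule: InjectionSchedule
    params: GeneratorParams
    injections: tuple[InjectionTruth, ...]

    def __iter__(self):
        return iter(self.injections)

    def injection(self, index: int) -> InjectionTruth:
        """Record of the regular injection with 1-based ``index`` (0 = null)."""
        for rec in self.injections:
            if rec.index == index:
                return rec
        raise KeyError(f"no injection with index {index}")


def cell_concentration_series(
    schedule: InjectionSchedule, displacement: bool = False
) -> list[tuple[float, float]]:
    """(c_before, c_after) pairs for every regular injection (mM).

    Default additive bookkeeping: c_after(n) = c0 + n·Δc₀ (the cell volume
    is treated as constant).  With ``displacement=True`` each injection also
    displaces a cell-volume fraction V_inj/V_cell of the current contents
    (overflow correction); this is not the default because the additive
    model reproduces the experiment's stated concentration checkpoints.
    """
    dc0 = step_concentration(schedule)
    out = []
    c = schedule.c0_cell_mM
    for _ in range(schedule.n_injections):
        if displacement:
            ratio = schedule.V_inj_uL / schedule.V_cell_uL
            c_after = c * (1.0 - ratio) + schedule.c_inj_mM * ratio
        else:
            c_after = c + dc0
        out.append((c, c_after))
        c = c_after
    return out


def first_injection_reaching(schedule: InjectionSchedule, c_s_mM: float) -> Optional[int]:
    """Smallest injection number n (1-based) with c_after(n) ≥ c_s.

    Returns 0 if the cell already starts at or above c_s, and None if the
    solubility is never reached within the schedule.
    """
    if schedule.c0_cell_mM >= c_s_mM:
        return 0
    for n, (_, c_after) in enumerate(cell_concentration_series(schedule), start=1):
        if c_after >= c_s_mM:
            return n
    return None


def kinetics_for_concentration(
    c_mM: float,
    k0_inv_s: float,
    c_s_mM: float,
    alpha_low: float,
    A_scale_uJ_per_mM: float,
    *,
    c_inj_mM: float,
    delta_c0_mM: float,
    k_inj_per_s: float = K_INJ_DEFAULT,
) -> Optional[DissolutionKinetics]:
    """Ground-truth dissolution kinetics at cell concentration c, or None at/above c_s.

    k follows the reversible rate law k⁻¹(c) = k₀⁻¹·c_s/(c_s − c); the lag
    exponent interpolates linearly from alpha_low at c = 0 to 1 at c = c_s
    (a declared modelling choice — the decay of the lag with concentration
    is qualitative in the underlying experiments).
    """
    if c_mM < 0:
        raise InvalidInputError("concentration must be non-negative")
    if c_mM >= c_s_mM:
        return None
    k_inv = reversible_rate_inverse(c_mM, RateModelParams(k0_inv_s, c_s_mM))
    alpha = alpha_low + (1.0 - alpha_low) * c_mM / c_s_mM
    return DissolutionKinetics(
        A_uJ_per_mM=A_scale_uJ_per_mM,
        k_per_s=1.0 / k_inv,
        alpha=max(alpha, 1.0),
        f_agg=aggregate_fraction(c_inj_mM, c_s_mM),
        delta_c0_mM=delta_c0_mM,
        k_inj_per_s=k_inj_per_s,
        c_mon0_mM=c_mM,
    )


def _truth_for_injection(
    index: int,
    c_before: float,
    c_after: float,
    schedule: InjectionSchedule,
    params: GeneratorParams,
) -> InjectionTruth:
    dc0 = step_concentration(schedule)
    kin = kinetics_for_concentration(
        c_before,
        params.k0_inv_s,
        params.c_s_mM,
        params.alpha_low,
        params.A_scale_uJ_per_mM(schedule),
        c_inj_mM=schedule.c_inj_mM,
        delta_c0_mM=dc0,
        k_inj_per_s=params.k_inj_per_s,
    )
    dissolved_fraction = float(np.clip((params.c_s_mM - c_before) / dc0, 0.0, 1.0))
    if kin is not None and dissolved_fraction < 1.0:
        # injection straddles the solubility: only part of the added
        # aggregate can dissolve, scaling the heat amplitude
        kin = replace(kin, A_uJ_per_mM=kin.A_uJ_per_mM * dissolved_fraction)
    peaks: list[DilutionPeak] = [params.exo_peak()]
    if c_before >= params.c_s_mM:
        peaks.append(params.endo_peak())
    dH_dis = 0.0 if kin is None else kin.A_uJ_per_mM * kin.f_agg * kin.delta_c0_mM
    dH_endo = peaks[1].enthalpy_uJ if len(peaks) > 1 else 0.0
    return InjectionTruth(
        index=index,
        c_before_mM=c_before,
        c_after_mM=c_after,
        kinetics=kin,
        peaks=tuple(peaks),
        enthalpy_dis_uJ=dH_dis,
        enthalpy_dil_exo_uJ=peaks[0].enthalpy_uJ,
        enthalpy_dil_endo_uJ=dH_endo,
        dissolved_fraction=dissolved_fraction if kin is not None else 0.0,
    )


def simulate_experiment(
    schedule: InjectionSchedule,
    params: GeneratorParams = GeneratorParams(),
    noise: NoiseDriftSpec = NoiseDriftSpec(),
    dt_s: float = 1.0,
) -> tuple[PowerTrace, SyntheticTruth]:
    """Simulate a full multi-injection trace with per-injection ground truth.

    The trace covers all spacing slots (including the null slot when the
    schedule has a null injection) at uniform sampling dt_s.  Each
    injection's model components are evaluated from its onset to the end of
    the trace, so unfinished dissolution tails carry into later windows just
    as in a real titration.  Deterministic for a fixed seed.
    """
    if dt_s > schedule.t_inj_s / 10.0:
        raise ConfigurationError(
            f"sampling interval {dt_s} s too coarse to resolve {schedule.t_inj_s} s injections"
        )
    n_samples = int(round(schedule.duration_s / dt_s))
    times = np.arange(n_samples) * dt_s
    values = np.polynomial.polynomial.polyval(times, list(noise.drift_coeffs))
    values = np.broadcast_to(values, times.shape).astype(float).copy()

    onsets = schedule.onset_times()
    records: list[InjectionTruth] = []
    for n, ((c_before, c_after), t0) in enumerate(
        zip(cell_concentration_series(schedule), onsets), start=1
    ):
        rec = _truth_for_injection(n, c_before, c_after, schedule, params)
        mask = times >= t0 - dt_s / 2
        values[mask] += injection_power(times[mask] - t0, rec.kinetics, rec.peaks)
        records.append(rec)

    if schedule.has_null:
        # dilution-only blip, scaled by the injected volume, flagged excluded
        v_null, _ = schedule.null_injection
        scale = v_null / schedule.V_inj_uL
        exo = params.exo_peak()
        null_peak = DilutionPeak.half_sine(exo.B_uJ_per_s * scale, exo.omega_per_s, exo.delta_s)
        mask = times >= -dt_s / 2
        values[mask] += injection_power(times[mask], None, (null_peak,))
        records.insert(
            0,
            InjectionTruth(
                index=0,
                c_before_mM=schedule.c0_cell_mM,
                c_after_mM=schedule.c0_cell_mM,
                kinetics=None,
                peaks=(null_peak,),
                enthalpy_dis_uJ=0.0,
                enthalpy_dil_exo_uJ=null_peak.enthalpy_uJ,
                enthalpy_dil_endo_uJ=0.0,
                dissolved_fraction=0.0,
                excluded=True,
            ),
        )

    if noise.noise_sd_uJ_per_s > 0:
        rng = np.random.default_rng(noise.seed)
        values += rng.normal(0.0, noise.noise_sd_uJ_per_s, size=values.shape)

    trace = PowerTrace(times, values, {"schedule": schedule, "dt_s": dt_s})
    return trace, SyntheticTruth(schedule=schedule, params=params, injections=tuple(records))
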