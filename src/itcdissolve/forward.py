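"""Closed-form forward model of a single ITC injection.

An injection adds peptide to the cell along a smoothed concentration ramp
Δc(t) = Δc₀(1 − e^{−k_inj t}).  A fraction f_agg = 1 − c_s/c_inj of the
injected peptide arrives as aggregates; below the monomer solubility c_s
these dissolve with a sigmoidal lag-phase law, so the monomer concentration
evolves as

    c_mon(t) = c_mon(0) + (1 − f_agg)·Δc(t) + f_agg·Δc(t)·(1 − e^{−kt})^α

with dissolution rate constant k and lag exponent α ≥ 1.  The dissolution
contribution to the differential power is A times the time derivative of the
third term, and its time integral is the dissolution enthalpy
ΔH = A·f_agg·Δc₀.  Heats of dilution are described empirically by a
half-sine (exothermic mode) or a Lorentzian (endothermic mode).

Units throughout: time s, power μJ/s, concentration mM, volume μL.  The
differential power is baseline-subtracted; exothermic events are negative
(A < 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "InjectionSchedule",
    "DissolutionKinetics",
    "DilutionPeak",
    "step_concentration",
    "aggregate_fraction",
    "delta_c_ideal",
    "delta_c_smooth",
    "monomer_concentration",
    "dissolution_power",
    "dissolution_enthalpy",
    "dilution_power",
    "injection_power",
    "molar_enthalpy_per_dissolved",
    "molar_enthalpy_per_injected",
]

#: Default injection-ramp smoothing rate (s⁻¹); the exponential ramp with
#: this rate mimics a 30 s linear injection.
K_INJ_DEFAULT = 1.0 / 15.0


def _check_nonnegative_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    return t


@dataclass(frozen=True)
class InjectionSchedule:
    """Geometry and timing of a titration experiment.

    Parameters
    ----------
    c_inj_mM : syringe peptide concentration (mM).
    V_inj_uL : volume of each regular injection (μL).
    V_cell_uL : cell volume (μL), constant throughout the experiment.
    t_inj_s : duration of one injection (s).
    spacing_s : time between consecutive injection onsets (s).
    n_injections : number of regular injections.
    c0_cell_mM : peptide concentration in the cell before the first injection.
    null_injection : optional (volume μL, duration s) of a small lead-in
        injection excluded from analysis and concentration bookkeeping.
    """

    c_inj_mM: float
    V_inj_uL: float = 10.0
    V_cell_uL: float = 1460.0
    t_inj_s: float = 30.0
    spacing_s: float = 3600.0
    n_injections: int = 27
    c0_cell_mM: float = 0.0
    null_injection: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.c_inj_mM < 0 or self.c0_cell_mM < 0:
            raise InvalidInputError("concentrations must be non-negative")
        if min(self.V_inj_uL, self.V_cell_uL, self.t_inj_s, self.spacing_s) <= 0:
            raise InvalidInputError("volumes and durations must be positive")
        if self.V_inj_uL >= self.V_cell_uL:
            raise InvalidInputError("V_inj must be smaller than V_cell")
        if self.n_injections < 1:
            raise InvalidInputError("n_injections must be at least 1")
        if self.spacing_s < self.t_inj_s:
            raise InvalidInputError("spacing must be at least the injection time")
        if self.null_injection is not None:
            v, d = self.null_injection
            if v <= 0 or d <= 0:
                raise InvalidInputError("null injection volume/duration must be positive")

    @property
    def delta_c0_mM(self) -> float:
        """Concentration step Δc₀ = c_inj·V_inj/V_cell of one injection (mM)."""
        return step_concentration(self)

    @property
    def has_null(self) -> bool:
        return self.null_injection is not None

    @property
    def n_slots(self) -> int:
        """Number of spacing slots in the recording, including the null slot."""
        return self.n_injections + int(self.has_null)

    @property
    def duration_s(self) -> float:
        """Total recording duration covered by the schedule (s)."""
        return self.n_slots * self.spacing_s

    def onset_times(self, include_null: bool = False) -> np.ndarray:
        """Onset times of the injections (s).

        The null injection, when present, occupies the first spacing slot;
        regular injection *n* (0-based) then starts at (n+1)·spacing.
        """
        offset = int(self.has_null)
        onsets = (np.arange(self.n_injections) + offset) * self.spacing_s
        if include_null and self.has_null:
            onsets = np.concatenate([[0.0], onsets])
        return onsets


def step_concentration(schedule: InjectionSchedule) -> float:
    """Concentration increase Δc₀ = c_inj·V_inj/V_cell of one injection (mM)."""
    return schedule.c_inj_mM * schedule.V_inj_uL / schedule.V_cell_uL


def aggregate_fraction(c_inj_mM: float, c_s_mM: float) -> float:
    """Fraction f_agg = 1 − c_s/c_inj of injected peptide that is aggregated."""
    if c_inj_mM <= 0:
        raise InvalidInputError("c_inj must be positive")
    if not 0 <= c_s_mM <= c_inj_mM:
        raise InvalidInputError("solubility must satisfy 0 <= c_s <= c_inj")
    return 1.0 - c_s_mM / c_inj_mM


def delta_c_ideal(t, delta_c0_mM: float, t_inj_s: float = 30.0):
    """Ideal (piecewise-linear) added concentration during an injection.

    Linear ramp Δc₀·t/t_inj for t < t_inj, constant Δc₀ afterwards.  Kept
    for reference and testing; the model functions use the smoothed ramp
    :func:`delta_c_smooth`.
    """
    t = _check_nonnegative_time(t)
    if t_inj_s <= 0:
        raise InvalidInputError("t_inj must be positive")
    out = np.where(t < t_inj_s, delta_c0_mM * t / t_inj_s, delta_c0_mM)
    return out if out.ndim else float(out)


def delta_c_smooth(t, delta_c0_mM: float, k_inj_per_s: float = K_INJ_DEFAULT):
    """Smoothed added concentration Δc₀·(1 − e^{−k_inj t}) (mM)."""
    t = _check_nonnegative_time(t)
    if k_inj_per_s <= 0:
        raise InvalidInputError("k_inj must be positive")
    out = delta_c0_mM * -np.expm1(-k_inj_per_s * t)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DissolutionKinetics:
    """Parameters of the dissolution model for one injection.

    A_uJ_per_mM is the heat released per unit dissolved concentration
    (negative = exothermic); k_per_s the dissolution rate constant; alpha
    the lag exponent; f_agg the aggregate fraction of the injected peptide;
    delta_c0_mM the concentration step; c_mon0_mM the monomer concentration
    in the cell before the injection.
    """

    A_uJ_per_mM: float
    k_per_s: float
    alpha: float
    f_agg: float
    delta_c0_mM: float
    k_inj_per_s: float = K_INJ_DEFAULT
    c_mon0_mM: float = 0.0

    def __post_init__(self) -> None:
        if self.k_per_s <= 0 or self.k_inj_per_s <= 0:
            raise InvalidInputError("rate constants must be positive")
        if self.alpha < 1:
            raise InvalidInputError("lag exponent alpha must be >= 1")
        if not 0 <= self.f_agg <= 1:
            raise InvalidInputError("f_agg must lie in [0, 1]")
        if self.delta_c0_mM <= 0:
            raise InvalidInputError("delta_c0 must be positive")


def monomer_concentration(t, params: DissolutionKinetics):
    """Monomer concentration c_mon(t) in the cell during/after an injection (mM)."""
    t = _check_nonnegative_time(t)
    dc = delta_c_smooth(t, params.delta_c0_mM, params.k_inj_per_s)
    sig = (-np.expm1(-params.k_per_s * t)) ** params.alpha
    out = params.c_mon0_mM + (1.0 - params.f_agg) * dc + params.f_agg * dc * sig
    return out if out.ndim else float(out)


def dissolution_power(t, params: DissolutionKinetics):
    """Dissolution contribution ΔP_dis(t) to the differential power (μJ/s).

    Equals A times d/dt of the sigmoidal dissolution term
    f_agg·Δc(t)·(1 − e^{−kt})^α; for α > 1 it vanishes at t = 0 and has a
    single interior extremum (a minimum for exothermic A < 0), reproducing
    the delayed dissolution peak.
    """
    t = _check_nonnegative_time(t)
    k, a, kj = params.k_per_s, params.alpha, params.k_inj_per_s
    u = -np.expm1(-k * t)          # 1 − e^{−kt}
    ekj = np.exp(-kj * t)
    # u**(a-1) with 0**0 == 1 covers the alpha == 1 case at t = 0
    term = kj * ekj * u**a + (1.0 - ekj) * a * k * np.exp(-k * t) * u ** (a - 1.0)
    out = params.A_uJ_per_mM * params.f_agg * params.delta_c0_mM * term
    return out if out.ndim else float(out)


def dissolution_enthalpy(params: DissolutionKinetics) -> float:
    """Total dissolution enthalpy ΔH = ∫₀^∞ ΔP_dis dt = A·f_agg·Δc₀ (μJ)."""
    return params.A_uJ_per_mM * params.f_agg * params.delta_c0_mM


@dataclass(frozen=True)
class DilutionPeak:
    """Empirical shape of one fast dilution peak.

    ``half_sine``: B·sin(ωt − δ) on the half period δ/ω ≤ t ≤ (δ+π)/ω, zero
    outside.  ``lorentzian``: C/[1 + w(t − δ)²].  Only the fields of the
    active shape are meaningful.
    """

    shape: str
    B_uJ_per_s: float = 0.0
    omega_per_s: float = 0.0
    delta_s: float = 0.0
    C_uJ_per_s: float = 0.0
    w_per_s2: float = 0.0

    def __post_init__(self) -> None:
        if self.shape == "half_sine":
            if self.omega_per_s <= 0:
                raise InvalidInputError("half_sine requires omega > 0")
        elif self.shape == "lorentzian":
            if self.w_per_s2 <= 0:
                raise InvalidInputError("lorentzian requires w > 0")
        else:
            raise InvalidInputError(f"unknown dilution peak shape: {self.shape!r}")

    @classmethod
    def half_sine(cls, B_uJ_per_s: float, omega_per_s: float, delta_s: float = 0.0) -> "DilutionPeak":
        return cls("half_sine", B_uJ_per_s=B_uJ_per_s, omega_per_s=omega_per_s, delta_s=delta_s)

    @classmethod
    def lorentzian(cls, C_uJ_per_s: float, w_per_s2: float, delta_s: float = 0.0) -> "DilutionPeak":
        return cls("lorentzian", C_uJ_per_s=C_uJ_per_s, w_per_s2=w_per_s2, delta_s=delta_s)

    @property
    def enthalpy_uJ(self) -> float:
        """Closed-form full-line integral of the peak (μJ)."""
        if self.shape == "half_sine":
            return 2.0 * self.B_uJ_per_s / self.omega_per_s
        return self.C_uJ_per_s * math.pi / math.sqrt(self.w_per_s2)


def dilution_power(t, peak: DilutionPeak):
    """Dilution contribution ΔP_dil(t) of one empirical peak (μJ/s)."""
    t = _check_nonnegative_time(t)
    if peak.shape == "half_sine":
        lo = peak.delta_s / peak.omega_per_s
        hi = (peak.delta_s + math.pi) / peak.omega_per_s
        out = np.where(
            (t >= lo) & (t <= hi),
            peak.B_uJ_per_s * np.sin(peak.omega_per_s * t - peak.delta_s),
            0.0,
        )
    else:
        out = peak.C_uJ_per_s / (1.0 + peak.w_per_s2 * (t - peak.delta_s) ** 2)
    return out if out.ndim else float(out)


def injection_power(t, kinetics: Optional[DissolutionKinetics], peaks: Sequence[DilutionPeak] = ()):
    """Total modelled differential power ΔP = ΔP_dil + ΔP_dis (μJ/s).

    ``kinetics`` is None above the solubility (dilution-only signal).
    """
    t = _check_nonnegative_time(t)
    out = np.zeros_like(t, dtype=float)
    for peak in peaks:
        out = out + dilution_power(t, peak)
    if kinetics is not None:
        out = out + dissolution_power(t, kinetics)
    return out if out.ndim else float(out)


def molar_enthalpy_per_dissolved(
    enthalpy_uJ: float,
    f_agg: float,
    delta_c0_mM: float,
    V_cell_uL: float,
    dissolved_fraction: float = 1.0,
) -> float:
    """Molar enthalpy (kJ/mol) normalised per mole of dissolved aggregate.

    The dissolved amount of one injection is dissolved_fraction·f_agg·Δc₀·V_cell
    (mM·μL = nmol), and μJ/nmol = kJ/mol, so no numeric conversion factor
    appears.
    """
    nmol = dissolved_fraction * f_agg * delta_c0_mM * V_cell_uL
    if nmol <= 0:
        raise InvalidInputError("no dissolved material to normalise by")
    return enthalpy_uJ / nmol


def molar_enthalpy_per_injected(enthalpy_uJ: float, delta_c0_mM: float, V_cell_uL: float) -> float:
    """Molar enthalpy (kJ/mol) normalised per mole of injected peptide."""
    nmol = delta_c0_mM * V_cell_uL
    if nmol <= 0:
        raise InvalidInputError("no injected material to normalise by")
    return enthalpy_uJ / nmol
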