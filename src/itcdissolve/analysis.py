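"""Downstream models: reversible rate law, diffusion-limited reference, pH model.

These are the concentration-dependent interpretations layered on top of the
per-injection fits: how the inverse dissolution rate k⁻¹ grows toward the
solubility c_s, how fast dissolution *would* be if it were diffusion
limited, and how the solution pH above c_s reflects partial deprotonation of
aggregated peptides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError, InvalidInputError

__all__ = [
    "RateModelParams",
    "DiffusionParams",
    "PhModelParams",
    "reversible_rate_inverse",
    "fit_rate_model",
    "diffusion_limited_radius",
    "diffusion_limited_time",
    "ph_model",
    "fit_ph_deprotonation",
    "molar_volume",
]


@dataclass(frozen=True)
class RateModelParams:
    """Reversible dissolution rate law: k⁻¹(c) = k₀⁻¹·c_s/(c_s − c).

    k0_inv_s is the infinite-dilution inverse rate constant (s); c_s_mM the
    monomer solubility (mM).  The net dissolution rate is the difference
    between detachment and attachment, so it vanishes (k⁻¹ diverges) as the
    monomer concentration approaches the solubility.
    """

    k0_inv_s: float
    c_s_mM: float

    def __post_init__(self) -> None:
        if self.k0_inv_s <= 0 or self.c_s_mM <= 0:
            raise InvalidInputError("k0_inv and c_s must be positive")


@dataclass(frozen=True)
class DiffusionParams:
    """Inputs of the diffusion-limited sphere-dissolution reference.

    D_m2_per_s: monomer self-diffusion coefficient (m²/s); v_cm3_per_mol:
    monomer molar volume (cm³/mol); R0_nm: initial aggregate radius (nm);
    c_s_mM: monomer solubility (mM).
    """

    D_m2_per_s: float
    v_cm3_per_mol: float
    R0_nm: float
    c_s_mM: float

    def __post_init__(self) -> None:
        if min(self.D_m2_per_s, self.v_cm3_per_mol, self.c_s_mM) <= 0 or self.R0_nm < 0:
            raise InvalidInputError("diffusion parameters must be positive")


@dataclass(frozen=True)
class PhModelParams:
    """Partial-deprotonation pH model above the solubility.

    Above c_s every aggregated peptide releases a proton with probability f,
    so [H⁺] = (c − c_s)·f and pH = −log₁₀[(c − c_s)·f] with concentrations
    in mol/L.  Below c_s the solution stays at the solvent pH.
    """

    c_s_mM: float
    f: float
    pH_solvent: float = 6.3

    def __post_init__(self) -> None:
        if self.c_s_mM <= 0:
            raise InvalidInputError("c_s must be positive")
        if not 0 < self.f <= 1:
            raise InvalidInputError("deprotonation fraction f must lie in (0, 1]")


def reversible_rate_inverse(c_mM, params: RateModelParams):
    """Inverse dissolution rate k⁻¹(c) = k₀⁻¹·c_s/(c_s − c) (s)."""
    c = np.asarray(c_mM, dtype=float)
    if np.any(c < 0) or np.any(c >= params.c_s_mM):
        raise DomainError("concentration must satisfy 0 <= c < c_s")
    out = params.k0_inv_s * params.c_s_mM / (params.c_s_mM - c)
    return out if out.ndim else float(out)


def fit_rate_model(points: Sequence[tuple[float, float]]) -> tuple[RateModelParams, dict]:
    """Least-squares fit of the reversible rate law to (c mM, k⁻¹ s) points.

    Returns the fitted parameters and a diagnostics dict with standard
    errors and residuals.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(np.unique(pts[:, 0])) < 3:
        raise InvalidInputError("need at least 3 points with distinct concentrations")
    c, k_inv = pts[:, 0], pts[:, 1]
    if np.any(k_inv <= 0):
        raise InvalidInputError("k_inv values must be positive")

    def model(c, k0_inv, c_s):
        return k0_inv * c_s / (c_s - c)

    p0 = (float(k_inv.min()), float(c.max()) * 1.5 + 1e-6)
    try:
        popt, pcov = curve_fit(
            model, c, k_inv, p0=p0,
            bounds=([1e-12, c.max() * (1 + 1e-9)], [np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"rate-law fit did not converge: {exc}") from exc
    resid = k_inv - model(c, *popt)
    diag = {
        "stderr": np.sqrt(np.diag(pcov)),
        "residuals": resid,
        "rss": float(resid @ resid),
    }
    return RateModelParams(k0_inv_s=float(popt[0]), c_s_mM=float(popt[1])), diag


def _vc_dimensionless(params: DiffusionParams) -> float:
    # v [cm³/mol] → m³/mol is ×1e-6; c_s [mM] ≡ mol/m³; the product is a
    # dimensionless volume fraction.
    return params.v_cm3_per_mol * 1e-6 * params.c_s_mM


def diffusion_limited_time(params: DiffusionParams) -> float:
    """Time t = R₀²/(2·D·v·c_s) for a sphere to dissolve by diffusion (s)."""
    R0_m = params.R0_nm * 1e-9
    return R0_m**2 / (2.0 * params.D_m2_per_s * _vc_dimensionless(params))


def diffusion_limited_radius(t, params: DiffusionParams, clamp: bool = False):
    """Radius R(t) = √(R₀² − 2·D·v·c_s·t) of a dissolving sphere (nm).

    Beyond the dissolution time the radicand is negative; by default that is
    a :class:`DomainError`, with ``clamp=True`` the radius is reported as 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    R0_m = params.R0_nm * 1e-9
    radicand = R0_m**2 - 2.0 * params.D_m2_per_s * _vc_dimensionless(params) * t
    if np.any(radicand < 0):
        if not clamp:
            raise DomainError("t exceeds the dissolution time; radius is zero from then on")
        radicand = np.clip(radicand, 0.0, None)
    out = np.sqrt(radicand) * 1e9
    return out if out.ndim else float(out)


def molar_volume(molar_mass_g_per_mol: float = 829.0, density_g_per_cm3: float = 1.5) -> float:
    """Monomer molar volume v = M/ρ (cm³/mol); defaults give ≈550 cm³/mol."""
    if molar_mass_g_per_mol <= 0 or density_g_per_cm3 <= 0:
        raise InvalidInputError("mass and density must be positive")
    return molar_mass_g_per_mol / density_g_per_cm3


def ph_model(c_mM, params: PhModelParams):
    """Solution pH versus total peptide concentration.

    pH = −log₁₀[(c − c_s)·f] (mol/L) above c_s; the solvent pH below.
    """
    c = np.asarray(c_mM, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("concentration must be non-negative")
    above = c > params.c_s_mM
    h_molar = np.where(above, (c - params.c_s_mM) * 1e-3 * params.f, 1.0)
    out = np.where(above, -np.log10(h_molar), params.pH_solvent)
    return out if out.ndim else float(out)


def fit_ph_deprotonation(
    points: Sequence[tuple[float, float]],
    pH_solvent: float = 6.3,
    branch_margin: float = 0.2,
) -> tuple[PhModelParams, dict]:
    """Fit (c_s, f) of the deprotonation model to (c mM, pH) points.

    Only points clearly on the acid branch (pH < pH_solvent − branch_margin)
    constrain the model; the rest are ignored.  f is constrained to (0, 1].
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (c, pH) pairs")
    sel = pts[pts[:, 1] < pH_solvent - branch_margin]
    if len(sel) < 3:
        raise InvalidInputError("need at least 3 points above the solubility (acid branch)")
    c, ph = sel[:, 0], sel[:, 1]

    def model(c, c_s, f):
        return -np.log10((c - c_s) * 1e-3 * f)

    c_min = float(c.min())
    p0 = (0.8 * c_min, 0.5)
    try:
        popt, pcov = curve_fit(
            model, c, ph, p0=p0,
            bounds=([1e-9, 1e-9], [c_min * (1 - 1e-9), 1.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"pH-model fit did not converge: {exc}") from exc
    resid = ph - model(c, *popt)
    diag = {
        "stderr": np.sqrt(np.diag(pcov)),
        "residuals": resid,
        "rss": float(resid @ resid),
        "n_used": len(sel),
    }
    return PhModelParams(c_s_mM=float(popt[0]), f=float(popt[1]), pH_solvent=pH_solvent), diag
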