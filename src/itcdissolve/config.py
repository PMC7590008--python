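"""Versioned pipeline configuration with explicit units in field names.

The experiment mixes mM, μL, μJ and seconds; every numeric field name
carries its unit suffix so a config file cannot silently mix them up.
Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError
from .fitting import FitConfig
from .forward import InjectionSchedule
from .synth import GeneratorParams, NoiseDriftSpec

__all__ = ["PipelineConfig", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScheduleBlock(_Block):
    c_inj_mM: float = 30.0
    V_inj_uL: float = 10.0
    V_cell_uL: float = 1460.0
    t_inj_s: float = 30.0
    spacing_s: float = 3600.0
    n_injections: int = 27
    c0_cell_mM: float = 0.0
    null_injection_uL: Optional[float] = 2.0
    null_injection_s: Optional[float] = 4.0

    def to_schedule(self) -> InjectionSchedule:
        null = None
        if self.null_injection_uL is not None and self.null_injection_s is not None:
            null = (self.null_injection_uL, self.null_injection_s)
        return InjectionSchedule(
            c_inj_mM=self.c_inj_mM,
            V_inj_uL=self.V_inj_uL,
            V_cell_uL=self.V_cell_uL,
            t_inj_s=self.t_inj_s,
            spacing_s=self.spacing_s,
            n_injections=self.n_injections,
            c0_cell_mM=self.c0_cell_mM,
            null_injection=null,
        )


class GeneratorBlock(_Block):
    c_s_mM: float = 5.0
    k0_inv_s: float = 30.0
    alpha_low: float = 10.0
    dH_dis_kJ_per_mol: float = -1.4
    dil_exo_dH_uJ: float = -30.0
    dil_endo_dH_uJ: float = 15.0
    noise_sd_uJ_per_s: float = 0.0
    drift_coeffs: list[float] = Field(default_factory=lambda: [0.0])
    seed: int = 0
    dt_s: float = 1.0

    @field_validator("drift_coeffs")
    @classmethod
    def _degree(cls, v: list[float]) -> list[float]:
        if len(v) > 4:
            raise ValueError("drift polynomial degree must be <= 3")
        return v

    def to_params(self) -> GeneratorParams:
        return GeneratorParams(
            c_s_mM=self.c_s_mM,
            k0_inv_s=self.k0_inv_s,
            alpha_low=self.alpha_low,
            dH_dis_kJ_per_mol=self.dH_dis_kJ_per_mol,
            dil_exo_dH_uJ=self.dil_exo_dH_uJ,
            dil_endo_dH_uJ=self.dil_endo_dH_uJ,
        )

    def to_noise(self, seed: Optional[int] = None) -> NoiseDriftSpec:
        return NoiseDriftSpec(
            noise_sd_uJ_per_s=self.noise_sd_uJ_per_s,
            drift_coeffs=tuple(self.drift_coeffs),
            seed=self.seed if seed is None else seed,
        )


class PreprocessingBlock(_Block):
    threshold_uJ_per_s2: float = 2e-3
    smooth_window: int = 5
    poly_degree: int = 3


class FittingBlock(_Block):
    c_s_estimate_mM: float = 5.0
    k_inj_per_s: float = 1.0 / 15.0
    alpha_min: float = 1.0
    alpha_max: float = 20.0
    alpha_starts: list[float] = Field(default_factory=lambda: [1.5, 3.0, 10.0])
    dissolution: str = "auto"
    n_baseline_passes: int = 3


class AnalysisBlock(_Block):
    D_m2_per_s: float = 2e-10
    v_cm3_per_mol: float = 550.0
    R0_nm: float = 100.0
    c_s_mM: float = 5.0
    pH_solvent: float = 6.3


class PipelineConfig(_Block):
    """Top-level pipeline configuration (schema version 1)."""

    version: int = 1
    schedule: ScheduleBlock = Field(default_factory=ScheduleBlock)
    generator: GeneratorBlock = Field(default_factory=GeneratorBlock)
    preprocessing: PreprocessingBlock = Field(default_factory=PreprocessingBlock)
    fitting: FittingBlock = Field(default_factory=FittingBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)

    def fit_config(self) -> FitConfig:
        f = self.fitting
        return FitConfig(
            c_s_estimate_mM=f.c_s_estimate_mM,
            k_inj_per_s=f.k_inj_per_s,
            alpha_bounds=(f.alpha_min, f.alpha_max),
            alpha_starts=tuple(f.alpha_starts),
            dissolution=f.dissolution,
            threshold=self.preprocessing.threshold_uJ_per_s2,
            smooth_window=self.preprocessing.smooth_window,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: not valid YAML ({exc})") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"{path}: invalid configuration\n{exc}") from exc
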