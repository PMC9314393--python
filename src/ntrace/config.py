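"""Run configuration: validated YAML in, fully reproducible runs out."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .synth import SynthConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Strict):
    resolution: float = 4.0
    lat_range: tuple[float, float] = (-60.0, 84.0)
    lon_range: tuple[float, float] = (-180.0, 180.0)


class SynthSection(_Strict):
    year_start: int = 1800
    year_end: int = 2020
    land_fraction: float = 0.85
    d15n_range: tuple[float, float] = (-5.0, 15.0)
    d15n_sigma: float = 1.0
    sigma_mr: float | tuple[float, float] = (5.4, 0.8)
    sigma_delta: float | tuple[float, float] = (0.5, 0.2)
    sigma_sp: float | tuple[float, float] = (1.2, 0.6)
    sigma_ef: float = 1.5
    era_split_year: int = 1940


class SoilSection(_Strict):
    frac_ex: float = 0.7
    d15n_input: float = -1.5      # permil; the alternative reading is +0.5
    fert_d15n: float = 3.0

    @field_validator("frac_ex")
    @classmethod
    def _frac_ex_range(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("frac_ex must lie in [0, 1]")
        return v


class EmissionSection(_Strict):
    fert_ef_red: float = 0.3
    temp_sens: float = 1.1
    temp_response: str = "linear"
    ef_year: int = 2010

    @field_validator("temp_response")
    @classmethod
    def _resp(cls, v):
        if v not in ("linear", "exponential"):
            raise ValueError("temp_response must be 'linear' or 'exponential'")
        return v


class AtmosSection(_Strict):
    tau_pi: float = 120.0
    mr_pi: float = 270.0
    eps_app_d15n: float = 13.0
    eps_app_sp: float = 6.0
    f_ocean_prior: tuple[float, float] = (4.0, 1.0)
    t_to_s_prior: tuple[float, float] = (0.25, 0.05)


class MCMCSection(_Strict):
    schedule: tuple[float, ...] = (0.75, 0.5, 0.25)
    block: int = 2000
    total: int | None = None


class RunConfig(_Strict):
    """Complete, serializable description of a run (with the seed)."""

    seed: int = 0
    grid: GridSection = Field(default_factory=GridSection)
    synth: SynthSection = Field(default_factory=SynthSection)
    soil: SoilSection = Field(default_factory=SoilSection)
    emission: EmissionSection = Field(default_factory=EmissionSection)
    atmosphere: AtmosSection = Field(default_factory=AtmosSection)
    mcmc: MCMCSection = Field(default_factory=MCMCSection)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            seed=self.seed,
            resolution=self.grid.resolution,
            lat_range=tuple(self.grid.lat_range),
            lon_range=tuple(self.grid.lon_range),
            year_start=self.synth.year_start,
            year_end=self.synth.year_end,
            land_fraction=self.synth.land_fraction,
            d15n_range=tuple(self.synth.d15n_range),
            d15n_sigma=self.synth.d15n_sigma,
            sigma_mr=self.synth.sigma_mr,
            sigma_delta=self.synth.sigma_delta,
            sigma_sp=self.synth.sigma_sp,
            sigma_ef=self.synth.sigma_ef,
            era_split_year=self.synth.era_split_year,
        )

    def build_model(self):
        from dataclasses import replace
        from .atmosphere import AtmosConstants
        from .model import CoupledIsotopeModel
        from .soil import FractionationSet
        constants = AtmosConstants(tau_pi=self.atmosphere.tau_pi,
                                   mr_pi=self.atmosphere.mr_pi,
                                   eps_app_d15n=self.atmosphere.eps_app_d15n,
                                   eps_app_sp=self.atmosphere.eps_app_sp)
        return CoupledIsotopeModel.from_synthetic(
            self.synth_config(),
            fractionation=FractionationSet(frac_ex=self.soil.frac_ex),
            constants=constants,
            d15n_input=self.soil.d15n_input,
            fert_d15n=self.soil.fert_d15n,
            ef_year=self.emission.ef_year,
            temp_response=self.emission.temp_response,
            f_ocean_prior=tuple(self.atmosphere.f_ocean_prior),
            t_to_s_prior=tuple(self.atmosphere.t_to_s_prior),
        )

    def default_params(self) -> dict:
        return {"frac_ex": self.soil.frac_ex,
                "temp_sens": self.emission.temp_sens,
                "fert_ef_red": self.emission.fert_ef_red,
                "tau_pi": self.atmosphere.tau_pi,
                "d15n_input": self.soil.d15n_input}

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=False)
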