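"""Run configuration: YAML schema, defaults, unit normalization.

Configuration values may be numbers (interpreted as SI) or strings with
units ("20 kPa", "1 us"); everything is normalized to SI on load.
Unknown keys are rejected — the silent default is the main
reproducibility hazard in this kind of metrology tool, so every
physical constant actually used in a run is echoed into output headers.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .constitutive import AmbientConditions, Material
from .inversion import FitBounds
from .synthetic import AcquisitionProtocol
from .units import parse_quantity

__all__ = ["RunConfig", "load_config"]

SCHEMA_VERSION = 1


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


def _quantity_validator(*fields):
    return field_validator(*fields, mode="before")(classmethod(
        lambda cls, v: v if v is None else parse_quantity(v)
    ))


class MaterialBlock(_Block):
    elastic_modulus: float = 0.0  # Pa
    kinematic_viscosity: float = 1.0e-6  # m^2/s
    density: float = 997.0  # kg/m^3
    surface_tension: float = 0.072  # N/m
    radial_failure_strain: Optional[float] = None

    _q = _quantity_validator(
        "elastic_modulus", "kinematic_viscosity", "density",
        "surface_tension", "radial_failure_strain",
    )

    def build(self) -> Material:
        return Material(**self.model_dump())


class AmbientBlock(_Block):
    far_field_pressure: float = 101325.0  # Pa
    vapor_pressure: float = 3169.0  # Pa
    adiabatic_index: float = 4.0 / 3.0
    temperature: float = 298.15  # K

    _q = _quantity_validator("far_field_pressure", "vapor_pressure", "temperature")

    def build(self) -> AmbientConditions:
        return AmbientConditions(**self.model_dump())


class SolverBlock(_Block):
    rtol: float = 1e-9
    max_step: Optional[float] = None  # s
    samples_per_segment: int = 400

    _q = _quantity_validator("max_step")


class FitBlock(_Block):
    mode: str = "with_failure"
    fit_time_offset: bool = True
    weighting: str = "point"
    eta_min: float = 0.0
    eta_max: float = 2.0e5  # Pa
    eps_f_rr_min: float = 0.0
    eps_f_rr_max: float = 0.499
    r_max_window_lo: float = 0.9
    r_max_window_hi: float = 1.5
    t0_bound: float = 2.0e-6  # s
    rtol: float = 1e-8
    diff_step: float = 1e-4
    xtol: float = 1e-8
    ftol: float = 1e-10

    _q = _quantity_validator("eta_min", "eta_max", "t0_bound")

    def bounds(self) -> FitBounds:
        return FitBounds(
            r_max_window=(self.r_max_window_lo, self.r_max_window_hi),
            eta=(self.eta_min, self.eta_max),
            eps_f_rr=(self.eps_f_rr_min, self.eps_f_rr_max),
            t0=self.t0_bound,
        )


class ProtocolBlock(_Block):
    delay_step: float = 1.0e-6  # s
    delay_start: float = 0.0
    delay_stop: float = 30.0e-6
    replicates_per_delay: int = 5
    radius_noise_sigma: float = 0.03
    additive_noise_floor: float = 0.0  # m
    seed: int = 0

    _q = _quantity_validator(
        "delay_step", "delay_start", "delay_stop", "additive_noise_floor"
    )

    def build(self, seed: Optional[int] = None) -> AcquisitionProtocol:
        kwargs = self.model_dump()
        if seed is not None:
            kwargs["seed"] = seed
        return AcquisitionProtocol(**kwargs)


class RunConfig(_Block):
    schema_version: int = SCHEMA_VERSION
    material: MaterialBlock = MaterialBlock()
    ambient: AmbientBlock = AmbientBlock()
    solver: SolverBlock = SolverBlock()
    fit: FitBlock = FitBlock()
    protocol: ProtocolBlock = ProtocolBlock()

    def config_hash(self) -> str:
        """Hash of the fully resolved (defaults applied, SI-normalized)
        configuration; embedded in every artifact."""
        canonical = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def header_lines(self) -> list[str]:
        """Provenance header echoing every physical constant in use."""
        from . import __version__

        m, a = self.material, self.ambient
        return [
            f"lcrheo {__version__} config_hash={self.config_hash()} "
            f"schema_version={self.schema_version}",
            f"material: eta={m.elastic_modulus} Pa nu={m.kinematic_viscosity} m^2/s "
            f"rho={m.density} kg/m^3 S={m.surface_tension} N/m "
            f"eps_f_rr={m.radial_failure_strain}",
            f"ambient: p_inf={a.far_field_pressure} Pa p_v={a.vapor_pressure} Pa "
            f"kappa={a.adiabatic_index} T={a.temperature} K",
        ]


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; an empty/absent file yields all
    defaults.  Unknown keys raise with the offending key named."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig(**raw)
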