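"""Simulation configuration: parameter blocks, YAML round trip, validation.

All defaults are documented modelling assumptions in the package's internal
unit system (lengths mm, pressures Pa, time days, except where noted): the
"day" is a simulation time unit, and absolute rate calibrations are
illustrative rather than patient-specific.  See docs/methods.md for the
rationale behind each value.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = [
    "GeometryConfig", "PatientConfig", "MaterialConfig", "GrowthConfig",
    "VasculatureConfig", "FluidConfig", "OxygenConfig", "DrugConfig",
    "SimulationConfig", "ConfigError",
]

SECONDS_PER_DAY = 86400.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass
class GeometryConfig:
    """Concentric-spheres mesh: 5 mm tumor seed inside a 50 mm host ball."""

    tumor_radius: float = 5.0      # mm
    host_radius: float = 50.0     # mm
    n_tumor_shells: int = 3
    n_host_shells: int = 3
    grading_ratio: float = 1.9


@dataclasses.dataclass
class PatientConfig:
    """Synthetic elastography / DTI virtual-patient generator parameters."""

    seed: int = 0
    mre_frequency_hz: float = 30.0      # driving frequency of the stiffness maps
    host_storage_mean: float = 1500.0   # G' mean, Pa
    host_storage_sd: float = 400.0      # heterogeneity amplitude, Pa
    correlation_length: float = 3.0     # mm (gyral-scale stiffness variation)
    loss_ratio: float = 0.4             # G''/G'
    clip_floor: float = 100.0           # Pa, lower clip of generated moduli
    tumor_storage: float = 1100.0       # Pa, mean seed stiffness
    tumor_storage_sd: float = 290.0     # Pa, intratumoral heterogeneity amplitude
    voxel_spacing: float = 2.0          # mm, generated field resolution
    dti_base: float = 0.05              # mm²/day cell diffusivity scale
    dti_anisotropy: float = 0.3         # fractional long-axis enhancement
    heterogeneous: bool = True          # False: constant-modulus control


@dataclasses.dataclass
class MaterialConfig:
    k_bulk: float = 20000.0   # Pa (near-incompressible, k/G ~ 20)
    isochoric: bool = True    # isochoric-invariant form of the shear energy


@dataclasses.dataclass
class GrowthConfig:
    k1: float = 0.06          # 1/day, max mass growth rate
    k2: float = 0.1           # oxygen level of half-maximal growth
    rho_cell: float = 0.012   # 1/day, host-side proliferation
    anisotropy: float = 0.0   # A: 0 isotropic; 25/50 stress-directed
    dt: float = 0.5           # day, growth step
    duration: float = 43.0    # days


@dataclasses.dataclass
class VasculatureConfig:
    s_v0: float = 0.7         # 1/mm (70 cm⁻¹) initial functional density
    sigma_half: float = 1000.0  # Pa of compressive bulk stress halving d/d₀


@dataclasses.dataclass
class FluidConfig:
    k_th: float = 3.1e-8      # mm²/(Pa·s) hydraulic conductivity
    p_v: float = 2000.0       # Pa vascular (gauge) pressure
    lymph_coeff: float = 1.0e-9  # L_Pl·S_vl, 1/(Pa·s), host only
    p_vl: float = 0.0         # Pa lymphatic pressure


@dataclasses.dataclass
class OxygenConfig:
    d_ox: float = 172.8       # mm²/day (2e-3 mm²/s)
    per_ox: float = 30.0      # mm/day vascular permeability to oxygen
    c_iox: float = 1.0        # vascular oxygen level (model units)
    a_ox: float = 40.0        # 1/day max uptake per unit cell density
    k_ox: float = 0.15        # Michaelis constant (model units)


@dataclasses.dataclass
class DrugConfig:
    drug_radius_nm: float = 70.0   # drug size (radius convention)
    pore_radius_nm: float = 200.0  # vessel-wall pore size
    gamma: float = 0.05            # pore area fraction of the wall
    eta_pa_s: float = 3.0e-3       # plasma viscosity
    l_vw_um: float = 5.0           # wall thickness
    temperature_k: float = 310.0   # for the Stokes–Einstein free diffusivity
    d_f_factor: float = 0.3        # tissue diffusivity as a fraction of D₀
    kon_ce_phi: float = 100.0      # 1/day effective binding rate k_on·c_e·Φ
    k_off: float = 10.0            # 1/day
    k_int: float = 10.0            # 1/day
    k_d: float = 1.0               # day, bolus circulation decay
    t_injection: float = 41.0      # day
    t_readout: float = 43.0        # day
    dt_minutes: float = 1.0        # drug sub-step

    def stokes_einstein_d0(self) -> float:
        """Free-solution diffusivity D₀ in mm²/s from the drug radius."""
        k_b = 1.380649e-23
        r_m = self.drug_radius_nm * 1e-9
        d0_m2_s = k_b * self.temperature_k / (6.0 * 3.141592653589793 * self.eta_pa_s * r_m)
        return d0_m2_s * 1e6  # m²/s → mm²/s

    @property
    def lambda_ratio(self) -> float:
        return min(1.0, self.drug_radius_nm / self.pore_radius_nm)


@dataclasses.dataclass
class SimulationConfig:
    geometry: GeometryConfig = dataclasses.field(default_factory=GeometryConfig)
    patient: PatientConfig = dataclasses.field(default_factory=PatientConfig)
    material: MaterialConfig = dataclasses.field(default_factory=MaterialConfig)
    growth: GrowthConfig = dataclasses.field(default_factory=GrowthConfig)
    vasculature: VasculatureConfig = dataclasses.field(default_factory=VasculatureConfig)
    fluid: FluidConfig = dataclasses.field(default_factory=FluidConfig)
    oxygen: OxygenConfig = dataclasses.field(default_factory=OxygenConfig)
    drug: DrugConfig = dataclasses.field(default_factory=DrugConfig)
    output_dir: str | None = None
    write_fields: bool = False     # per-checkpoint VTK output
    checkpoint_days: float = 1.0

    def validate(self) -> "SimulationConfig":
        g = self.geometry
        if not 0 < g.tumor_radius < g.host_radius:
            raise ConfigError("need 0 < tumor_radius < host_radius")
        gr = self.growth
        if gr.dt <= 0 or gr.duration < 0:
            raise ConfigError("growth dt must be positive and duration non-negative")
        d = self.drug
        if not (0 <= d.t_injection <= d.t_readout):
            raise ConfigError("need 0 <= injection time <= readout time")
        if d.t_readout > gr.duration and gr.duration > 0:
            raise ConfigError("readout time exceeds simulation duration")
        if self.vasculature.sigma_half <= 0:
            raise ConfigError("sigma_half must be positive")
        return self

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    _SECTIONS = {
        "geometry": GeometryConfig, "patient": PatientConfig,
        "material": MaterialConfig, "growth": GrowthConfig,
        "vasculature": VasculatureConfig, "fluid": FluidConfig,
        "oxygen": OxygenConfig, "drug": DrugConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        valid_top = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for name, value in data.items():
            if name not in valid_top:
                raise ConfigError(f"unknown config section: {name!r}")
            sub_cls = cls._SECTIONS.get(name)
            if sub_cls is not None:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {name!r} must be a mapping")
                unknown = set(value) - {sf.name for sf in dataclasses.fields(sub_cls)}
                if unknown:
                    raise ConfigError(f"unknown keys in {name}: {sorted(unknown)}")
                kwargs[name] = sub_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
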