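"""Canonical parameter registry and scenario configuration.

All models store SI values (m, s, Pa, mol/m^3, K-offsets in deg C where noted).
Quantities that the tumor-transport literature quotes in cm/mmHg/h units are
converted once, at document-load time (see ``load_scenario``); the mapping of
config keys to their input units is in ``INPUT_UNITS``.

Defaults fall into three groups:

* printed tissue/transport/drug constants (tissue density, conductivity and
  heat capacity; Starling and Darcy coefficients; Dox binding, uptake and
  survival constants; the 42 deg C liposome release rate);
* standard magnetite and Pennes-model values that any such simulation needs
  but that are not tabulated (domain magnetization, attempt time, blood
  heat capacity, perfusion, metabolic heat);
* calibrated values (anisotropy constant, MNP effective deposition radius,
  plasma decay constants, liposome vessel-wall permeability scale, pore-size
  spread), produced by ``scripts/calibrate.py`` against the printed
  treatment observables and documented in docs/methods.md.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .units import convert_units

KB = 1.380649e-23  # Boltzmann constant, J/K
MU0 = 4.0e-7 * math.pi  # vacuum permeability, H/m
R_GAS = 8.314  # J/(mol K)
T_BODY_C = 37.0
CELSIUS_OFFSET = 273.15

# ---------------------------------------------------------------------------
# calibrated defaults (scripts/calibrate.py; see docs/methods.md)
# ---------------------------------------------------------------------------
KEFF_DEFAULT = 4.3934e4  # J/m^3, anisotropy constant; thermal calibration
MNP_DEPOSITION_RADIUS_DEFAULT = 5.0e-3  # m, effective MNP spread radius
PERFUSION_TUMOR_DEFAULT = 1.0e-4  # 1/s
PERFUSION_NORMAL_DEFAULT = 5.0e-4  # 1/s
KD_TSL_DEFAULT = 1.08e5  # s (~30 h), liposome plasma decay time constant
KD_FREE_DEFAULT = 8.3e3  # s (~2.3 h), free-Dox plasma decay time constant
TSL_PERMEABILITY_SCALE_DEFAULT = 2.6e-8  # m/s, vessel-wall scale for TSLs
PORE_GSD_DEFAULT = 2.0  # geometric SD of the vessel pore-size distribution


class ValidationError(ValueError):
    """A scenario document violated a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class TissueThermalParams(_Block):
    """Pennes bioheat coefficients for one tissue region."""

    density: float = 1060.0  # kg/m^3
    specific_heat: float = 3600.0  # J/(kg degC)
    thermal_conductivity: float = 0.59  # W/(m degC)
    blood_density: float = 1000.0  # kg/m^3
    blood_specific_heat: float = 3600.0  # J/(kg degC)
    perfusion_rate: float = PERFUSION_NORMAL_DEFAULT  # 1/s
    arterial_temperature: float = T_BODY_C  # deg C
    # basal metabolic heat is folded into the 37 deg C reference state (the
    # pre-treatment tissue is in thermal equilibrium); set a nonzero value
    # to model excess metabolic load explicitly
    metabolic_heat: float = 0.0  # W/m^3
    mnp_source_scale: float = 1.0  # alpha in the bioheat source term

    @model_validator(mode="after")
    def _invariants(self) -> "TissueThermalParams":
        for name in ("density", "specific_heat", "thermal_conductivity",
                     "blood_density", "blood_specific_heat"):
            _require(getattr(self, name) > 0, f"thermal.{name} must be > 0")
        _require(self.perfusion_rate >= 0, "thermal.perfusion_rate must be >= 0")
        _require(self.metabolic_heat >= 0, "thermal.metabolic_heat must be >= 0")
        _require(0.0 <= self.mnp_source_scale <= 1.0,
                 "thermal.mnp_source_scale must be in [0, 1]")
        return self

    @property
    def volumetric_heat_capacity(self) -> float:
        return self.density * self.specific_heat

    @property
    def perfusion_heat_coefficient(self) -> float:
        """rho_b * C_b * omega_b, W/(m^3 degC)."""
        return self.blood_density * self.blood_specific_heat * self.perfusion_rate


def normal_tissue_thermal() -> TissueThermalParams:
    return TissueThermalParams(
        density=1060.0, thermal_conductivity=0.59, specific_heat=3600.0,
        perfusion_rate=PERFUSION_NORMAL_DEFAULT)


def tumor_tissue_thermal() -> TissueThermalParams:
    return TissueThermalParams(
        density=1040.0, thermal_conductivity=0.57, specific_heat=3600.0,
        perfusion_rate=PERFUSION_TUMOR_DEFAULT)


class MagneticSpec(_Block):
    """Magnetite nanoparticle and suspension properties."""

    core_diameter: float = 10e-9  # m; superparamagnetic regime requires <= 20 nm
    coating_thickness: float = 0.0  # m
    volume_fraction: float = 0.033  # ferrofluid solids fraction at injection
    anisotropy_constant: float = KEFF_DEFAULT  # J/m^3
    domain_magnetization: float = 446e3  # A/m (magnetite)
    attempt_time: float = 1e-9  # s
    suspension_viscosity: float = 1e-3  # Pa s
    particle_density: float = 5180.0  # kg/m^3
    particle_specific_heat: float = 670.0  # J/(kg K)
    particle_conductivity: float = 528.0  # W/(m degC)
    neel_form: Literal["rosensweig", "literal"] = "rosensweig"
    rosensweig_pi: bool = False  # insert the textbook pi prefactor in Q_MNP

    @model_validator(mode="after")
    def _invariants(self) -> "MagneticSpec":
        _require(0 < self.core_diameter <= 20e-9,
                 "magnetic.core_diameter must be in (0, 20 nm] "
                 "(single-domain superparamagnetic regime)")
        _require(self.coating_thickness >= 0,
                 "magnetic.coating_thickness must be >= 0")
        _require(0.0 < self.volume_fraction < 1.0,
                 "magnetic.volume_fraction must be in (0, 1)")
        for name in ("anisotropy_constant", "domain_magnetization",
                     "attempt_time", "suspension_viscosity"):
            _require(getattr(self, name) > 0, f"magnetic.{name} must be > 0")
        return self

    @property
    def magnetic_volume(self) -> float:
        """Core volume V_M = pi/6 d^3, m^3."""
        return math.pi / 6.0 * self.core_diameter**3

    @property
    def hydrodynamic_volume(self) -> float:
        """Coated volume V_H = pi/6 (d + 2 t)^3, m^3."""
        return math.pi / 6.0 * (self.core_diameter + 2 * self.coating_thickness) ** 3


class FieldSpec(_Block):
    """Alternating magnetic field exposure."""

    amplitude: float = 11e3  # A/m
    frequency: float = 400e3  # Hz
    on_time: float = 0.0  # s, AMF switch-on within the heating stage
    off_time: float = 3600.0  # s, AMF switch-off
    safety_product_limit: float = 5e9  # A/(m s), clinical H*f bound

    @model_validator(mode="after")
    def _invariants(self) -> "FieldSpec":
        _require(self.amplitude >= 0, "field.amplitude must be >= 0")
        _require(self.frequency >= 0, "field.frequency must be >= 0")
        _require(self.on_time < self.off_time,
                 "field.on_time must be < field.off_time")
        product = self.amplitude * self.frequency
        _require(product <= self.safety_product_limit,
                 f"field amplitude*frequency = {product:.3g} A/(m s) exceeds "
                 f"safety_product_limit = {self.safety_product_limit:.3g}; raise "
                 "field.safety_product_limit explicitly to run such an exposure")
        return self


class ArrheniusParams(_Block):
    """First-order thermal damage kinetics."""

    frequency_factor: float = 1.98e106  # 1/s
    activation_energy: float = 6.67e5  # J/mol
    gas_constant: float = R_GAS  # J/(mol K)

    @model_validator(mode="after")
    def _invariants(self) -> "ArrheniusParams":
        for name in ("frequency_factor", "activation_energy", "gas_constant"):
            _require(getattr(self, name) > 0, f"arrhenius.{name} must be > 0")
        return self


class FlowParams(_Block):
    """Darcy-Starling interstitial fluid parameters (SI)."""

    interstitium_hydraulic_conductivity: float = 4.13e-8 * 1e-4 / 133.322  # m^2/(Pa s)
    vessel_hydraulic_conductivity: float = 2.80e-7 * 1e-2 / 133.322  # m/(Pa s)
    vessel_area_density: float = 2.0e4  # 1/m
    vascular_pressure: float = 15.6 * 133.322  # Pa
    plasma_osmotic_pressure: float = 20.0 * 133.322  # Pa
    interstitial_osmotic_pressure: float = 15.0 * 133.322  # Pa
    osmotic_reflection: float = 0.82
    lymph_drainage: float = 0.0  # 1/s; zero inside the tumor
    # normal tissue: functional lymphatics drain the interstitium toward
    # zero pressure ('lymphatic_sink', the standard Baxter-Jain picture,
    # which produces the near-zero peritumoral IFP and the outward rim
    # velocity); 'net_zero' suppresses any net fluid exchange there and
    # 'starling' applies the tumor-style source everywhere
    normal_tissue_source: Literal["lymphatic_sink", "net_zero", "starling"] = \
        "lymphatic_sink"

    @model_validator(mode="after")
    def _invariants(self) -> "FlowParams":
        _require(self.interstitium_hydraulic_conductivity > 0,
                 "flow.interstitium_hydraulic_conductivity must be > 0")
        _require(self.vessel_hydraulic_conductivity >= 0,
                 "flow.vessel_hydraulic_conductivity must be >= 0")
        _require(0.0 <= self.osmotic_reflection <= 1.0,
                 "flow.osmotic_reflection must be in [0, 1]")
        _require(self.lymph_drainage >= 0, "flow.lymph_drainage must be >= 0")
        return self

    @property
    def effective_pressure(self) -> float:
        """p_e = P_b - sigma_s (pi_B - pi_i), Pa; the filtration driving head."""
        return self.vascular_pressure - self.osmotic_reflection * (
            self.plasma_osmotic_pressure - self.interstitial_osmotic_pressure)


class DrugParams(_Block):
    """Doxorubicin / thermosensitive-liposome transport and kinetics (SI)."""

    tsl_diffusivity: float = 4.5e-13  # m^2/s, hindered interstitial diffusion
    free_drug_diffusivity: float = 3.4e-10  # m^2/s
    vessel_permeability_free: float = 3.0e-6  # m/s
    # None -> computed from the hindered-pore closure (carrier vs pore size)
    vessel_permeability_tsl: float | None = None
    filtration_reflection_free: float = 0.0
    filtration_reflection_tsl: float | None = None
    tsl_permeability_scale: float = TSL_PERMEABILITY_SCALE_DEFAULT  # m/s
    pore_gsd: float = PORE_GSD_DEFAULT
    release_rate_at_42: float = 0.05409  # 1/s
    release_threshold_low: float = 39.0  # deg C
    release_threshold_high: float = 42.0  # deg C
    release_ramp: Literal["linear", "exponential"] = "linear"
    binding_on: float = 1.5  # m^3/(mol s)  (= 1.5e3 1/(M s))
    binding_off: float = 8e-3  # 1/s
    internalization: float = 5e-5  # 1/s
    accessible_fraction: float = 0.3
    receptor_concentration: float = 0.01  # mol/m^3 (= 1e-5 M)
    survival_constant: float = 0.6603  # m^3/mol
    plasma_decay: float = KD_TSL_DEFAULT  # s, TSL time constant (Eq. CpL decay)
    plasma_decay_free: float = KD_FREE_DEFAULT  # s, free-Dox time constant
    initial_plasma_dose: float = 1.0  # mol/m^3
    carrier_diameter: float = 100e-9  # m
    vessel_pore_diameter: float = 200e-9  # m, tumor vasculature
    normal_pore_diameter: float = 12e-9  # m, healthy vasculature
    allow_out_of_range: bool = False

    @model_validator(mode="after")
    def _invariants(self) -> "DrugParams":
        for name in ("free_drug_diffusivity", "binding_on", "binding_off",
                     "internalization", "receptor_concentration",
                     "survival_constant", "plasma_decay", "plasma_decay_free",
                     "carrier_diameter", "vessel_pore_diameter"):
            _require(getattr(self, name) > 0, f"drug.{name} must be > 0")
        _require(self.tsl_diffusivity >= 0, "drug.tsl_diffusivity must be >= 0")
        _require(0.0 <= self.filtration_reflection_free <= 1.0,
                 "drug.filtration_reflection_free must be in [0, 1]")
        if self.filtration_reflection_tsl is not None:
            _require(0.0 <= self.filtration_reflection_tsl <= 1.0,
                     "drug.filtration_reflection_tsl must be in [0, 1]")
        _require(0.0 < self.accessible_fraction <= 1.0,
                 "drug.accessible_fraction must be in (0, 1]")
        _require(self.release_threshold_low < self.release_threshold_high,
                 "drug.release_threshold_low must be < release_threshold_high")
        _require(self.pore_gsd >= 1.0, "drug.pore_gsd must be >= 1")
        if not self.allow_out_of_range:
            _require(0.5 <= self.initial_plasma_dose <= 1.5,
                     "drug.initial_plasma_dose outside the documented "
                     "0.5-1.5 mol/m^3 range; set drug.allow_out_of_range to "
                     "override")
        return self


class TreatmentMode(str, Enum):
    CHEMO = "chemo"
    MHT_ONLY = "mht_only"
    COMBINATION = "combination"


class GeometryConfig(_Block):
    injection_radius: float = 0.25e-2  # m
    tumor_radius: float = 1.0e-2  # m
    outer_radius: float = 3.0e-2  # m

    @model_validator(mode="after")
    def _invariants(self) -> "GeometryConfig":
        _require(0 < self.injection_radius < self.tumor_radius < self.outer_radius,
                 "geometry radii must satisfy 0 < injection < tumor < outer")
        return self


class ScheduleConfig(_Block):
    delay: float = 9 * 3600.0  # s, TSL injection -> AMF start
    amf_duration: float = 3600.0  # s
    horizon: float = 72 * 3600.0  # s, from TSL injection

    @model_validator(mode="after")
    def _invariants(self) -> "ScheduleConfig":
        _require(self.delay >= 0, "schedule.delay must be >= 0")
        _require(self.amf_duration > 0, "schedule.amf_duration must be > 0")
        _require(self.horizon >= self.delay + self.amf_duration,
                 "schedule.horizon must cover delay + amf_duration")
        return self


class SolverConfig(_Block):
    n_injection: int = 20
    n_tumor: int = 80  # nodes across the tumor annulus (>= 50 contract)
    n_normal: int = 60
    grading: float = 3.0  # refinement strength toward region interfaces
    dt_thermal: float = 3.6  # s (0.001 h, fixed-step parity mode)
    dt_transport: float = 18.0  # s, outside the AMF window
    dt_transport_mht: float = 3.6  # s, during the AMF window
    checkpoint_interval: float = 360.0  # s, time-series cadence
    steady_tolerance: float = 1e-6  # K/s, |dT/dt| threshold
    mass_balance_tolerance: float = 5e-3  # relative drift -> hard error
    cooldown_stop_temperature: float = 37.5  # deg C, Arrhenius accumulation stop
    seed: int | None = None  # no stochastic components by default

    @model_validator(mode="after")
    def _invariants(self) -> "SolverConfig":
        _require(self.n_tumor + self.n_injection >= 50,
                 "solver: at least 50 nodes are required across the tumor")
        for name in ("dt_thermal", "dt_transport", "dt_transport_mht",
                     "checkpoint_interval"):
            _require(getattr(self, name) > 0, f"solver.{name} must be > 0")
        return self


class ThermalConfig(_Block):
    normal: TissueThermalParams = Field(default_factory=normal_tissue_thermal)
    tumor: TissueThermalParams = Field(default_factory=tumor_tissue_thermal)
    # effective radius over which injected MNPs deposit; the ferrofluid dose
    # (0.45 cm^3 at the nominal volume fraction) is conserved when it spreads
    mnp_deposition_radius: float = MNP_DEPOSITION_RADIUS_DEFAULT  # m
    conserve_mnp_dose: bool = True
    conductivity_mixing: Literal["arithmetic", "maxwell_garnett"] = "arithmetic"

    @model_validator(mode="after")
    def _invariants(self) -> "ThermalConfig":
        _require(self.mnp_deposition_radius > 0,
                 "thermal.mnp_deposition_radius must be > 0")
        return self


class ScenarioConfig(_Block):
    mode: TreatmentMode = TreatmentMode.COMBINATION
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    thermal: ThermalConfig = Field(default_factory=ThermalConfig)
    magnetic: MagneticSpec = Field(default_factory=MagneticSpec)
    field: FieldSpec = Field(default_factory=FieldSpec)
    arrhenius: ArrheniusParams = Field(default_factory=ArrheniusParams)
    flow: FlowParams = Field(default_factory=FlowParams)
    drug: DrugParams = Field(default_factory=DrugParams)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)

    @model_validator(mode="after")
    def _invariants(self) -> "ScenarioConfig":
        _require(self.thermal.mnp_deposition_radius <= self.geometry.tumor_radius,
                 "thermal.mnp_deposition_radius must lie within the tumor")
        return self

    def to_dict(self) -> dict[str, Any]:
        return self.model_dump(mode="json")


# ---------------------------------------------------------------------------
# document loading
# ---------------------------------------------------------------------------

# config keys whose YAML value is given in a non-SI input unit
INPUT_UNITS: dict[tuple[str, str], tuple[str, str]] = {
    ("flow", "interstitium_hydraulic_conductivity"): ("cm^2/(mmHg*s)", "m^2/(Pa*s)"),
    ("flow", "vessel_hydraulic_conductivity"): ("cm/(mmHg*s)", "m/(Pa*s)"),
    ("flow", "vessel_area_density"): ("1/cm", "1/m"),
    ("flow", "vascular_pressure"): ("mmHg", "Pa"),
    ("flow", "plasma_osmotic_pressure"): ("mmHg", "Pa"),
    ("flow", "interstitial_osmotic_pressure"): ("mmHg", "Pa"),
    ("drug", "free_drug_diffusivity"): ("cm^2/s", "m^2/s"),
    ("drug", "tsl_diffusivity"): ("cm^2/s", "m^2/s"),
    ("drug", "vessel_permeability_free"): ("cm/s", "m/s"),
    ("drug", "vessel_permeability_tsl"): ("cm/s", "m/s"),
    ("drug", "tsl_permeability_scale"): ("cm/s", "m/s"),
    ("drug", "receptor_concentration"): ("M", "mol/m^3"),
    ("drug", "binding_on"): ("M", "mol/m^3"),  # handled specially below
    ("geometry", "injection_radius"): ("cm", "m"),
    ("geometry", "tumor_radius"): ("cm", "m"),
    ("geometry", "outer_radius"): ("cm", "m"),
    ("thermal", "mnp_deposition_radius"): ("cm", "m"),
    ("drug", "carrier_diameter"): ("nm", "m"),
    ("drug", "vessel_pore_diameter"): ("nm", "m"),
    ("drug", "normal_pore_diameter"): ("nm", "m"),
    ("schedule", "delay"): ("h", "s"),
    ("schedule", "amf_duration"): ("h", "s"),
    ("schedule", "horizon"): ("h", "s"),
    ("drug", "plasma_decay"): ("h", "s"),
    ("drug", "plasma_decay_free"): ("h", "s"),
    ("magnetic", "core_diameter"): ("nm", "m"),
    ("magnetic", "coating_thickness"): ("nm", "m"),
}


def _convert_block(block: str, data: dict[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in data.items():
        if isinstance(value, dict):
            out[key] = _convert_block(f"{block}.{key}", value)
            continue
        lookup = (block.split(".")[0], key)
        if value is not None and lookup in INPUT_UNITS:
            if lookup == ("drug", "binding_on"):
                # 1/(M s) -> m^3/(mol s): divide by 1000
                value = value / 1000.0
            else:
                src, dst = INPUT_UNITS[lookup]
                value = convert_units(float(value), src, dst)
        out[key] = value
    return out


def _check_known_keys(data: dict[str, Any], model: type[BaseModel], path: str = "") -> None:
    fields = model.model_fields
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in fields:
            raise ValidationError(f"unknown configuration key: {where!r}")
        ann = fields[key].annotation
        if isinstance(value, dict) and isinstance(ann, type) and issubclass(ann, BaseModel):
            _check_known_keys(value, ann, where)


def _deep_merge(base: dict[str, Any], override: dict[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_scenario(config_text: str = "", assume_si: bool = False) -> ScenarioConfig:
    """Parse a YAML scenario document into a fully resolved SI configuration.

    An empty document yields the default scenario.  Unknown keys are rejected
    with their key path; invariant violations raise ``ValidationError`` naming
    the offending invariant.  Values for keys listed in ``INPUT_UNITS`` are
    given in the documented input unit and converted here; pass
    ``assume_si=True`` for documents that are already SI throughout (e.g. a
    ``resolved_config.yaml`` echoed by a previous run).
    """
    raw = yaml.safe_load(config_text) if config_text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("scenario document must be a mapping")
    _check_known_keys(raw, ScenarioConfig)
    if assume_si:
        converted = raw
    else:
        converted = {
            block: (_convert_block(block, value) if isinstance(value, dict) else value)
            for block, value in raw.items()
        }
    try:
        return ScenarioConfig.model_validate(converted)
    except ValidationError:
        raise
    except Exception as exc:  # pydantic error -> uniform validation error
        raise ValidationError(str(exc)) from exc


def load_scenario_file(path: str) -> ScenarioConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return load_scenario(fh.read())


def apply_overrides(config: ScenarioConfig, overrides: dict[str, Any]) -> ScenarioConfig:
    """Return a new config with dotted-path overrides applied (SI values)."""
    data = config.model_dump()
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        node = data
        for part in parts[:-1]:
            if part not in node:
                raise ValidationError(f"unknown configuration key: {dotted!r}")
            node = node[part]
        if parts[-1] not in node:
            raise ValidationError(f"unknown configuration key: {dotted!r}")
        node[parts[-1]] = value
    try:
        return ScenarioConfig.model_validate(data)
    except ValidationError:
        raise
    except Exception as exc:
        raise ValidationError(str(exc)) from exc
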