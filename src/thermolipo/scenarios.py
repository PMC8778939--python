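"""Scenario orchestration: flow -> heating -> transport -> pharmacodynamics.

A scenario is one treatment protocol on the nested spherical geometry:

* ``chemo`` - conventional free-doxorubicin bolus, no heating;
* ``mht_only`` - intratumoral MNPs plus one AMF exposure, no drug;
* ``combination`` - TSL-Dox bolus at t = 0, AMF applied after the scheduled
  delay, transport followed to the horizon.

All stages are deterministic fixed-step solves, so re-running an identical
configuration reproduces every output bit for bit.
"""

from __future__ import annotations

import importlib.resources
import time as _time
from dataclasses import dataclass, field

import numpy as np

from . import bioheat as _bioheat
from .bioheat import (
    TemperatureHistory,
    ThermalDamageField,
    material_fields,
    mnp_source_field,
    run_heating_stage,
    steady_energy_audit,
)
from .flow import FlowSolution, solve_ifp
from .grid import RadialGrid, build_grid
from .params import ScenarioConfig, TreatmentMode, apply_overrides, load_scenario
from .pharmacodynamics import EfficacyReport, combine_kill
from .transport import TransportResult, run_transport


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    grid: RadialGrid
    flow: FlowSolution
    temperature: TemperatureHistory | None
    damage: ThermalDamageField | None
    transport: TransportResult | None
    efficacy: EfficacyReport
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> dict:
        cfg = self.config
        out: dict = {
            "mode": cfg.mode.value,
            "fkc_heat": self.efficacy.fkc_heat,
            "fkc_drug": self.efficacy.fkc_drug,
            "fkc_combined": self.efficacy.fkc_combined,
            "decomposition": self.efficacy.decomposition,
            "mean_ci_terminal": self.efficacy.mean_ci,
            "ifp_center_mmhg": float(self.flow.pressure_mmhg[0]),
        }
        if self.temperature is not None:
            probes = self.temperature.probes
            idx = int(np.argmin(np.abs(
                self.temperature.times - cfg.schedule.amf_duration)))
            out["temperature_end_heating"] = {
                name: float(series[idx]) for name, series in probes.items()}
            out["temperature_max"] = {
                name: float(series.max()) for name, series in probes.items()}
        if self.transport is not None:
            t_peak, ci_peak = self.transport.peak("ci")
            out["peak_mean_ci"] = ci_peak
            out["peak_mean_ci_time_h"] = t_peak / 3600.0
            t_peak_l, cl_peak = self.transport.peak("cl")
            out["peak_mean_cl"] = cl_peak
            out["peak_mean_cl_time_h"] = t_peak_l / 3600.0
            out["mass_audit"] = self.transport.state.mass_audit()
        out.update(self.diagnostics)
        return out


def _shared_grid(config: ScenarioConfig) -> RadialGrid:
    g = config.geometry
    s = config.solver
    return build_grid(g.injection_radius, g.tumor_radius, g.outer_radius,
                      n_injection=s.n_injection, n_tumor=s.n_tumor,
                      n_normal=s.n_normal, grading=s.grading)


def run_scenario(config: ScenarioConfig,
                 _cache: dict | None = None) -> ScenarioResult:
    """Execute one full scenario; optional cache shares stage results."""
    started = _time.perf_counter()
    cache = _cache if _cache is not None else {}

    grid = cache.get("grid")
    if grid is None:
        grid = _shared_grid(config)
    flow = cache.get("flow")
    if flow is None:
        flow = solve_ifp(grid, config.flow)

    temperature: TemperatureHistory | None = None
    damage: ThermalDamageField | None = None
    transport: TransportResult | None = None
    diagnostics: dict = {}

    if config.mode in (TreatmentMode.MHT_ONLY, TreatmentMode.COMBINATION):
        cached_heat = cache.get("heating")
        if cached_heat is not None:
            temperature, damage = cached_heat
        else:
            temperature, damage = run_heating_stage(config, grid)
        # steady-state energy audit: source power vs perfusion + boundary
        # losses on the steady solution the heated field converges toward
        mats = material_fields(grid, config.thermal, config.magnetic,
                               config.geometry.injection_radius)
        source = mnp_source_field(grid, mats, config.magnetic, config.field)
        t_steady = _bioheat.solve_steady(grid, mats, source)
        diagnostics["energy_audit"] = steady_energy_audit(
            grid, mats, source, t_steady)
        diagnostics["steady_temperature"] = {
            "center": float(t_steady[0]),
            "injection_border": float(t_steady[int(np.argmin(np.abs(
                grid.r - grid.boundaries["injection"][1])))]),
            "tumor_border": float(t_steady[int(np.argmin(np.abs(
                grid.r - grid.boundaries["tumor"][1])))]),
        }

    if config.mode is TreatmentMode.CHEMO:
        transport = run_transport(grid, flow, config.drug, config.schedule,
                                  config.solver, mode="chemo")
    elif config.mode is TreatmentMode.COMBINATION:
        transport = run_transport(grid, flow, config.drug, config.schedule,
                                  config.solver, mode="tsl",
                                  temperature_history=temperature)

    survival_heat = damage.survival if damage is not None else np.ones(grid.n)
    ci = transport.state.ci if transport is not None else np.zeros(grid.n)
    efficacy = combine_kill(survival_heat, ci,
                            config.drug.survival_constant, grid)
    diagnostics["runtime_s"] = _time.perf_counter() - started
    return ScenarioResult(config=config, grid=grid, flow=flow,
                          temperature=temperature, damage=damage,
                          transport=transport, efficacy=efficacy,
                          diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

SWEEP_AXES = ("delay", "dose", "pore_size", "field_amplitude")


def _sweep_config(base: ScenarioConfig, axis: str, value: float) -> ScenarioConfig:
    if axis == "delay":
        # keep the post-exposure observation window fixed as the delay moves
        post_window = base.schedule.horizon - base.schedule.delay
        return apply_overrides(base, {
            "schedule.delay": value,
            "schedule.horizon": value + post_window,
        })
    if axis == "dose":
        return apply_overrides(base, {"drug.initial_plasma_dose": value})
    if axis == "pore_size":
        return apply_overrides(base, {"drug.vessel_pore_diameter": value})
    if axis == "field_amplitude":
        return apply_overrides(base, {"field.amplitude": value})
    raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")


def run_sweep(base: ScenarioConfig, axis: str, values) -> list[dict]:
    """One scenario run per value, sharing stages the axis cannot affect.

    Returns one summary dict per value; a failing run is recorded with its
    error and the sweep continues.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")
    cache: dict = {}
    cache["grid"] = _shared_grid(base)
    cache["flow"] = solve_ifp(cache["grid"], base.flow)
    if axis != "field_amplitude" and base.mode is not TreatmentMode.CHEMO:
        cache["heating"] = run_heating_stage(base, cache["grid"])

    rows: list[dict] = []
    for value in values:
        row = {"axis": axis, "value": float(value)}
        try:
            cfg = _sweep_config(base, axis, float(value))
            result = run_scenario(cfg, _cache=cache)
            row.update(result.summary())
        except Exception as exc:  # record and continue
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def list_presets() -> list[str]:
    root = importlib.resources.files("thermolipo") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ScenarioConfig:
    root = importlib.resources.files("thermolipo") / "presets"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None
    return load_scenario(text)
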