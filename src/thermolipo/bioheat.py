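"""Transient Pennes bioheat solver with MNP source and Arrhenius damage.

The temperature equation per tissue region,

    rho C dT/dt = div(k grad T) + rho_b C_b omega_b (Tb - T) + Qm + alpha Q_MNP,

is discretized with the conservative finite-volume scheme of
:mod:`thermolipo.grid` (harmonic-mean face conductivity, zero flux at r = 0,
Dirichlet body temperature at the outer boundary) and integrated with
backward Euler at a fixed step, perfusion treated implicitly.  Thermal
properties are temperature independent and perfusion is not temperature
modulated.

Cell kill by heat follows first-order Arrhenius kinetics: the survival
fraction DS = exp(-Omega) with Omega = integral of A exp(-dE/(R T(t))) dt,
accumulated per node with the trapezoidal rule; the fraction of killed
cells by heat alone is 1 - DS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .grid import RadialGrid, region_mask, volume_average
from .magnetics import volumetric_power
from .params import (
    CELSIUS_OFFSET,
    T_BODY_C,
    ArrheniusParams,
    FieldSpec,
    MagneticSpec,
    ScenarioConfig,
    ThermalConfig,
)


class SolverDivergence(RuntimeError):
    pass


@dataclass
class MaterialFields:
    """Per-node bioheat coefficients, with MNP loading folded in."""

    heat_capacity: np.ndarray  # rho C, J/(m^3 K)
    conductivity: np.ndarray  # W/(m K)
    perfusion_coeff: np.ndarray  # rho_b C_b omega_b, W/(m^3 K)
    metabolic: np.ndarray  # W/m^3
    source_scale: np.ndarray  # alpha * local MNP fill fraction
    mnp_volume_fraction: float  # phi in the deposition zone


def material_fields(grid: RadialGrid, thermal: ThermalConfig,
                    magnetic: MagneticSpec,
                    injection_radius: float) -> MaterialFields:
    """Blend tissue and MNP material properties over the deposition zone.

    The injected ferrofluid dose (nominal volume fraction over the injection
    sphere) is conserved when it spreads to ``thermal.mnp_deposition_radius``:
    the in-zone volume fraction is scaled by the cube of the radius ratio.
    Conductivity mixing is arithmetic (parallel bound; aggregated deposits)
    or Maxwell-Garnett (isolated-sphere dilute limit).
    """
    tumor_mask = grid.r <= grid.boundaries["tumor"][1]
    rho_c = np.where(tumor_mask,
                     thermal.tumor.volumetric_heat_capacity,
                     thermal.normal.volumetric_heat_capacity)
    k = np.where(tumor_mask,
                 thermal.tumor.thermal_conductivity,
                 thermal.normal.thermal_conductivity)
    perf = np.where(tumor_mask,
                    thermal.tumor.perfusion_heat_coefficient,
                    thermal.normal.perfusion_heat_coefficient)
    qm = np.where(tumor_mask,
                  thermal.tumor.metabolic_heat,
                  thermal.normal.metabolic_heat)

    a_dep = thermal.mnp_deposition_radius
    phi = magnetic.volume_fraction
    if thermal.conserve_mnp_dose:
        phi = phi * (injection_radius / a_dep) ** 3
    fill = region_mask(grid, 0.0, a_dep)  # CV overlap fraction with the zone

    # volumetric heat capacity mixes linearly in the local MNP fraction
    phi_local = phi * fill
    rho_c_mnp = magnetic.particle_density * magnetic.particle_specific_heat
    rho_c = (1.0 - phi_local) * rho_c + phi_local * rho_c_mnp

    kp = magnetic.particle_conductivity
    if thermal.conductivity_mixing == "arithmetic":
        k = (1.0 - phi_local) * k + phi_local * kp
    else:  # maxwell_garnett
        num = kp + 2 * k + 2 * phi_local * (kp - k)
        den = kp + 2 * k - phi_local * (kp - k)
        k = k * num / den

    alpha = np.where(tumor_mask, thermal.tumor.mnp_source_scale,
                     thermal.normal.mnp_source_scale)
    return MaterialFields(heat_capacity=rho_c, conductivity=k,
                          perfusion_coeff=perf, metabolic=qm,
                          source_scale=alpha * fill,
                          mnp_volume_fraction=phi)


@dataclass
class TemperatureHistory:
    grid: RadialGrid
    times: np.ndarray  # s, relative to AMF switch-on
    temperatures: np.ndarray  # (nt, n) deg C
    probes: dict  # name -> series (deg C)

    def at(self, t: float) -> np.ndarray:
        """Temperature field at time t (clamped, linear interpolation)."""
        t = float(np.clip(t, self.times[0], self.times[-1]))
        idx = np.searchsorted(self.times, t)
        if idx == 0:
            return self.temperatures[0]
        t0, t1 = self.times[idx - 1], self.times[idx]
        w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        return (1 - w) * self.temperatures[idx - 1] + w * self.temperatures[idx]


@dataclass
class ThermalDamageField:
    grid: RadialGrid
    survival: np.ndarray  # DS per node, in (0, 1]
    omega: np.ndarray  # damage integral, -ln DS

    @property
    def fkc_heat(self) -> np.ndarray:
        return 1.0 - self.survival


def _assemble_diffusion(grid: RadialGrid, k: np.ndarray):
    """Face conductances G_{i+1/2} = k_face A_face / dr (harmonic mean k)."""
    dr = np.diff(grid.r)
    k_face = 2.0 * k[:-1] * k[1:] / (k[:-1] + k[1:])
    areas = grid.face_areas[1:-1]
    return k_face * areas / dr  # length n-1


def _banded_solve(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray,
                  rhs: np.ndarray) -> np.ndarray:
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = diag
    ab[2, :-1] = lower
    return solve_banded((1, 1), ab, rhs)


def mnp_source_field(grid: RadialGrid, mats: MaterialFields,
                     magnetic: MagneticSpec, field: FieldSpec,
                     Ts_celsius: float = T_BODY_C) -> np.ndarray:
    """alpha * Q_MNP per node (W/m^3), evaluated at suspension temperature Ts.

    The linear-response power is evaluated at a fixed reference temperature
    (body temperature by default), which keeps the heating stage linear and
    bit-reproducible; the relaxation times' mild temperature dependence over
    the hyperthermic range is a second-order effect.
    """
    q = volumetric_power(magnetic, field, Ts_celsius + CELSIUS_OFFSET,
                         volume_fraction=mats.mnp_volume_fraction)
    return mats.source_scale * q


def solve_bioheat(grid: RadialGrid, mats: MaterialFields, source: np.ndarray,
                  on_duration: float, dt: float,
                  t_body: float = T_BODY_C,
                  cooldown_stop: float = 37.5,
                  max_cooldown: float = 4 * 3600.0,
                  store_every: int = 1) -> TemperatureHistory:
    """Integrate the bioheat equation through heating and cool-down.

    ``source`` (W/m^3) acts for ``on_duration`` seconds, then switches off;
    integration continues until the peak temperature falls below
    ``cooldown_stop`` (or ``max_cooldown`` elapses).  The outer boundary is
    held at ``t_body``; r = 0 is a symmetry (zero-flux) node.
    """
    n = grid.n
    vol = grid.volumes
    cond = _assemble_diffusion(grid, mats.conductivity)

    def step_matrix(with_source: bool):
        diag = vol * mats.heat_capacity / dt + vol * mats.perfusion_coeff
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        diag[:-1] += cond
        diag[1:] += cond
        lower[:] = -cond
        upper[:] = -cond
        # Dirichlet at the outer node
        diag[-1] = 1.0
        lower[-1] = 0.0
        base = vol * (mats.perfusion_coeff * t_body + mats.metabolic)
        if with_source:
            base = base + vol * source
        return lower, diag, upper, base

    T = np.full(n, t_body)
    records = [T.copy()]
    times = [0.0]
    probes: dict[str, list[float]] = {}

    phases = [(True, on_duration), (False, max_cooldown)]
    t = 0.0
    step_count = 0
    for with_source, duration in phases:
        lower, diag, upper, base = step_matrix(with_source)
        n_steps = int(round(duration / dt))
        for _ in range(n_steps):
            rhs = vol * mats.heat_capacity / dt * T + base
            rhs[-1] = t_body
            T = _banded_solve(lower, diag, upper, rhs)
            if not np.all(np.isfinite(T)):
                raise SolverDivergence(
                    "bioheat solver produced non-finite temperatures "
                    f"(dt = {dt} s, {n} nodes)")
            t += dt
            step_count += 1
            if step_count % store_every == 0:
                records.append(T.copy())
                times.append(t)
            if not with_source and T.max() < cooldown_stop:
                break
        if times[-1] != t:
            records.append(T.copy())
            times.append(t)

    temperatures = np.asarray(records)
    times_arr = np.asarray(times)
    probe_idx = {
        "center": 0,
        "injection_border": int(np.argmin(np.abs(
            grid.r - grid.boundaries["injection"][1]))),
        "tumor_border": int(np.argmin(np.abs(
            grid.r - grid.boundaries["tumor"][1]))),
    }
    probes = {name: temperatures[:, idx] for name, idx in probe_idx.items()}
    return TemperatureHistory(grid=grid, times=times_arr,
                              temperatures=temperatures, probes=probes)


def solve_steady(grid: RadialGrid, mats: MaterialFields, source: np.ndarray,
                 t_body: float = T_BODY_C) -> np.ndarray:
    """Direct steady-state solution (no time stepping)."""
    n = grid.n
    vol = grid.volumes
    cond = _assemble_diffusion(grid, mats.conductivity)
    diag = vol * mats.perfusion_coeff
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    diag[:-1] += cond
    diag[1:] += cond
    lower[:] = -cond
    upper[:] = -cond
    diag[-1] = 1.0
    lower[-1] = 0.0
    rhs = vol * (mats.perfusion_coeff * t_body + mats.metabolic + source)
    rhs[-1] = t_body
    return _banded_solve(lower, diag, upper, rhs)


def steady_energy_audit(grid: RadialGrid, mats: MaterialFields,
                        source: np.ndarray, T: np.ndarray,
                        t_body: float = T_BODY_C) -> dict:
    """Energy bookkeeping at steady state.

    Integrated source power (MNP + metabolic) must equal perfusion sink plus
    conduction loss through the outer boundary.
    """
    vol = grid.volumes
    power_in = float(np.dot(vol, source + mats.metabolic))
    perfusion_sink = float(np.dot(vol, mats.perfusion_coeff * (T - t_body)))
    # discrete flux from the last interior node into the Dirichlet node,
    # using the same face conductance as the solver
    k_face = 2.0 * mats.conductivity[-2] * mats.conductivity[-1] / (
        mats.conductivity[-2] + mats.conductivity[-1])
    area = grid.face_areas[-2]
    boundary_loss = float(
        k_face * area * (T[-2] - T[-1]) / (grid.r[-1] - grid.r[-2]))
    residual = power_in - perfusion_sink - boundary_loss
    return {
        "power_in_w": power_in,
        "perfusion_sink_w": perfusion_sink,
        "boundary_loss_w": boundary_loss,
        "relative_residual": residual / power_in if power_in else 0.0,
    }


def arrhenius_rate(T_celsius: np.ndarray, params: ArrheniusParams) -> np.ndarray:
    """Instantaneous damage rate A exp(-dE/(R T)) at temperature T (deg C)."""
    T_kelvin = np.asarray(T_celsius, dtype=float) + CELSIUS_OFFSET
    log_rate = np.log(params.frequency_factor) \
        - params.activation_energy / (params.gas_constant * T_kelvin)
    return np.exp(log_rate)


def arrhenius_survival(history: TemperatureHistory,
                       params: ArrheniusParams) -> ThermalDamageField:
    """Accumulate the damage integral over the stored temperature history."""
    rates = arrhenius_rate(history.temperatures, params)
    omega = np.trapezoid(rates, history.times, axis=0)
    survival = np.exp(-omega)
    return ThermalDamageField(grid=history.grid, survival=survival, omega=omega)


def run_heating_stage(config: ScenarioConfig, grid: RadialGrid,
                      store_every: int = 5):
    """Bioheat + Arrhenius for one AMF exposure; returns (history, damage).

    Times in the returned history are relative to AMF switch-on.
    """
    mats = material_fields(grid, config.thermal, config.magnetic,
                           config.geometry.injection_radius)
    source = mnp_source_field(grid, mats, config.magnetic, config.field)
    history = solve_bioheat(
        grid, mats, source,
        on_duration=config.schedule.amf_duration,
        dt=config.solver.dt_thermal,
        cooldown_stop=config.solver.cooldown_stop_temperature,
        store_every=store_every)
    damage = arrhenius_survival(history, config.arrhenius)
    return history, damage


def fkc_heat_average(damage: ThermalDamageField,
                     region: str = "malignant") -> float:
    """Volume-averaged heat-kill fraction (whole tumor sphere by default)."""
    weights = damage.grid.region_weights(region)
    return float(np.dot(weights, damage.fkc_heat) / weights.sum())
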