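"""Temperature-coupled four-compartment drug transport.

Compartments on the radial grid (all mol/m^3 of tissue):

* ``CL`` - drug still encapsulated in thermosensitive liposomes (TSL-Dox),
  extravasating from plasma, advected and (weakly) diffusing, releasing its
  cargo at rate K_EL(T);
* ``CF`` - free doxorubicin in the interstitium, diffusing and advected,
  exchanging with cell-surface receptors;
* ``CB`` - receptor-bound doxorubicin;
* ``CI`` - internalized doxorubicin (terminal sink, monotone in time).

Transvascular exchange follows the Patlak form

    Phi_B = phi_B (1 - sigma_f) CpL + P S/V (CpL - C) Pe / (e^Pe - 1),
    Pe = phi_B (1 - sigma_f) / (P S/V),

with the plasma concentration decaying mono-exponentially after a bolus.
In conventional-chemotherapy mode the liposome compartment is absent and
free drug extravasates directly.  In TSL mode free drug has no
transvascular term: the carrier crosses the wall, the released drug stays
in the tissue.

Numerics: per time step an operator split of (1) implicit local
reaction/exchange (release, binding, internalization, transvascular
source) and (2) implicit upwind finite-volume diffusion-convection for the
mobile species, with zero concentration imposed at the outer tissue
boundary and flux/concentration continuity holding by construction at
interior interfaces.  Mass bookkeeping (influx, boundary outflux,
compartment totals) is accumulated every step and audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .bioheat import TemperatureHistory
from .flow import FlowSolution
from .grid import RadialGrid, region_mask
from .hindrance import tsl_wall_coefficients
from .params import DrugParams, ScheduleConfig, SolverConfig


class MassBalanceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# local closures
# ---------------------------------------------------------------------------

def release_rate(T, params: DrugParams):
    """Liposome release rate K_EL(T) in 1/s (scalar or array).

    Zero below the low threshold, a monotone ramp between the thresholds,
    and the calibrated 42 deg C plateau at and above the high threshold.
    """
    T = np.asarray(T, dtype=float)
    lo, hi = params.release_threshold_low, params.release_threshold_high
    s = np.clip((T - lo) / (hi - lo), 0.0, 1.0)
    if params.release_ramp == "exponential":
        gamma = 3.0
        s = np.expm1(gamma * s) / np.expm1(gamma)
    out = params.release_rate_at_42 * s
    return float(out) if out.ndim == 0 else out


def plasma_concentration(t, params: DrugParams, mode: str = "tsl"):
    """CpL(t) = Cp0 exp(-t / kd) after a bolus at t = 0."""
    kd = params.plasma_decay if mode == "tsl" else params.plasma_decay_free
    return params.initial_plasma_dose * np.exp(-np.asarray(t, dtype=float) / kd)


def patlak_factor(pe):
    """Pe / (e^Pe - 1), continuous through Pe = 0."""
    pe = np.asarray(pe, dtype=float)
    small = np.abs(pe) < 1e-8
    safe = np.where(small, 1.0, pe)
    out = np.where(small, 1.0 - pe / 2.0, safe / np.expm1(safe))
    return float(out) if out.ndim == 0 else out


def transmural_source(cpl, c, phi_b, permeability, sigma_f, sv):
    """Patlak transvascular solute source Phi_B (mol/(m^3 s)).

    Lymphatic drainage is zero (no functional lymphatics in the tumor).
    Arguments may be scalars or per-node arrays.
    """
    conv = np.asarray(phi_b, dtype=float) * (1.0 - np.asarray(sigma_f))
    psv = np.asarray(permeability, dtype=float) * sv
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = np.where(psv > 0, conv / np.where(psv > 0, psv, 1.0), np.inf)
    diff = np.where(psv > 0,
                    psv * (cpl - np.asarray(c)) * patlak_factor(np.where(np.isfinite(pe), pe, 0.0)),
                    0.0)
    # pure-convective branch: the diffusive term vanishes as Pe -> inf
    diff = np.where(np.isfinite(pe), diff, 0.0)
    out = conv * cpl + diff
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# coefficient bundle
# ---------------------------------------------------------------------------

@dataclass
class TransportCoefficients:
    """Per-node wall/kinetic coefficients for one treatment mode."""

    grid: RadialGrid
    drug: DrugParams
    mode: str  # 'tsl' | 'chemo'
    phi_b: np.ndarray  # Starling fluid source, 1/s
    sv: float  # vessel area density, 1/m
    perm_l: np.ndarray  # TSL wall permeability per node, m/s
    sigma_l: np.ndarray  # TSL filtration reflection per node
    perm_f: np.ndarray  # free-drug wall permeability per node, m/s
    sigma_f: np.ndarray  # free-drug filtration reflection per node
    kon: float  # (1/phi) K_ON C_rec, 1/s
    koff: float  # (1/phi) K_OFF, 1/s
    kint: float  # 1/s


def build_coefficients(grid: RadialGrid, flow: FlowSolution, drug: DrugParams,
                       mode: str, sv: float) -> TransportCoefficients:
    tumor_frac = region_mask(grid, 0.0, grid.boundaries["tumor"][1])
    p_tum, s_tum = tsl_wall_coefficients(drug)
    p_nor, s_nor = tsl_wall_coefficients(drug, normal_tissue=True)
    perm_l = p_tum * tumor_frac + p_nor * (1.0 - tumor_frac)
    sigma_l = s_tum * tumor_frac + s_nor * (1.0 - tumor_frac)
    if mode == "chemo":
        # small molecule crosses tumor and normal walls alike (systemic
        # exposure is precisely chemotherapy's side-effect route)
        perm_f = np.full(grid.n, drug.vessel_permeability_free)
        sigma_f = np.full(grid.n, drug.filtration_reflection_free)
    else:
        # released drug has no transvascular pathway at all in the TSL
        # formulation: the carrier crossed the wall, the cargo stays put
        perm_f = np.zeros(grid.n)
        sigma_f = np.ones(grid.n)
    # the outer node is the far-field Dirichlet sink; it carries no
    # transvascular exchange of its own
    perm_l = perm_l.copy()
    perm_f = perm_f.copy()
    perm_l[-1] = 0.0
    perm_f[-1] = 0.0
    phi = drug.accessible_fraction
    phi_b = flow.starling_source.copy()
    phi_b[-1] = 0.0
    return TransportCoefficients(
        grid=grid, drug=drug, mode=mode, phi_b=phi_b,
        sv=sv, perm_l=perm_l, sigma_l=sigma_l, perm_f=perm_f, sigma_f=sigma_f,
        kon=drug.binding_on * drug.receptor_concentration / phi,
        koff=drug.binding_off / phi, kint=drug.internalization)


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class DrugState:
    grid: RadialGrid
    cl: np.ndarray
    cf: np.ndarray
    cb: np.ndarray
    ci: np.ndarray
    time: float = 0.0
    influx: float = 0.0  # cumulative transvascular moles in
    outflux: float = 0.0  # cumulative moles out through the outer boundary

    @classmethod
    def zeros(cls, grid: RadialGrid) -> "DrugState":
        z = lambda: np.zeros(grid.n)
        return cls(grid=grid, cl=z(), cf=z(), cb=z(), ci=z())

    def total_moles(self) -> float:
        vol = self.grid.volumes
        return float(np.dot(vol, self.cl + self.cf + self.cb + self.ci))

    def mass_audit(self) -> dict:
        net = self.influx - self.outflux
        total = self.total_moles()
        scale = max(abs(self.influx), abs(total), 1e-300)
        return {
            "total_moles": total,
            "influx_moles": self.influx,
            "outflux_moles": self.outflux,
            "relative_drift": (total - net) / scale,
        }


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

class _ImplicitAdvectionDiffusion:
    """Prefactored backward-Euler step for one mobile species.

    Conservative FV fluxes: harmonic-mean diffusive conductance plus
    first-order upwind convection on the frozen Darcy velocity field.
    Outer boundary: Dirichlet zero concentration.
    """

    def __init__(self, grid: RadialGrid, diffusivity: float,
                 face_velocity: np.ndarray, dt: float):
        n = grid.n
        self.grid = grid
        self.dt = dt
        dr = np.diff(grid.r)
        areas = grid.face_areas[1:-1]
        d_cond = diffusivity * areas / dr  # interior face conductances
        u = face_velocity[1:-1]
        up = np.maximum(u, 0.0) * areas  # upwind from node i
        dn = np.minimum(u, 0.0) * areas  # upwind from node i+1

        vol = grid.volumes
        diag = vol / dt
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        diag[:-1] += d_cond + up
        diag[1:] += d_cond - dn
        lower[:] = -(d_cond + up)
        upper[:] = -(d_cond - dn)
        # Dirichlet C = 0 at the outer node; the flux that the last interior
        # node sends into it is the moles leaving the domain
        diag[-1] = 1.0
        lower[-1] = 0.0
        self._edge_out = d_cond[-1] + up[-1]

        ab = np.zeros((3, n))
        ab[0, 1:] = upper
        ab[1] = diag
        ab[2, :-1] = lower
        self._ab = ab
        self._vol_over_dt = vol / dt

    def step(self, c: np.ndarray) -> tuple[np.ndarray, float]:
        """Advance one step; returns (new field, moles leaving the boundary)."""
        rhs = self._vol_over_dt * c
        rhs[-1] = 0.0
        new = solve_banded((1, 1), self._ab, rhs)
        out = self._edge_out * new[-2] * self.dt
        return new, out


def reaction_step(state: DrugState, coeffs: TransportCoefficients,
                  kel: np.ndarray, cpl: float, dt: float) -> None:
    """One implicit local step of release + exchange + binding kinetics.

    The local system is linear and lower-triangular in blocks
    (CL) -> (CF, CB) -> (CI), so backward Euler reduces to a scalar solve,
    a 2x2 solve and an update, all vectorized over nodes.  Mutates ``state``
    in place and accrues the transvascular influx.
    """
    grid = state.grid
    vol = grid.volumes
    kon, koff, kint = coeffs.kon, coeffs.koff, coeffs.kint

    influx = 0.0
    if coeffs.mode == "tsl":
        # CL: implicit in the linear (CpL - CL) exchange and release sink
        conv = coeffs.phi_b * (1.0 - coeffs.sigma_l)
        psv = coeffs.perm_l * coeffs.sv
        pe = np.divide(conv, psv, out=np.zeros_like(conv), where=psv > 0)
        pf = patlak_factor(pe)
        loss = psv * pf  # coefficient of -CL in Phi_B
        gain = (conv + psv * pf) * cpl
        cl_new = (state.cl + dt * gain) / (1.0 + dt * (kel + loss))
        influx += float(np.dot(vol, gain - loss * cl_new)) * dt
        released = kel * cl_new  # mol/(m^3 s), feeds CF
        state.cl = cl_new
    else:
        released = np.zeros(grid.n)

    # free-drug transvascular exchange (chemo mode only)
    conv_f = coeffs.phi_b * (1.0 - coeffs.sigma_f)
    psv_f = coeffs.perm_f * coeffs.sv
    pe_f = np.divide(conv_f, psv_f, out=np.zeros_like(conv_f), where=psv_f > 0)
    pf_f = patlak_factor(pe_f)
    loss_f = psv_f * pf_f
    gain_f = (conv_f + psv_f * pf_f) * cpl

    # implicit 2x2 for (CF, CB):
    #   (1 + dt (kon + loss_f)) CF - dt koff CB = CF_n + dt (rel + gain_f)
    #   -dt kon CF + (1 + dt (koff + kint)) CB = CB_n
    a11 = 1.0 + dt * (kon + loss_f)
    a12 = -dt * koff
    a21 = -dt * kon
    a22 = 1.0 + dt * (koff + kint)
    b1 = state.cf + dt * (released + gain_f)
    b2 = state.cb
    det = a11 * a22 - a12 * a21
    cf_new = (b1 * a22 - a12 * b2) / det
    cb_new = (a11 * b2 - a21 * b1) / det
    influx += float(np.dot(vol, gain_f - loss_f * cf_new)) * dt

    state.ci = state.ci + dt * kint * cb_new
    state.cf = cf_new
    state.cb = cb_new
    state.influx += influx


# ---------------------------------------------------------------------------
# trajectory driver
# ---------------------------------------------------------------------------

@dataclass
class TransportResult:
    grid: RadialGrid
    times: np.ndarray  # checkpoint times, s
    mean_cl: np.ndarray  # volume averages over the whole tumor sphere
    mean_cf: np.ndarray
    mean_cb: np.ndarray
    mean_ci: np.ndarray
    mean_fkc_drug: np.ndarray  # volume average of the local drug kill
    state: DrugState  # final state
    snapshots: dict = field(default_factory=dict)  # time -> dict of fields
    audits: list = field(default_factory=list)

    @property
    def peak_ci(self) -> float:
        return float(self.mean_ci.max())

    def peak(self, series: str) -> tuple[float, float]:
        values = getattr(self, f"mean_{series}")
        idx = int(np.argmax(values))
        return float(self.times[idx]), float(values[idx])


def run_transport(grid: RadialGrid, flow: FlowSolution, drug: DrugParams,
                  schedule: ScheduleConfig, solver: SolverConfig,
                  mode: str = "tsl",
                  temperature_history: TemperatureHistory | None = None,
                  sv: float | None = None,
                  snapshot_times: tuple = (),
                  audit: bool = True) -> TransportResult:
    """Integrate the transport system from bolus injection to the horizon.

    ``temperature_history`` holds the heating stage with times relative to
    AMF switch-on (the scenario delay offsets it); outside that window the
    tissue sits at body temperature and the release rate is zero.
    """
    if mode not in ("tsl", "chemo"):
        raise ValueError(f"unknown transport mode {mode!r}")
    if sv is None:
        sv = flow.vessel_area_density
    coeffs = build_coefficients(grid, flow, drug, mode, sv)

    state = DrugState.zeros(grid)
    kel_zero = np.zeros(grid.n)

    # heated window in absolute scenario time
    if temperature_history is not None and mode == "tsl":
        t_on = schedule.delay
        t_off = schedule.delay + float(temperature_history.times[-1])
    else:
        t_on = t_off = -1.0  # never

    op_cache: dict[tuple[str, float], _ImplicitAdvectionDiffusion] = {}

    def mobile_op(species: str, dt: float) -> _ImplicitAdvectionDiffusion:
        key = (species, dt)
        if key not in op_cache:
            diff = (drug.tsl_diffusivity if species == "cl"
                    else drug.free_drug_diffusivity)
            op_cache[key] = _ImplicitAdvectionDiffusion(
                grid, diff, flow.face_velocity, dt)
        return op_cache[key]

    times = [0.0]
    weights = grid.region_weights("malignant")
    wsum = weights.sum()
    omega = drug.survival_constant

    def averages():
        means = tuple(float(np.dot(weights, f) / wsum)
                      for f in (state.cl, state.cf, state.cb, state.ci))
        fkc = float(np.dot(weights, -np.expm1(-omega * state.ci)) / wsum)
        return means + (fkc,)

    series = [averages()]
    snapshots: dict[float, dict] = {}
    audits: list[dict] = []
    snap_queue = sorted(snapshot_times)

    t = 0.0
    next_checkpoint = solver.checkpoint_interval
    horizon = schedule.horizon
    while t < horizon - 1e-9:
        in_window = t_on - 1e-9 <= t < t_off
        dt = solver.dt_transport_mht if in_window else solver.dt_transport
        # do not step across window edges or the horizon
        for edge in (t_on, t_off, horizon):
            if t < edge - 1e-9:
                dt = min(dt, edge - t)
        if in_window:
            T_field = temperature_history.at(t + 0.5 * dt - t_on)
            kel = release_rate(T_field, drug)
        else:
            kel = kel_zero

        reaction_step(state, coeffs, kel,
                      float(plasma_concentration(t + dt, drug, mode)), dt)
        if mode == "tsl":
            state.cl, out_l = mobile_op("cl", dt).step(state.cl)
            state.outflux += out_l
        state.cf, out_f = mobile_op("cf", dt).step(state.cf)
        state.outflux += out_f
        t += dt
        state.time = t

        if np.any(state.cf < -1e-9) or np.any(state.cl < -1e-9):
            raise MassBalanceError(
                f"negative concentration beyond tolerance at t = {t:.1f} s")

        if t >= next_checkpoint - 1e-9 or t >= horizon - 1e-9:
            times.append(t)
            series.append(averages())
            if audit:
                report = state.mass_audit()
                report["time_s"] = t
                audits.append(report)
                if abs(report["relative_drift"]) > solver.mass_balance_tolerance:
                    raise MassBalanceError(
                        f"drug mass balance drift {report['relative_drift']:.2e} "
                        f"exceeds tolerance at t = {t:.0f} s")
            while next_checkpoint <= t + 1e-9:
                next_checkpoint += solver.checkpoint_interval
        while snap_queue and t >= snap_queue[0] - 1e-9:
            snapshots[snap_queue.pop(0)] = {
                "cl": state.cl.copy(), "cf": state.cf.copy(),
                "cb": state.cb.copy(), "ci": state.ci.copy()}

    arr = np.asarray(series)
    return TransportResult(
        grid=grid, times=np.asarray(times), mean_cl=arr[:, 0],
        mean_cf=arr[:, 1], mean_cb=arr[:, 2], mean_ci=arr[:, 3],
        mean_fkc_drug=arr[:, 4], state=state, snapshots=snapshots,
        audits=audits)
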