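"""Steady Darcy interstitial fluid mechanics with Starling transvascular source.

Pressure obeys -kappa laplacian(p) = phi_B - phi_L with the Starling
filtration rate phi_B = Lp (S/V) (p_e - p), p_e = P_b - sigma_s (pi_B - pi_i)
being the effective filtration head.  Inside the tumor there is no functional
lymphatic drainage (phi_L = 0); normal tissue defaults to a net-zero fluid
source (lymphatics balancing filtration), which reproduces the classic
picture of a high central IFP plateau falling to near zero just outside the
tumor margin.  The interstitial fluid velocity follows Darcy's law
u = -kappa grad p, and the flow field is solved once and frozen for the
transport problem (temperature does not feed back on flow).

For a homogeneous sphere with Starling source everywhere the problem has the
closed-form solution p(r) = p_e [1 - (R/r) sinh(alpha r / R) / sinh(alpha)],
alpha = R sqrt(Lp (S/V) / kappa), which serves as the solver's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RadialGrid, region_mask
from .params import FlowParams
from .units import MMHG_PER_PA


class SingularFlowSystem(RuntimeError):
    pass


@dataclass
class FlowSolution:
    grid: RadialGrid
    pressure: np.ndarray  # Pa, per node
    velocity: np.ndarray  # m/s, radial component per node
    face_velocity: np.ndarray  # m/s at control-volume faces (length n+1)
    starling_source: np.ndarray  # transvascular filtration phi_B per node, 1/s
    net_fluid_source: np.ndarray  # phi_B - phi_L per node, 1/s
    effective_pressure: float  # p_e, Pa
    vessel_area_density: float = 2.0e4  # S/V carried along for transport, 1/m

    @property
    def pressure_mmhg(self) -> np.ndarray:
        return self.pressure * MMHG_PER_PA

    def mass_balance(self) -> dict:
        """Global audit: net volumetric source must equal boundary outflux.

        The residual is reported relative to the gross filtration rate (the
        physically meaningful scale: with lymphatic drainage the *net*
        source is a difference of near-cancelling terms).
        """
        source = float(np.dot(self.grid.volumes, self.net_fluid_source))
        outflux = float(self.face_velocity[-1] * self.grid.face_areas[-1])
        gross = float(np.dot(self.grid.volumes,
                             np.abs(self.starling_source)))
        scale = max(gross, abs(source), abs(outflux), 1e-300)
        return {
            "source_m3_per_s": source,
            "boundary_outflux_m3_per_s": outflux,
            "gross_filtration_m3_per_s": gross,
            "relative_residual": (source - outflux) / scale,
        }


def _tridiag_solve(lower, diag, upper, rhs):
    from scipy.linalg import solve_banded

    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1] = diag
    ab[2, :-1] = lower
    return solve_banded((1, 1), ab, rhs)


def solve_ifp(grid: RadialGrid, flow: FlowParams,
              tumor_radius: float | None = None) -> FlowSolution:
    """Solve the steady IFP problem on the nested grid.

    ``tumor_radius`` bounds the Starling-source region; it defaults to the
    grid's tumor boundary.  With ``flow.normal_tissue_source == 'starling'``
    the source acts over the whole domain instead.
    """
    if flow.interstitium_hydraulic_conductivity <= 0:
        raise SingularFlowSystem("interstitial hydraulic conductivity must be > 0")
    n = grid.n
    vol = grid.volumes
    kappa = flow.interstitium_hydraulic_conductivity
    if tumor_radius is None:
        tumor_radius = grid.boundaries["tumor"][1]

    dr = np.diff(grid.r)
    cond = kappa * grid.face_areas[1:-1] / dr  # face conductances

    lp_sv = flow.vessel_hydraulic_conductivity * flow.vessel_area_density
    pe = flow.effective_pressure
    tumor_frac = region_mask(grid, 0.0, tumor_radius)

    # -div(kappa grad p) = s (p_target - p): Starling filtration toward p_e
    # inside the tumor; in normal tissue, per the configured closure, either
    # lymphatic-dominated drainage toward zero, nothing, or full Starling
    if flow.normal_tissue_source == "starling":
        sink_coeff = np.full(n, lp_sv)
        p_target = np.full(n, pe)
    elif flow.normal_tissue_source == "lymphatic_sink":
        sink_coeff = np.full(n, lp_sv)
        p_target = pe * tumor_frac
    else:  # net_zero
        sink_coeff = lp_sv * tumor_frac
        p_target = np.full(n, pe)
    sink = vol * sink_coeff

    diag = sink.copy()
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    diag[:-1] += cond
    diag[1:] += cond
    lower[:] = -cond
    upper[:] = -cond
    rhs = sink * p_target
    # Dirichlet p = 0 at the outer boundary
    diag[-1] = 1.0
    lower[-1] = 0.0
    rhs[-1] = 0.0

    if lp_sv == 0.0 or not np.any(sink_coeff > 0):
        pressure = np.zeros(n)
    else:
        pressure = _tridiag_solve(lower, diag, upper, rhs)
        if not np.all(np.isfinite(pressure)):
            raise SingularFlowSystem("IFP system produced non-finite pressures")

    face_velocity = np.zeros(n + 1)
    face_velocity[1:-1] = -kappa * np.diff(pressure) / dr
    # outer face: one-sided gradient consistent with the Dirichlet condition
    face_velocity[-1] = -kappa * (pressure[-1] - pressure[-2]) / dr[-1]
    velocity = np.zeros(n)
    velocity[1:-1] = 0.5 * (face_velocity[1:-2] + face_velocity[2:-1])
    velocity[-1] = face_velocity[-1]

    # transvascular filtration available to carry solute: tumor everywhere;
    # in normal tissue only when vessels there exchange fluid at all
    if flow.normal_tissue_source == "net_zero":
        phi_b = lp_sv * tumor_frac * (pe - pressure)
    else:
        phi_b = lp_sv * np.maximum(pe - pressure, 0.0)
    net = sink_coeff * (p_target - pressure)
    return FlowSolution(grid=grid, pressure=pressure, velocity=velocity,
                        face_velocity=face_velocity, starling_source=phi_b,
                        net_fluid_source=net, effective_pressure=pe,
                        vessel_area_density=flow.vessel_area_density)


def analytic_ifp_sphere(flow: FlowParams, radius: float,
                        r: np.ndarray) -> np.ndarray:
    """Closed-form IFP for a homogeneous source sphere with p(R) = 0 (Pa)."""
    lp_sv = flow.vessel_hydraulic_conductivity * flow.vessel_area_density
    kappa = flow.interstitium_hydraulic_conductivity
    pe = flow.effective_pressure
    alpha = radius * np.sqrt(lp_sv / kappa)
    r = np.asarray(r, dtype=float)
    if alpha == 0.0:
        return np.zeros_like(r)
    x = alpha * r / radius
    with np.errstate(invalid="ignore", divide="ignore"):
        shape = np.where(
            r > 0,
            (radius / np.where(r > 0, r, 1.0)) * np.sinh(x) / np.sinh(alpha),
            alpha / np.sinh(alpha))
    return pe * (1.0 - shape)
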