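"""Pennes bioheat solver and Arrhenius damage accumulation.

The steady conduction-perfusion problem with a uniform spherical source has
a screened-Poisson (modified Helmholtz) closed form, which serves as the
independent oracle for the finite-volume solver; constant-temperature
exposure gives the Arrhenius integral in closed form.
"""

import math

import numpy as np
import pytest

from thermolipo.bioheat import (
    MaterialFields,
    arrhenius_rate,
    arrhenius_survival,
    solve_bioheat,
    solve_steady,
    steady_energy_audit,
    TemperatureHistory,
)
from thermolipo.grid import build_grid, region_mask
from thermolipo.params import ArrheniusParams


def screened_poisson_sphere(r, q, lam, k, a, R):
    """Closed-form steady rise for a uniform source sphere, u(R) = 0.

    u_in = q/lam + A sinh(br)/r, u_out = B sinh(b(R-r))/r with b = sqrt(lam/k)
    and (A, B) fixed by continuity of value and flux at r = a.
    """
    beta = math.sqrt(lam / k)
    sh, ch = np.sinh, np.cosh
    M = np.array([
        [sh(beta * a) / a, -sh(beta * (R - a)) / a],
        [beta * ch(beta * a) / a - sh(beta * a) / a**2,
         beta * ch(beta * (R - a)) / a + sh(beta * (R - a)) / a**2],
    ])
    A, B = np.linalg.solve(M, [-q / lam, 0.0])
    safe_r = np.where(r > 0, r, 1.0)
    return np.where(
        r < a,
        q / lam + A * np.where(r > 0, sh(beta * r) / safe_r, beta),
        B * sh(beta * (R - r)) / safe_r)


def uniform_mats(grid, k=0.5, lam=3420.0):
    n = grid.n
    return MaterialFields(
        heat_capacity=np.full(n, 3.7e6), conductivity=np.full(n, k),
        perfusion_coeff=np.full(n, lam), metabolic=np.zeros(n),
        source_scale=np.zeros(n), mnp_volume_fraction=0.0)


Q, LAM, K = 5e5, 3420.0, 0.5
A_SRC, R_OUT = 0.25e-2, 3e-2


def _steady_error(n_tumor):
    g = build_grid(A_SRC, 1e-2, R_OUT, n_injection=max(20, n_tumor // 3),
                   n_tumor=n_tumor, n_normal=n_tumor, grading=1.0)
    mats = uniform_mats(g)
    src = Q * region_mask(g, 0.0, A_SRC)
    u = solve_steady(g, mats, src) - 37.0
    exact = screened_poisson_sphere(g.r, Q, LAM, K, A_SRC, R_OUT)
    return g, mats, src, np.max(np.abs(u - exact)) / exact.max()


def test_steady_state_matches_screened_poisson_oracle():
    _, _, _, err = _steady_error(120)
    assert err < 5e-3  # < 0.5 % everywhere on a fine grid


def test_grid_halving_convergence_is_second_order():
    errs = [_steady_error(n)[3] for n in (40, 80, 160)]
    orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
    for p in orders:
        assert 1.7 < p < 2.3


def test_steady_energy_audit_closes():
    g, mats, src, _ = _steady_error(120)
    T = solve_steady(g, mats, src)
    audit = steady_energy_audit(g, mats, src, T)
    assert abs(audit["relative_residual"]) < 1e-3
    assert audit["power_in_w"] > 0


def test_maximum_principle_without_source():
    g = build_grid(A_SRC, 1e-2, R_OUT, n_injection=10, n_tumor=50, n_normal=20)
    mats = uniform_mats(g)
    hist = solve_bioheat(g, mats, np.zeros(g.n), on_duration=360.0, dt=3.6,
                         max_cooldown=0.0)
    assert np.max(np.abs(hist.temperatures - 37.0)) < 1e-9


def test_transient_approaches_steady_state():
    g, mats, src, _ = _steady_error(60)
    steady = solve_steady(g, mats, src)
    hist = solve_bioheat(g, mats, src, on_duration=3600.0, dt=3.6,
                         max_cooldown=0.0)
    i_end = int(np.argmin(np.abs(hist.times - 3600.0)))
    assert hist.temperatures[i_end, 0] == pytest.approx(steady[0], abs=0.02)


def test_heating_plateau_reached_within_exposure(mht11_result):
    """Center temperature levels off well before the end of the 60 min AMF."""
    hist = mht11_result.temperature
    center = hist.probes["center"]
    i30 = int(np.argmin(np.abs(hist.times - 1800.0)))
    i60 = int(np.argmin(np.abs(hist.times - 3600.0)))
    rise_60 = center[i60] - 37.0
    assert center[i60] - center[i30] < 0.05 * rise_60
    # and the heated field decays back toward body temperature afterwards
    assert hist.temperatures[-1].max() < center[i60]


@pytest.mark.parametrize("t_c, hours, omega_expected, fkc_expected", [
    (37.0, 1.0, 3.270e-3, 0.003265),  # negligible kill at body temperature
    (43.0, 1.0, 0.44314, 0.35798),    # hyperthermic-range kill
])
def test_arrhenius_constant_temperature_closed_form(t_c, hours, omega_expected,
                                                    fkc_expected):
    params = ArrheniusParams()
    rate = params.frequency_factor * math.exp(
        -params.activation_energy / (params.gas_constant * (t_c + 273.15)))
    g = build_grid(A_SRC, 1e-2, R_OUT, n_injection=10, n_tumor=50, n_normal=10)
    times = np.linspace(0.0, hours * 3600.0, 200)
    hist = TemperatureHistory(
        grid=g, times=times,
        temperatures=np.full((len(times), g.n), t_c), probes={})
    dmg = arrhenius_survival(hist, params)
    assert dmg.omega[0] == pytest.approx(rate * hours * 3600.0, rel=1e-6)
    assert dmg.omega[0] == pytest.approx(omega_expected, rel=5e-3)
    assert (1.0 - dmg.survival[0]) == pytest.approx(fkc_expected, rel=5e-3)


def test_arrhenius_linear_in_exposure_time():
    params = ArrheniusParams()
    g = build_grid(A_SRC, 1e-2, R_OUT, n_injection=10, n_tumor=50, n_normal=10)

    def omega(hours):
        times = np.linspace(0.0, hours * 3600.0, 400)
        hist = TemperatureHistory(
            grid=g, times=times,
            temperatures=np.full((len(times), g.n), 43.0), probes={})
        return arrhenius_survival(hist, params).omega[0]

    assert omega(2.0) == pytest.approx(2 * omega(1.0), rel=1e-9)


def test_arrhenius_rate_monotone_in_temperature():
    params = ArrheniusParams()
    temps = np.linspace(37.0, 46.0, 50)
    rates = arrhenius_rate(temps, params)
    assert np.all(np.diff(rates) > 0)


def test_damage_survival_exponential_identity(mht13_result):
    dmg = mht13_result.damage
    assert np.allclose(dmg.survival, np.exp(-dmg.omega))
    assert np.all(dmg.survival > 0) and np.all(dmg.survival <= 1.0)
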