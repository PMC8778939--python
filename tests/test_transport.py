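"""Four-compartment drug transport: closures, kinetics oracle, conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import thermolipo as tl
from thermolipo.flow import solve_ifp
from thermolipo.grid import build_grid
from thermolipo.params import DrugParams, FlowParams, apply_overrides
from thermolipo.transport import (
    DrugState,
    build_coefficients,
    patlak_factor,
    plasma_concentration,
    reaction_step,
    release_rate,
    run_transport,
    transmural_source,
)

from conftest import COARSE


# ---------------------------------------------------------------------------
# release closure
# ---------------------------------------------------------------------------

def test_release_rate_plateau_and_threshold():
    drug = DrugParams()
    assert release_rate(42.0, drug) == pytest.approx(0.05409)
    assert release_rate(45.0, drug) == pytest.approx(0.05409)  # plateau
    assert release_rate(37.0, drug) == 0.0  # no release in normothermia
    assert release_rate(38.9, drug) == 0.0
    # linear ramp midpoint between the 39 / 42 thresholds
    assert release_rate(40.5, drug) == pytest.approx(0.05409 / 2)


def test_release_rate_monotone_and_ramp_variants():
    lin = DrugParams()
    expo = DrugParams(release_ramp="exponential")
    temps = np.linspace(36.0, 46.0, 200)
    for drug in (lin, expo):
        k = release_rate(temps, drug)
        assert np.all(np.diff(k) >= -1e-15)
        assert k[0] == 0.0 and k[-1] == pytest.approx(0.05409)
    # the exponential ramp lags the linear one in the transition band
    mid = release_rate(40.5, expo)
    assert 0.0 < mid < release_rate(40.5, lin)


def test_plasma_bolus_decay():
    drug = DrugParams()
    assert plasma_concentration(0.0, drug) == pytest.approx(1.0)
    t = drug.plasma_decay
    assert plasma_concentration(t, drug) == pytest.approx(np.exp(-1.0))


# ---------------------------------------------------------------------------
# transvascular exchange
# ---------------------------------------------------------------------------

def test_patlak_factor_limits():
    assert patlak_factor(0.0) == pytest.approx(1.0)
    assert patlak_factor(1e-12) == pytest.approx(1.0, abs=1e-9)
    # continuity across the small-Pe switch
    assert patlak_factor(1.0001e-8) == pytest.approx(patlak_factor(0.9999e-8),
                                                     rel=1e-6)
    assert patlak_factor(50.0) < 1e-12
    assert patlak_factor(1.0) == pytest.approx(1.0 / (np.e - 1.0), rel=1e-12)


def test_transmural_source_diffusive_limit():
    # phi_b = 0 -> Pe = 0 -> pure diffusion P S/V (CpL - C)
    psv = 3e-6 * 2e4
    got = transmural_source(cpl=1.0, c=0.25, phi_b=0.0, permeability=3e-6,
                            sigma_f=0.0, sv=2e4)
    assert got == pytest.approx(psv * 0.75, rel=1e-12)


def test_transmural_source_equilibrium():
    # CpL = C and sigma_f = 1: no driving force at all
    got = transmural_source(cpl=0.7, c=0.7, phi_b=1e-4, permeability=3e-6,
                            sigma_f=1.0, sv=2e4)
    assert got == pytest.approx(0.0, abs=1e-15)


def test_transmural_source_against_direct_arithmetic():
    # independent evaluation of the Patlak form with tabulated magnitudes
    phi_b, p, sigma, sv, cpl, c = 1.2e-4, 3e-6, 0.15, 2e4, 1.0, 0.0
    conv = phi_b * (1 - sigma)
    pe = conv / (p * sv)
    expected = conv * cpl + p * sv * (cpl - c) * pe / (np.exp(pe) - 1.0)
    got = transmural_source(cpl, c, phi_b, p, sigma, sv)
    assert got == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# reaction kinetics vs an independent stiff-ODE oracle
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def well_mixed_setup():
    g = build_grid(0.25e-2, 1e-2, 3e-2, n_injection=10, n_tumor=45,
                   n_normal=10)
    drug = DrugParams()
    flow = solve_ifp(g, FlowParams())
    coeffs = build_coefficients(g, flow, drug, "tsl", flow.vessel_area_density)
    i = 30  # tumor-interior node; make the whole grid share its coefficients
    for name in ("phi_b", "perm_l", "sigma_l", "perm_f", "sigma_f"):
        getattr(coeffs, name)[:] = getattr(coeffs, name)[i]
    return g, drug, coeffs, i


def test_well_mixed_reaction_matches_ode_oracle(well_mixed_setup):
    """Backward-Euler kinetics (Richardson extrapolated) vs Radau to 1e-6."""
    g, drug, coeffs, i = well_mixed_setup
    kel = 0.01
    kd, cp0 = drug.plasma_decay, drug.initial_plasma_dose
    conv = coeffs.phi_b[i] * (1 - coeffs.sigma_l[i])
    psv = coeffs.perm_l[i] * coeffs.sv
    pe = conv / psv
    pf = pe / np.expm1(pe) if pe > 1e-8 else 1.0
    loss_l, gain_coef = psv * pf, conv + psv * pf
    kon, koff, kint = coeffs.kon, coeffs.koff, coeffs.kint

    def rhs(t, y):
        cl, cf, cb, ci = y
        cpl = cp0 * np.exp(-t / kd)
        return [gain_coef * cpl - (kel + loss_l) * cl,
                kel * cl - kon * cf + koff * cb,
                kon * cf - (koff + kint) * cb,
                kint * cb]

    horizon = 1800.0
    oracle = solve_ivp(rhs, (0, horizon), [0.0] * 4, method="Radau",
                       rtol=1e-11, atol=1e-14).y[:, -1]

    def backward_euler(dt):
        st = DrugState.zeros(g)
        t = 0.0
        for _ in range(int(round(horizon / dt))):
            reaction_step(st, coeffs, np.full(g.n, kel),
                          float(cp0 * np.exp(-(t + dt) / kd)), dt)
            t += dt
        return np.array([st.cl[i], st.cf[i], st.cb[i], st.ci[i]])

    xh, xh2, xh4 = backward_euler(1.0), backward_euler(0.5), backward_euler(0.25)
    extrapolated = (4 * (2 * xh4 - xh2) - (2 * xh2 - xh)) / 3
    assert np.max(np.abs(extrapolated / oracle - 1.0)) < 1e-6
    # receptor-limited cap: bound pool below the kon/koff partition of the
    # running free-drug maximum
    assert oracle[2] <= coeffs.kon / coeffs.koff * np.max([xh[1], oracle[1]]) * 1.2


def test_reaction_step_identity_without_drivers(well_mixed_setup):
    g, drug, coeffs0, i = well_mixed_setup
    flow0 = solve_ifp(g, FlowParams(vessel_hydraulic_conductivity=0.0))
    quiet = build_coefficients(g, flow0, drug, "tsl", 2e4)
    quiet.perm_l[:] = 0.0
    st = DrugState.zeros(g)
    st.cl[:] = 0.7
    st.cf[:] = 0.0
    before = st.cl.copy()
    reaction_step(st, quiet, np.zeros(g.n), cpl=0.0, dt=100.0)
    assert np.array_equal(st.cl, before)
    assert np.all(st.cf == 0.0) and np.all(st.cb == 0.0) and np.all(st.ci == 0.0)
    assert st.influx == 0.0


# ---------------------------------------------------------------------------
# full trajectories
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def coarse_chemo_result():
    cfg = apply_overrides(tl.load_preset("chemo_baseline"), COARSE)
    return tl.run_scenario(cfg)


def test_zero_dose_keeps_all_compartments_zero():
    cfg = apply_overrides(tl.load_preset("chemo_baseline"), {
        **COARSE, "drug.initial_plasma_dose": 1e-300,
        "drug.allow_out_of_range": True, "schedule.horizon": 6 * 3600.0})
    res = tl.run_scenario(cfg)
    assert res.transport.mean_ci.max() < 1e-250
    assert res.efficacy.fkc_drug == pytest.approx(0.0, abs=1e-12)


def test_tsl_without_heating_releases_nothing():
    cfg = apply_overrides(tl.load_preset("combo_9h"), {
        **COARSE, "schedule.horizon": 12 * 3600.0})
    # run the transport stage directly with no temperature history
    g = build_grid(cfg.geometry.injection_radius, cfg.geometry.tumor_radius,
                   cfg.geometry.outer_radius, 15, 40, 25)
    flow = solve_ifp(g, cfg.flow)
    tr = run_transport(g, flow, cfg.drug, cfg.schedule, cfg.solver, mode="tsl",
                       temperature_history=None)
    assert tr.mean_cl.max() > 0.1  # liposomes do accumulate
    assert tr.mean_cf.max() == pytest.approx(0.0, abs=1e-15)
    assert tr.mean_ci.max() == pytest.approx(0.0, abs=1e-15)


def test_internalized_pool_is_monotone(combo_result):
    ci = combo_result.transport.mean_ci
    assert np.all(np.diff(ci) >= -1e-12)


def test_mass_audit_within_tolerance(combo_result, coarse_chemo_result):
    for res in (combo_result, coarse_chemo_result):
        drift = res.transport.state.mass_audit()["relative_drift"]
        assert abs(drift) < 5e-3


def test_all_concentrations_nonnegative(combo_result):
    st = combo_result.transport.state
    for f in (st.cl, st.cf, st.cb, st.ci):
        assert np.all(f >= -1e-12)


def test_chemo_bound_pool_follows_plasma_decay(coarse_chemo_result):
    """Bound drug rises with the bolus, then decays as plasma clears."""
    tr = coarse_chemo_result.transport
    cb = tr.mean_cb
    i_peak = int(np.argmax(cb))
    t_peak = tr.times[i_peak]
    assert t_peak < 4 * 3600.0  # early peak
    assert cb[-1] < 0.05 * cb[i_peak]  # washed out by 72 h
    # tail decay tracks the plasma time constant within a factor of two
    kd = coarse_chemo_result.config.drug.plasma_decay_free
    i1 = int(np.argmin(np.abs(tr.times - 6 * 3600)))
    i2 = int(np.argmin(np.abs(tr.times - 12 * 3600)))
    rate = np.log(cb[i1] / cb[i2]) / (tr.times[i2] - tr.times[i1])
    assert rate == pytest.approx(1.0 / kd, rel=0.5)


def test_liposome_pool_rises_peaks_and_clears(combo_result):
    """Tumor TSL concentration rises after the bolus, peaks before the AMF
    window closes, and is largely cleared by 72 h (release + washout)."""
    tr = combo_result.transport
    cl = tr.mean_cl
    i_peak = int(np.argmax(cl))
    assert 0 < i_peak < len(cl) - 1
    assert 3600.0 < tr.times[i_peak] < 9 * 3600.0
    assert cl[-1] < 0.15 * cl[i_peak]


def test_step_halving_consistency():
    """Halving both transport steps moves the terminal kill by < 1%."""
    base = apply_overrides(tl.load_preset("combo_9h"), {
        **COARSE, "schedule.horizon": 16 * 3600.0})
    fine = apply_overrides(base, {
        "solver.dt_transport": COARSE["solver.dt_transport"] / 2,
        "solver.dt_transport_mht": COARSE["solver.dt_transport_mht"] / 2})
    r1 = tl.run_scenario(base)
    r2 = tl.run_scenario(fine)
    assert r2.efficacy.mean_ci == pytest.approx(r1.efficacy.mean_ci, rel=0.01)
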