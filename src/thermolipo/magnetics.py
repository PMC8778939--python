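"""Linear-response-theory power deposition of superparamagnetic MNPs.

Single-domain iron-oxide particles under an alternating magnetic field
dissipate power through Neel (internal moment reversal) and Brown (physical
rotation) relaxation.  The volumetric power follows the standard
linear-response chain: equilibrium (chord Langevin) susceptibility, effective
relaxation time as the harmonic combination of the two mechanisms, and the
Debye out-of-phase factor 2*pi*f*tau / (1 + (2*pi*f*tau)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import KB, MU0, CELSIUS_OFFSET, FieldSpec, MagneticSpec


@dataclass(frozen=True)
class RelaxationTimes:
    brown: float  # s
    neel: float  # s
    effective: float  # s
    anisotropy_ratio: float  # Gamma = Keff V_H / (kB Ts)


def relaxation_times(spec: MagneticSpec, Ts: float = 310.15) -> RelaxationTimes:
    """Brown, Neel and effective relaxation times at suspension temperature Ts (K).

    tau_B = 3 delta V_H / (kB Ts); tau_N follows Rosensweig's
    (sqrt(pi)/2) tau0 exp(Gamma)/sqrt(Gamma) by default, or the literal
    pi tau0 exp(Gamma) / (2 Gamma) variant when ``spec.neel_form == 'literal'``;
    1/tau_eff = 1/tau_B + 1/tau_N.
    """
    if Ts <= 0:
        raise ValueError("suspension temperature must be positive (K)")
    vh = spec.hydrodynamic_volume
    if vh <= 0:
        raise ValueError("non-physical magnetic spec: zero hydrodynamic volume")
    kbt = KB * Ts
    tau_b = 3.0 * spec.suspension_viscosity * vh / kbt
    gamma = spec.anisotropy_constant * vh / kbt
    if not math.isfinite(gamma):
        raise ValueError("anisotropy ratio is not finite")
    if spec.neel_form == "rosensweig":
        tau_n = (math.sqrt(math.pi) / 2.0) * spec.attempt_time \
            * math.exp(gamma) / math.sqrt(gamma)
    else:  # literal rendering of the source formula
        tau_n = math.pi * spec.attempt_time * math.exp(gamma) / (2.0 * gamma)
    tau_eff = tau_b * tau_n / (tau_b + tau_n)
    return RelaxationTimes(brown=tau_b, neel=tau_n, effective=tau_eff,
                           anisotropy_ratio=gamma)


def initial_susceptibility(spec: MagneticSpec, Ts: float = 310.15) -> float:
    """chi_i = mu0 Md^2 V_M / (3 kB Ts), per unit particle volume.

    The MNP volume fraction is *not* folded in here; it appears exactly once,
    explicitly, in :func:`volumetric_power`.
    """
    return MU0 * spec.domain_magnetization**2 * spec.magnetic_volume / (3.0 * KB * Ts)


def langevin_parameter(spec: MagneticSpec, amplitude: float,
                       Ts: float = 310.15) -> float:
    """xi = mu0 Md Hm V_M / (kB Ts)."""
    return MU0 * spec.domain_magnetization * amplitude * spec.magnetic_volume \
        / (KB * Ts)


def equilibrium_susceptibility(spec: MagneticSpec, field: FieldSpec,
                               Ts: float = 310.15) -> float:
    """Chord (Langevin) susceptibility chi_0 = chi_i (3/xi)(coth xi - 1/xi).

    Reduces to chi_i as Hm -> 0 and decreases monotonically with field
    amplitude (Langevin saturation).
    """
    chi_i = initial_susceptibility(spec, Ts)
    xi = langevin_parameter(spec, field.amplitude, Ts)
    if xi < 1e-6:
        # small-argument expansion of (3/xi) L(xi) = 1 - xi^2/15 + ...
        return chi_i * (1.0 - xi * xi / 15.0)
    chord = (3.0 / xi) * (1.0 / math.tanh(xi) - 1.0 / xi)
    return chi_i * chord


def volumetric_power(spec: MagneticSpec, field: FieldSpec,
                     Ts: float = 310.15,
                     volume_fraction: float | None = None) -> float:
    """Dissipated MNP power density Q_MNP (W/m^3 of composite).

    Q = phi mu0 chi0 Hm^2 f * [2 pi f tau / (1 + (2 pi f tau)^2)], with an
    optional textbook pi prefactor behind ``spec.rosensweig_pi``.
    ``volume_fraction`` overrides the spec's nominal value (used when the
    deposited dose spreads over a larger volume than injected).
    """
    phi = spec.volume_fraction if volume_fraction is None else volume_fraction
    if field.amplitude == 0.0 or field.frequency == 0.0 or phi == 0.0:
        return 0.0
    chi0 = equilibrium_susceptibility(spec, field, Ts)
    tau = relaxation_times(spec, Ts).effective
    x = 2.0 * math.pi * field.frequency * tau
    bracket = x / (1.0 + x * x)
    q = phi * MU0 * chi0 * field.amplitude**2 * field.frequency * bracket
    if spec.rosensweig_pi:
        q *= math.pi
    return q


def power_summary(spec: MagneticSpec, field: FieldSpec,
                  Ts_celsius: float = 37.0) -> dict:
    """Diagnostic bundle for calibration and the CLI ``mnp-power`` command."""
    Ts = Ts_celsius + CELSIUS_OFFSET
    times = relaxation_times(spec, Ts)
    return {
        "tau_brown_s": times.brown,
        "tau_neel_s": times.neel,
        "tau_eff_s": times.effective,
        "anisotropy_ratio": times.anisotropy_ratio,
        "chi_initial": initial_susceptibility(spec, Ts),
        "chi0": equilibrium_susceptibility(spec, field, Ts),
        "langevin_parameter": langevin_parameter(spec, field.amplitude, Ts),
        "q_mnp_w_per_m3": volumetric_power(spec, field, Ts),
    }
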