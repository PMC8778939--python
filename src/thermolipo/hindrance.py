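"""Hindered-pore closure for liposome transvascular transport.

The vessel wall is modelled as a population of cylindrical pores whose
diameters are lognormally distributed around the nominal pore size (tumor
vasculature is leaky and heterogeneous; a single pore size would make a
carrier exactly as large as the nominal pore completely impermeant, which
is neither physical nor observed).  For a carrier-to-pore diameter ratio
lam the classic Renkin-Deen steric factors apply per pore:

    diffusive   H(lam) = (1-lam)^2 (1 - 2.104 lam + 2.09 lam^3 - 0.95 lam^5)
    reflection  sigma(lam) = (1 - (1-lam)^2)^2

and the wall-scale coefficients are conductance (pore-area) weighted means
over the distribution.  The liposome wall permeability is then
P_tsl = tsl_permeability_scale * H_eff, where the scale absorbs pore length
and density (not separately observable here; calibrated against the
treatment observables, see docs/methods.md).
"""

from __future__ import annotations

import math

import numpy as np

from .params import DrugParams

_GH_POINTS = 48


def renkin_diffusive(lam: np.ndarray) -> np.ndarray:
    """Steric + hydrodynamic hindrance to diffusion in a cylindrical pore."""
    lam = np.asarray(lam, dtype=float)
    h = (1 - lam) ** 2 * (1 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5)
    return np.where(lam < 1.0, np.maximum(h, 0.0), 0.0)


def pore_reflection(lam: np.ndarray) -> np.ndarray:
    """Osmotic/filtration reflection coefficient of a single pore."""
    lam = np.asarray(lam, dtype=float)
    sigma = (1 - (1 - lam) ** 2) ** 2
    return np.where(lam < 1.0, np.clip(sigma, 0.0, 1.0), 1.0)


def _lognormal_quadrature(median: float, gsd: float, n: int = _GH_POINTS):
    """Gauss-Hermite nodes/weights for E[f(d)] with d lognormal."""
    z, w = np.polynomial.hermite_e.hermegauss(n)
    sigma_ln = math.log(gsd)
    d = median * np.exp(sigma_ln * z)
    return d, w / w.sum()


def effective_hindrance(carrier_diameter: float, pore_diameter: float,
                        gsd: float = 1.6) -> tuple[float, float]:
    """Pore-area-weighted (H_eff, sigma_eff) over the pore-size distribution."""
    if gsd <= 1.0:
        lam = carrier_diameter / pore_diameter
        return float(renkin_diffusive(lam)), float(pore_reflection(lam))
    d, w = _lognormal_quadrature(pore_diameter, gsd)
    lam = carrier_diameter / d
    area_w = w * d**2
    area_w = area_w / area_w.sum()
    h_eff = float(np.dot(area_w, renkin_diffusive(lam)))
    sigma_eff = float(np.dot(area_w, pore_reflection(lam)))
    return h_eff, sigma_eff


def tsl_wall_coefficients(drug: DrugParams,
                          pore_diameter: float | None = None,
                          normal_tissue: bool = False) -> tuple[float, float]:
    """(P_tsl, sigma_f_tsl) for the tumor (or normal-tissue) vessel wall.

    Explicit overrides in the config short-circuit the closure.  Normal
    vasculature (pores ~12 nm) is effectively impermeable to 100 nm
    liposomes, which is what confines TSL extravasation to the tumor.
    """
    if pore_diameter is None:
        pore_diameter = (drug.normal_pore_diameter if normal_tissue
                         else drug.vessel_pore_diameter)
        if not normal_tissue and drug.vessel_permeability_tsl is not None:
            sigma = drug.filtration_reflection_tsl
            if sigma is None:
                _, sigma = effective_hindrance(
                    drug.carrier_diameter, pore_diameter, drug.pore_gsd)
            return drug.vessel_permeability_tsl, sigma
    h_eff, sigma_eff = effective_hindrance(
        drug.carrier_diameter, pore_diameter, drug.pore_gsd)
    p_tsl = drug.tsl_permeability_scale * h_eff
    if drug.filtration_reflection_tsl is not None and not normal_tissue:
        sigma_eff = drug.filtration_reflection_tsl
    return p_tsl, sigma_eff
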