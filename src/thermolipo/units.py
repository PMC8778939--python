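"""Unit conversion at the I/O boundary.

The solver works in SI throughout; the tumor-transport literature quotes
hydraulic properties in cm/mmHg units and schedules in hours, so conversion
happens exactly once, when a scenario document is resolved.
"""

from __future__ import annotations

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322

# (from, to) -> multiplicative factor
_FACTORS: dict[tuple[str, str], float] = {
    ("mmHg", "Pa"): PA_PER_MMHG,
    ("cm", "m"): 1e-2,
    ("h", "s"): 3600.0,
    ("min", "s"): 60.0,
    ("M", "mol/m^3"): 1000.0,
    ("cm/s", "m/s"): 1e-2,
    ("cm^2/s", "m^2/s"): 1e-4,
    ("1/cm", "1/m"): 1e2,
    ("cm/(mmHg*s)", "m/(Pa*s)"): 1e-2 / 133.322,
    ("cm^2/(mmHg*s)", "m^2/(Pa*s)"): 1e-4 / 133.322,
    ("nm", "m"): 1e-9,
}
# closed under inversion
for (_a, _b), _f in list(_FACTORS.items()):
    _FACTORS[(_b, _a)] = 1.0 / _f
for _u in {u for pair in _FACTORS for u in pair}:
    _FACTORS[(_u, _u)] = 1.0


class UnsupportedUnitError(ValueError):
    pass


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two supported units.

    Round trips are exact to floating point (a single multiplicative factor
    and its reciprocal), satisfying the 1e-12 relative identity contract.
    """
    try:
        factor = _FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise UnsupportedUnitError(
            f"unsupported unit conversion: {from_unit!r} -> {to_unit!r}"
        ) from None
    return value * factor
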