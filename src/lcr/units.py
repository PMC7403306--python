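"""Unit handling at I/O boundaries.

Everything inside the package is SI (m, s, Pa, K).  Laboratory-facing
files and configuration use the units the instrument community works in
(µm, µs, kPa); conversion happens here and only here.
"""

from __future__ import annotations

import re

# multiplicative factors to SI, keyed by lower-cased unit symbol
UNIT_FACTORS: dict[str, float] = {
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # time
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6, "ns": 1e-9,
    # pressure / modulus
    "pa": 1.0, "kpa": 1e3, "mpa": 1e6,
    # kinematic viscosity
    "m^2/s": 1.0, "m2/s": 1.0, "mm^2/s": 1e-6, "mm2/s": 1e-6, "cst": 1e-6,
    # surface tension
    "n/m": 1.0, "mn/m": 1e-3,
    # density
    "kg/m^3": 1.0, "kg/m3": 1.0, "g/cm^3": 1e3, "g/cm3": 1e3, "g/ml": 1e3,
    # temperature (kelvin only; no offsets)
    "k": 1.0,
    # strain and other dimensionless quantities
    "": 1.0, "-": 1.0, "1": 1.0,
}

#: handy scale constants for the µm/µs/kPa boundary
UM = 1e-6
US = 1e-6
KPA = 1e3

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


def parse_quantity(value: float | int | str) -> float:
    """Convert a number or a "number unit" string to an SI float.

    >>> parse_quantity("20 kPa")
    20000.0
    >>> parse_quantity(3169)
    3169.0
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANTITY_RE.match(value)
    if m is None:
        raise ValueError(f"cannot parse quantity {value!r}")
    number, unit = m.groups()
    key = unit.lower().replace("μ", "µ")
    if key not in UNIT_FACTORS:
        raise ValueError(
            f"unknown unit {unit!r} in {value!r}; known units: "
            + ", ".join(sorted(u for u in UNIT_FACTORS if u))
        )
    return float(number) * UNIT_FACTORS[key]
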