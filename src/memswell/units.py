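"""Quantity-string parsing and unit conversion.

Every physical input is given as a ``"value unit"`` string (e.g.
``"0.0101 dyn/nm"``) and converted explicitly to the package's canonical
units.  The canonical choices are the ones the formulas are evaluated in:

========================  ==================  =========================
quantity                  canonical unit      notes
========================  ==================  =========================
length                    um                  geometry works in um
area                      um^2
volume                    um^3
stretch rigidity          N/m                 1 dyn/nm = 1e4 N/m
pressure                  Pa
water permeability        m/s/Pa              volume flux / area / Pa
concentration             mM                  1 mM = 1 mol/m^3 exactly
temperature               K
time                      s
bending modulus           erg                 1 erg = 1e-7 J
curvature                 1/um
========================  ==================  =========================

Disruption coefficients (``um^-n1``) are dimensionful in a strain power
that depends on the exponent ``n1``; they are accepted in ``um^-<n>``
only and carried through unconverted.
"""

from __future__ import annotations

import re

__all__ = ["UnitError", "parse_quantity", "convert", "CANONICAL"]


class UnitError(ValueError):
    """Raised when a quantity string cannot be parsed or converted."""


#: factor tables: unit spelling -> multiplier into the canonical unit
_TABLES: dict[str, dict[str, float]] = {
    "length": {"um": 1.0, "µm": 1.0, "micron": 1.0, "nm": 1e-3, "mm": 1e3, "m": 1e6},
    "area": {"um^2": 1.0, "µm^2": 1.0, "m^2": 1e12},
    "volume": {"um^3": 1.0, "µm^3": 1.0, "m^3": 1e18, "ul": 1e9, "L": 1e15},
    "rigidity": {"N/m": 1.0, "mN/m": 1e-3, "dyn/nm": 1e4, "dyn/cm": 1e-3, "dyn/um": 10.0},
    "pressure": {"Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "barye": 0.1, "dyn/cm^2": 0.1, "atm": 101325.0},
    # volume flux per unit area per unit pressure
    "permeability": {
        "m/s/Pa": 1.0,
        "m/(s Pa)": 1.0,
        "um/s/Pa": 1e-6,
        "cm/s/Pa": 1e-2,
        # 1 ul/min per Pa per um^2 = 1e-9 m^3 / (60 s * Pa * 1e-12 m^2)
        "ul/min/Pa/um^2": 1e-9 / 60.0 / 1e-12,
        "ul min^-1 Pa^-1 um^-2": 1e-9 / 60.0 / 1e-12,
    },
    "concentration": {"mM": 1.0, "mol/m^3": 1.0, "M": 1e3, "mol/L": 1e3, "uM": 1e-3},
    "temperature": {"K": 1.0},
    "time": {"s": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0},
    "energy": {"erg": 1.0, "J": 1e7, "kT": None},  # kT rejected below (T-dependent)
    "curvature": {"1/um": 1.0, "um^-1": 1.0, "1/m": 1e-6, "m^-1": 1e-6},
}

CANONICAL = {
    "length": "um",
    "area": "um^2",
    "volume": "um^3",
    "rigidity": "N/m",
    "pressure": "Pa",
    "permeability": "m/s/Pa",
    "concentration": "mM",
    "temperature": "K",
    "time": "s",
    "energy": "erg",
    "curvature": "1/um",
}

_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"
_QUANTITY_RE = re.compile(rf"^\s*({_NUM})\s*(.*?)\s*$")
_DISRUPTION_RE = re.compile(r"^(?:um|µm)\^?(-\d+)$")


def parse_quantity(text: str | float | int) -> tuple[float, str]:
    """Split ``"3.1e2 ul/min/Pa/um^2"`` into ``(310.0, "ul/min/Pa/um^2")``.

    Bare numbers (or numeric types) parse with an empty unit string.
    """
    if isinstance(text, (int, float)):
        return float(text), ""
    m = _QUANTITY_RE.match(str(text))
    if not m:
        raise UnitError(f"cannot parse quantity {text!r}")
    return float(m.group(1)), m.group(2)


def convert(text: str | float | int, kind: str, *, n1: int | None = None) -> float:
    """Convert a quantity string to the canonical unit of *kind*.

    ``kind="disruption"`` accepts ``um^-<n>`` (optionally checked against
    the disruption exponent *n1*) and returns the value unchanged — the
    canonical strain unit is um.  A bare number is accepted for any kind
    and taken to already be in canonical units.
    """
    value, unit = parse_quantity(text)
    if unit == "":
        return value
    if kind == "disruption":
        m = _DISRUPTION_RE.match(unit.replace(" ", ""))
        if not m:
            raise UnitError(f"disruption coefficient needs unit um^-<n>, got {unit!r}")
        if n1 is not None and int(m.group(1)) != -n1:
            raise UnitError(f"disruption unit {unit!r} inconsistent with n1={n1}")
        return value
    try:
        table = _TABLES[kind]
    except KeyError:
        raise UnitError(f"unknown quantity kind {kind!r}") from None
    norm = unit.replace("µ", "u").replace("μ", "u")
    for spelling, factor in table.items():
        if spelling.replace("µ", "u") == norm:
            if factor is None:
                raise UnitError(f"unit {unit!r} is not convertible for {kind}")
            return value * factor
    raise UnitError(f"unknown {kind} unit {unit!r} (accepted: {sorted(table)})")
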