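"""Unit-tagged quantities and bit-stable conversions.

Every downstream formula in this package is evaluated in SI after
normalizing its inputs here. The unit vocabulary is deliberately closed:
it covers exactly the dimensions that appear in swine thoracic-duct
hemodynamics (pressures/stresses, volumetric flows, lengths, areas,
viscosities, masses, time) — this is not a general unit-algebra system.

Conversion factors worth noting:

* 1 mmHg = 133.322 Pa (stored at full precision; rounds to the commonly
  printed 133.32 at two decimals),
* 1 cmH2O = 98.0665 Pa,
* 1 dyn/cm^2 = 0.1 Pa,
* 1 ml/min = 1e-6/60 m^3/s (exactly; the frequently quoted 1.67e-5 L/s
  is the rounded form of 1.6667e-5).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


class DimensionError(ValueError):
    """Raised when a conversion is requested across incompatible dimensions."""


class UnknownUnitError(ValueError):
    """Raised for a unit tag outside the supported vocabulary."""


#: alias -> canonical tag (unicode and spelling variants)
_ALIASES = {
    "dyn/cm²": "dyn/cm2",
    "dynes/cm2": "dyn/cm2",
    "mm²": "mm2",
    "cm²": "cm2",
    "m²": "m2",
    "cm³/s": "cm3/s",
    "m³/s": "m3/s",
    "l/s": "L/s",
    "mL/min": "ml/min",
    "Pa.s": "Pa·s",
    "Pa*s": "Pa·s",
    "1": "dimensionless",
    "": "dimensionless",
}

#: canonical tag -> (dimension, multiplicative factor to SI)
_UNITS: dict[str, tuple[str, float]] = {
    "Pa": ("pressure", 1.0),
    "kPa": ("pressure", 1e3),
    "mmHg": ("pressure", 133.322),
    "cmH2O": ("pressure", 98.0665),
    "dyn/cm2": ("pressure", 0.1),
    "m3/s": ("flow", 1.0),
    "L/s": ("flow", 1e-3),
    "cm3/s": ("flow", 1e-6),
    "ml/min": ("flow", 1e-6 / 60.0),
    "m": ("length", 1.0),
    "cm": ("length", 1e-2),
    "mm": ("length", 1e-3),
    "m2": ("area", 1.0),
    "cm2": ("area", 1e-4),
    "mm2": ("area", 1e-6),
    "Pa·s": ("viscosity", 1.0),
    "P": ("viscosity", 0.1),
    "cP": ("viscosity", 1e-3),
    "kg": ("mass", 1.0),
    "g": ("mass", 1e-3),
    "s": ("time", 1.0),
    "min": ("time", 60.0),
    "dimensionless": ("dimensionless", 1.0),
}

#: dimension -> its SI unit tag
SI_UNIT = {
    "pressure": "Pa",
    "flow": "m3/s",
    "length": "m",
    "area": "m2",
    "viscosity": "Pa·s",
    "mass": "kg",
    "time": "s",
    "dimensionless": "dimensionless",
}


def canonical_unit(unit: str) -> str:
    """Resolve aliases to the canonical unit tag, validating the tag."""
    tag = _ALIASES.get(unit, unit)
    if tag not in _UNITS:
        raise UnknownUnitError(f"unknown unit tag {unit!r}")
    return tag


def dimension_of(unit: str) -> str:
    """Dimension name ('pressure', 'flow', ...) of a unit tag."""
    return _UNITS[canonical_unit(unit)][0]


@dataclass(frozen=True)
class Quantity:
    """A scalar magnitude with a unit tag from the closed vocabulary."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", canonical_unit(self.unit))
        object.__setattr__(self, "value", float(self.value))

    @property
    def dimension(self) -> str:
        return _UNITS[self.unit][0]

    def to(self, target_unit: str) -> "Quantity":
        return convert(self, target_unit)

    def si(self) -> "Quantity":
        """The same quantity expressed in its dimension's SI unit."""
        return self.to(SI_UNIT[self.dimension])

    @property
    def si_value(self) -> float:
        return self.value * _UNITS[self.unit][1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:g} {self.unit}"


def q(value: float, unit: str) -> Quantity:
    """Shorthand constructor."""
    return Quantity(value, unit)


def convert(quantity: Quantity, target_unit: str) -> Quantity:
    """Convert a quantity to a compatible unit.

    Raises
    ------
    DimensionError
        If the source and target tags live in different dimensions; the
        message names both dimensions.
    """
    target = canonical_unit(target_unit)
    src_dim, src_factor = _UNITS[quantity.unit]
    tgt_dim, tgt_factor = _UNITS[target]
    if src_dim != tgt_dim:
        raise DimensionError(
            f"cannot convert {quantity.unit!r} ({src_dim}) to {target!r} ({tgt_dim})"
        )
    return Quantity(quantity.value * src_factor / tgt_factor, target)


def as_si(value: float, unit: str) -> float:
    """Magnitude of ``value unit`` in the dimension's SI unit."""
    return float(value) * _UNITS[canonical_unit(unit)][1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Deterministic half-up rounding at a fixed decimal position.

    Floats are pre-rounded to 12 significant digits so that values such as
    0.2550000000000001 (a binary artifact of 0.51/2) round to 0.26 rather
    than tracking the representation error.
    """
    d = Decimal(f"{float(x):.12g}")
    exp = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(exp, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Half-up rounding to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not sig > 0:
        return 0.0
    d = Decimal(f"{float(x):.12g}")
    shift = sig - 1 - d.adjusted()
    exp = Decimal(1).scaleb(-shift)
    return float(d.quantize(exp, rounding=ROUND_HALF_UP))


def format_unit_column(name: str, unit: str) -> str:
    """CSV header convention: bracketed unit suffix, e.g. ``pressure[mmHg]``."""
    return f"{name}[{unit}]"


def parse_unit_column(header: str) -> tuple[str, str]:
    """Split ``name[unit]`` into (name, canonical unit tag).

    A bare header is treated as dimensionless — the report validator uses
    this to reject unitless numeric columns.
    """
    if header.endswith("]") and "[" in header:
        name, unit = header[:-1].split("[", 1)
        return name, canonical_unit(unit)
    return header, "dimensionless"
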