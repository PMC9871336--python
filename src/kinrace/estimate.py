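"""Rate estimates with symmetric 95% confidence intervals and unit algebra.

Every derived quantity in the kinetic-race analysis (dwell time, off-rate,
run length, step count, tethered-head on-rate, dissociation constant, fold
change) is a nonnegative number with a symmetric 95% CI and a physical unit.
:class:`RateEstimate` carries all three and implements first-order
relative-error quadrature for products, quotients, and reciprocals, which is
the standard propagation rule for uncorrelated multiplicative errors:

    (dz/z)^2 = (dx/x)^2 + (dy/y)^2      for z = x*y or z = x/y.

Units live on a small three-dimensional lattice (time, concentration,
length); multiplying or dividing estimates adds/subtracts exponents, and the
result must land on one of the named units below or a :class:`UnitError` is
raised — mixing incompatible units never silently computes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import DomainError, UnitError

__all__ = ["Unit", "RateEstimate"]


class Unit(str, Enum):
    """Named units used by the analysis.

    The value strings double as CSV/JSON tags.
    """

    PER_SECOND = "per_second"
    PER_MICROMOLAR_PER_SECOND = "per_micromolar_per_second"
    MICROMOLAR = "micromolar"
    MICROMETER = "micrometer"
    SECOND = "second"
    DIMENSIONLESS = "dimensionless"


# dimension exponents: (time, concentration, length)
_DIMS: dict[Unit, tuple[int, int, int]] = {
    Unit.PER_SECOND: (-1, 0, 0),
    Unit.PER_MICROMOLAR_PER_SECOND: (-1, -1, 0),
    Unit.MICROMOLAR: (0, 1, 0),
    Unit.MICROMETER: (0, 0, 1),
    Unit.SECOND: (1, 0, 0),
    Unit.DIMENSIONLESS: (0, 0, 0),
}
_FROM_DIMS = {dims: unit for unit, dims in _DIMS.items()}


def _combine(a: Unit, b: Unit, sign: int) -> Unit:
    da, db = _DIMS[a], _DIMS[b]
    dims = tuple(x + sign * y for x, y in zip(da, db))
    try:
        return _FROM_DIMS[dims]
    except KeyError:
        op = "*" if sign > 0 else "/"
        raise UnitError(
            f"{a.value} {op} {b.value} has no named unit (dims {dims})"
        ) from None


@dataclass(frozen=True)
class RateEstimate:
    """A nonnegative value with a symmetric 95% CI half-width and a unit.

    Parameters
    ----------
    value:
        Point estimate; must be >= 0.
    ci95:
        Half-width of the symmetric 95% confidence interval, same unit as
        ``value``; must be >= 0. Defaults to 0 (exact).
    unit:
        One of :class:`Unit`. Defaults to dimensionless.
    """

    value: float
    ci95: float = 0.0
    unit: Unit = Unit.DIMENSIONLESS

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise DomainError(f"value must be finite and >= 0, got {self.value}")
        if not math.isfinite(self.ci95) or self.ci95 < 0:
            raise DomainError(f"ci95 must be finite and >= 0, got {self.ci95}")
        object.__setattr__(self, "unit", Unit(self.unit))

    @property
    def relative_ci(self) -> float:
        """ci95 / value; 0 for a zero value with zero CI."""
        if self.value == 0:
            return 0.0 if self.ci95 == 0 else math.inf
        return self.ci95 / self.value

    # -- arithmetic with relative-error quadrature ---------------------------

    def __mul__(self, other: "RateEstimate | float") -> "RateEstimate":
        if isinstance(other, RateEstimate):
            value = self.value * other.value
            rel = math.hypot(self.relative_ci, other.relative_ci)
            return RateEstimate(value, value * rel, _combine(self.unit, other.unit, +1))
        return self.scaled(float(other))

    __rmul__ = __mul__

    def __truediv__(self, other: "RateEstimate | float") -> "RateEstimate":
        if isinstance(other, RateEstimate):
            if other.value == 0:
                raise DomainError("division by a zero-valued estimate")
            value = self.value / other.value
            rel = math.hypot(self.relative_ci, other.relative_ci)
            return RateEstimate(value, value * rel, _combine(self.unit, other.unit, -1))
        return self.scaled(1.0 / float(other))

    def reciprocal(self) -> "RateEstimate":
        """1/x with the relative CI preserved (first order)."""
        if self.value == 0:
            raise DomainError("reciprocal of a zero-valued estimate")
        value = 1.0 / self.value
        unit = _combine(Unit.DIMENSIONLESS, self.unit, -1)
        return RateEstimate(value, value * self.relative_ci, unit)

    def scaled(self, factor: float) -> "RateEstimate":
        """Multiply by an exact scalar (> 0); CI scales by the same factor."""
        if factor <= 0 or not math.isfinite(factor):
            raise DomainError(f"scale factor must be finite and > 0, got {factor}")
        return RateEstimate(self.value * factor, self.ci95 * factor, self.unit)

    def with_unit(self, unit: Unit) -> "RateEstimate":
        """Relabel the unit without touching the numbers (explicit cast)."""
        return RateEstimate(self.value, self.ci95, Unit(unit))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:g} ± {self.ci95:g} {self.unit.value}"
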