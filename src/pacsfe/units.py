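"""Unit-tagged energies.

Free energies in this package travel either in reduced units (multiples of
the thermal energy kT) or in kcal/mol.  Mixing the two without an explicit
conversion is a hard error rather than a silent bug, so energies that cross
module boundaries are wrapped in :class:`Energy`.
"""
from __future__ import annotations

from dataclasses import dataclass

from .constants import kt_kcal_per_mol

KT = "kT"
KCAL_PER_MOL = "kcal/mol"
_UNITS = (KT, KCAL_PER_MOL)


class UnitsError(TypeError):
    """Raised when energies in different units are combined without conversion."""


@dataclass(frozen=True)
class Energy:
    """An energy value with an explicit unit tag ("kT" or "kcal/mol")."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise UnitsError(f"unknown energy unit {self.unit!r}; expected one of {_UNITS}")

    def to(self, unit: str, temperature: float | None = None) -> "Energy":
        """Convert to ``unit``; kT <-> kcal/mol requires a temperature in K."""
        if unit not in _UNITS:
            raise UnitsError(f"unknown energy unit {unit!r}")
        if unit == self.unit:
            return self
        if temperature is None:
            raise UnitsError(
                f"converting {self.unit} -> {unit} requires an explicit temperature"
            )
        kt = kt_kcal_per_mol(temperature)
        if self.unit == KT:
            return Energy(self.value * kt, KCAL_PER_MOL)
        return Energy(self.value / kt, KT)

    def in_kt(self, temperature: float | None = None) -> float:
        return self.to(KT, temperature).value

    def in_kcal_per_mol(self, temperature: float | None = None) -> float:
        return self.to(KCAL_PER_MOL, temperature).value

    def _check(self, other: object) -> "Energy":
        if not isinstance(other, Energy):
            raise UnitsError(
                "bare numbers cannot be combined with a unit-tagged Energy; wrap them"
            )
        if other.unit != self.unit:
            raise UnitsError(
                f"cannot combine energies in {self.unit!r} and {other.unit!r} "
                "without an explicit .to() conversion"
            )
        return other

    def __add__(self, other: object) -> "Energy":
        return Energy(self.value + self._check(other).value, self.unit)

    def __sub__(self, other: object) -> "Energy":
        return Energy(self.value - self._check(other).value, self.unit)

    def __neg__(self) -> "Energy":
        return Energy(-self.value, self.unit)
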