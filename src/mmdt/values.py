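"""Tagged clinical value union and unit normalization.

Every observation or derivation result is a :class:`ClinicalValue`: a number
with a unit, a category drawn from the entity's declared value set, a
three-valued state, or a date.  An absent observation is represented as the
UNKNOWN tri-state so that operators receive a uniform input type.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tristate import TriState, UNKNOWN

NUMERIC = "numeric"
CATEGORY = "category"
TRISTATE = "tristate"
DATE = "date"


class UnitError(ValueError):
    """Raised when a value's unit cannot be normalized to the entity's unit."""


@dataclass(frozen=True)
class ClinicalValue:
    kind: str
    magnitude: float | None = None
    unit: str = ""
    label: str | None = None
    state: TriState | None = None
    date: str | None = None

    # -- constructors -------------------------------------------------
    @classmethod
    def number(cls, magnitude: float, unit: str = "") -> "ClinicalValue":
        return cls(kind=NUMERIC, magnitude=float(magnitude), unit=unit)

    @classmethod
    def category(cls, label: str) -> "ClinicalValue":
        return cls(kind=CATEGORY, label=str(label))

    @classmethod
    def tristate(cls, state: TriState) -> "ClinicalValue":
        return cls(kind=TRISTATE, state=state)

    @classmethod
    def date_value(cls, iso: str) -> "ClinicalValue":
        return cls(kind=DATE, date=iso)

    @classmethod
    def unknown(cls) -> "ClinicalValue":
        return cls(kind=TRISTATE, state=UNKNOWN)

    # -- accessors ----------------------------------------------------
    def is_unknown(self) -> bool:
        return self.kind == TRISTATE and self.state is UNKNOWN

    def as_number(self) -> float | None:
        """The numeric magnitude, or None when absent/non-numeric."""
        if self.kind == NUMERIC:
            return self.magnitude
        return None

    def as_category(self) -> str | None:
        if self.kind == CATEGORY:
            return self.label
        return None

    def as_tristate(self) -> TriState:
        if self.kind == TRISTATE and self.state is not None:
            return self.state
        return UNKNOWN

    def to_jsonable(self) -> dict:
        out: dict = {"kind": self.kind}
        if self.kind == NUMERIC:
            out["magnitude"] = self.magnitude
            out["unit"] = self.unit
        elif self.kind == CATEGORY:
            out["label"] = self.label
        elif self.kind == TRISTATE:
            out["state"] = self.state.value if self.state else "unknown"
        elif self.kind == DATE:
            out["date"] = self.date
        return out


# Canonical units per quantity, with the conversions routine data actually
# mixes (labs are reported in g/l vs g/dl, µmol/L vs mg/dl, ...).  Factors
# convert *from* the listed unit *to* the canonical unit.
_CONVERSIONS: dict[str, dict[str, float]] = {
    "g/dl": {"g/dl": 1.0, "g/l": 0.1, "mg/ml": 0.1},
    "mg/l": {"mg/l": 1.0, "mg/dl": 10.0, "ug/ml": 1.0, "µg/ml": 1.0},
    "mmol/l": {"mmol/l": 1.0, "mg/dl": 0.2495},  # total calcium
    "mg/dl": {"mg/dl": 1.0, "umol/l": 1.0 / 88.4, "µmol/l": 1.0 / 88.4},  # creatinine
    "ml/min": {"ml/min": 1.0, "ml/min/1.73m2": 1.0},
    "years": {"years": 1.0, "a": 1.0},
    "%": {"%": 1.0},
    "": {"": 1.0},
}


def normalize_unit(magnitude: float, unit: str, canonical: str) -> float:
    """Convert ``magnitude`` expressed in ``unit`` to the canonical unit.

    Raises :class:`UnitError` when no conversion is known.
    """
    unit_key = unit.strip().lower()
    canonical_key = canonical.strip().lower()
    if unit_key == canonical_key or (canonical_key == "dimensionless" and unit_key in ("", "dimensionless")):
        return float(magnitude)
    table = _CONVERSIONS.get(canonical_key)
    if table is None or unit_key not in table:
        raise UnitError(f"cannot convert unit {unit!r} to canonical {canonical!r}")
    return float(magnitude) * table[unit_key]
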