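"""Three-valued (Kleene) logic for clinical facts.

Missing clinical data must not be mistaken for a negative finding: a high-risk
state can be *confirmed* from partial data (one positive marker suffices) but
its *absence* can only be concluded once every contributing marker is known to
be negative.  ``TriState`` and the disjunction/conjunction below implement
exactly that asymmetry.
"""

from __future__ import annotations

import enum
from typing import Iterable


class TriState(enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("TriState is not coercible to bool; compare explicitly")

    @classmethod
    def from_bool(cls, value: bool | None) -> "TriState":
        if value is None:
            return cls.UNKNOWN
        return cls.YES if value else cls.NO


YES = TriState.YES
NO = TriState.NO
UNKNOWN = TriState.UNKNOWN


def tri_or(values: Iterable[TriState]) -> TriState:
    """Kleene disjunction: YES dominates; NO only if every input is NO."""
    result = NO
    for v in values:
        if v is YES:
            return YES
        if v is UNKNOWN:
            result = UNKNOWN
    return result


def tri_and(values: Iterable[TriState]) -> TriState:
    """Kleene conjunction: NO dominates; YES only if every input is YES."""
    result = YES
    for v in values:
        if v is NO:
            return NO
        if v is UNKNOWN:
            result = UNKNOWN
    return result


def tri_not(value: TriState) -> TriState:
    if value is UNKNOWN:
        return UNKNOWN
    return NO if value is YES else YES
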