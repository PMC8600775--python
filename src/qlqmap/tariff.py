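"""UK EQ-5D-3L value set and the geometry of the feasible utility space.

The EQ-5D-3L describes health on five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at one of
three levels, giving 3**5 = 243 distinct states.  A country-specific
value set (tariff) converts a state into a societal utility.  The UK
time-trade-off tariff shipped here has three structural features that
shape every model downstream:

* full health (state 11111) is valued at exactly 1;
* the next feasible value below 1 is 0.883, so the open interval
  (0.883, 1) contains no attainable utility (the "gap");
* the worst state 33333 ("pits") is valued at -0.594, the floor.

Utilities are plain floats; feasibility is enforced by validators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DIMENSIONS",
    "Eq5dResponse",
    "ValueSet",
    "UK_TTO",
    "FULL_HEALTH",
    "FLOOR",
    "GAP_LOWER",
    "score_state",
    "score_levels",
    "enumerate_states",
    "feasible_utilities",
    "validate_utilities",
    "InvalidStateError",
    "InfeasibleUtilityError",
]

#: Dimension names in tariff order (also the lexicographic enumeration order,
#: mobility varying slowest).
DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


class InvalidStateError(ValueError):
    """A dimension level outside {1, 2, 3}."""


class InfeasibleUtilityError(ValueError):
    """A utility value in one of the three infeasible zones."""


@dataclass(frozen=True)
class Eq5dResponse:
    """One EQ-5D-3L health state: five dimension levels, each in {1, 2, 3}."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for name in DIMENSIONS:
            level = getattr(self, name)
            if level not in (1, 2, 3):
                raise InvalidStateError(
                    f"{name} level must be 1, 2 or 3; got {level!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, name) for name in DIMENSIONS)

    @property
    def label(self) -> str:
        """Compact state label, e.g. '11223'."""
        return "".join(str(v) for v in self.levels)

    @classmethod
    def from_label(cls, label: str) -> "Eq5dResponse":
        if len(label) != 5 or not label.isdigit():
            raise InvalidStateError(f"state label must be 5 digits, got {label!r}")
        return cls(*(int(ch) for ch in label))


@dataclass(frozen=True)
class ValueSet:
    """A 3L tariff: constant + per-level decrements subtracted from 1.

    ``constant`` applies as soon as any dimension leaves level 1;
    ``any_level3`` (the N3 term) applies once if any dimension is at
    level 3.  ``level2``/``level3`` are per-dimension decrements in
    :data:`DIMENSIONS` order.  Only the UK TTO set ships, but any 3L
    tariff with this structure can be plugged in.
    """

    constant: float = 0.081
    any_level3: float = 0.269
    level2: tuple[float, ...] = (0.069, 0.104, 0.036, 0.123, 0.071)
    level3: tuple[float, ...] = (0.314, 0.214, 0.094, 0.386, 0.236)

    def __post_init__(self) -> None:
        if len(self.level2) != 5 or len(self.level3) != 5:
            raise ValueError("level2/level3 must each have 5 entries")


#: The UK time-trade-off value set.
UK_TTO = ValueSet()

FULL_HEALTH: float = 1.0
#: Utility of the pits state 33333 under the UK tariff.
FLOOR: float = -0.594
#: Largest feasible utility strictly below full health (state 11211).
GAP_LOWER: float = 0.883


def score_state(state: Eq5dResponse, value_set: ValueSet = UK_TTO) -> float:
    """Tariff utility of a single state.

    Returns exactly 1.0 for 11111; otherwise 1 minus the constant, the
    per-dimension level decrements and (if any dimension is at level 3)
    the N3 decrement.
    """
    levels = state.levels
    if all(v == 1 for v in levels):
        return FULL_HEALTH
    value = 1.0 - value_set.constant
    for i, level in enumerate(levels):
        if level == 2:
            value -= value_set.level2[i]
        elif level == 3:
            value -= value_set.level3[i]
    if any(v == 3 for v in levels):
        value -= value_set.any_level3
    return round(value, 10)


def score_levels(levels: np.ndarray, value_set: ValueSet = UK_TTO) -> np.ndarray:
    """Vectorised tariff scoring of an (n, 5) integer level array."""
    levels = np.asarray(levels)
    if levels.ndim != 2 or levels.shape[1] != 5:
        raise InvalidStateError("levels must be an (n, 5) array")
    if not np.isin(levels, (1, 2, 3)).all():
        raise InvalidStateError("all levels must be in {1, 2, 3}")
    l2 = np.asarray(value_set.level2)
    l3 = np.asarray(value_set.level3)
    any_dysf = (levels > 1).any(axis=1)
    any_l3 = (levels == 3).any(axis=1)
    value = (
        1.0
        - value_set.constant * any_dysf
        - ((levels == 2) * l2).sum(axis=1)
        - ((levels == 3) * l3).sum(axis=1)
        - value_set.any_level3 * any_l3
    )
    return np.round(value, 10)


def enumerate_states() -> list[Eq5dResponse]:
    """All 243 states in lexicographic order (mobility slowest-varying)."""
    return [Eq5dResponse(*lv) for lv in product((1, 2, 3), repeat=5)]


def feasible_utilities(value_set: ValueSet = UK_TTO) -> np.ndarray:
    """Sorted unique tariff values over all 243 states (ascending)."""
    values = [score_state(s, value_set) for s in enumerate_states()]
    return np.unique(np.asarray(values))


def validate_utilities(
    values: Iterable[float],
    floor: float = FLOOR,
    gap_lower: float = GAP_LOWER,
    atol: float = 1e-8,
) -> np.ndarray:
    """Check that every value lies in [floor, gap_lower] union {1}.

    Raises :class:`InfeasibleUtilityError` if any value sits in the gap
    (gap_lower, 1), above 1 or below the floor.  Returns the values as
    a float array for convenience.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    finite = arr[np.isfinite(arr)]
    if (finite > 1.0 + atol).any() or (finite < floor - atol).any():
        raise InfeasibleUtilityError("utility outside [floor, 1]")
    in_gap = (finite > gap_lower + atol) & (finite < 1.0 - atol)
    if in_gap.any():
        raise InfeasibleUtilityError(
            f"{int(in_gap.sum())} utilities in the infeasible gap "
            f"({gap_lower}, 1)"
        )
    return arr
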