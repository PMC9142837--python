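"""Regulation conditions: monotone update templates over regulator occupancy.

A component's next value depends only on how many of its effective
activators and repressors are currently active, coarsened to three
occupancy levels (``none``, ``some``, ``all``).  A *regulation condition*
is a Boolean table over the 3x3 grid of (activator level, repressor
level) that is

* non-decreasing as the activator level rises (none < some < all),
* non-increasing as the repressor level rises, and
* non-constant.

Exactly 20 of the 512 possible grid tables are monotone and exactly two
of those (all-false, all-true) are constant, leaving the 18 templates
used throughout this package.

Ordering convention
-------------------
The 18 tables are sorted by their 9-bit truth table read in the cell
order (none,none), (none,some), (none,all), (some,none), ...,
(all,all), false before true; then the table at index 5 is swapped with
the table

    AllActivators OR (NoRepressors AND NOT NoActivators)

i.e. ON exactly on the cells {(all, *), (some, none)}, so that index 5
carries the canonical "any activator suffices unless repressed"
semantics.  The full table is documented in docs/regulation_conditions.md.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Tuple


class Level(enum.IntEnum):
    """Occupancy level of a regulator class (ordered)."""

    NONE = 0
    SOME = 1
    ALL = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


#: Canonical cell order of the 3x3 occupancy grid (activator-major).
GRID_CELLS: Tuple[Tuple[Level, Level], ...] = tuple(
    (a, r) for a in Level for r in Level
)

Table = Dict[Tuple[Level, Level], bool]


@dataclass(frozen=True)
class RegulationCondition:
    """One monotone, non-constant update template.

    ``index`` is the position in the canonical ordering (0..17); the
    ``table`` maps every grid cell to the component's next value.
    """

    index: int
    table: Table = field(hash=False)

    def __post_init__(self) -> None:
        if set(self.table) != set(GRID_CELLS):
            raise ValueError("regulation condition table must cover the 3x3 grid")
        if not is_monotone(self.table):
            raise ValueError("regulation condition table must be monotone")
        if is_constant(self.table):
            raise ValueError("regulation condition table must be non-constant")

    def __call__(self, activator_level: Level, repressor_level: Level) -> bool:
        return self.table[(activator_level, repressor_level)]

    def bits(self) -> Tuple[bool, ...]:
        """Truth table as a 9-tuple in canonical cell order."""
        return tuple(self.table[cell] for cell in GRID_CELLS)

    def __repr__(self) -> str:
        bitstring = "".join("1" if b else "0" for b in self.bits())
        return f"RegulationCondition({self.index}, {bitstring})"


def is_monotone(table: Table) -> bool:
    """Non-decreasing in activators, non-increasing in repressors."""
    for (a, r), value in table.items():
        if a < Level.ALL and value and not table[(Level(a + 1), r)]:
            return False
        if r < Level.ALL and table[(a, Level(r + 1))] and not value:
            return False
    return True


def is_constant(table: Table) -> bool:
    values = set(table.values())
    return len(values) == 1


def eq1_table() -> Table:
    """AllActivators(c,q) OR (NoRepressors(c,q) AND NOT NoActivators(c,q))."""
    return {
        (a, r): a == Level.ALL or (r == Level.NONE and a != Level.NONE)
        for a, r in GRID_CELLS
    }


@lru_cache(maxsize=1)
def enumerate_regulation_conditions() -> Tuple[RegulationCondition, ...]:
    """The 18 regulation conditions in the canonical order.

    Enumerates all 2^9 tables over the occupancy grid, keeps the
    monotone non-constant ones, sorts them by bitstring and pins the
    table of :func:`eq1_table` at index 5 by a single swap.
    """
    tables = []
    for bits in itertools.product((False, True), repeat=9):
        table = dict(zip(GRID_CELLS, bits))
        if is_monotone(table) and not is_constant(table):
            tables.append(table)
    assert len(tables) == 18
    tables.sort(key=lambda t: tuple(t[cell] for cell in GRID_CELLS))
    pinned = eq1_table()
    where = next(i for i, t in enumerate(tables) if t == pinned)
    tables[5], tables[where] = tables[where], tables[5]
    return tuple(
        RegulationCondition(index=i, table=table) for i, table in enumerate(tables)
    )


def condition(index: int) -> RegulationCondition:
    """Look up a regulation condition by canonical index (0..17)."""
    conditions = enumerate_regulation_conditions()
    if not 0 <= index < len(conditions):
        raise ValueError(f"regulation condition index out of range: {index}")
    return conditions[index]


def find_condition(table: Table) -> RegulationCondition:
    """Return the canonical condition with the given truth table."""
    for cond in enumerate_regulation_conditions():
        if cond.table == table:
            return cond
    raise ValueError("table is not monotone/non-constant")


def _semantic(name: str) -> RegulationCondition:
    predicates = {
        # At least one activator active and no repressor active.
        "some_activators_no_repressors": lambda a, r: a != Level.NONE
        and r == Level.NONE,
        # Every activator active (and at least one exists) regardless of
        # repressors.
        "all_activators": lambda a, r: a == Level.ALL,
        # No repressor active, activators ignored (maintains expression
        # by default; used e.g. for derepression-driven components).
        "no_repressors": lambda a, r: r == Level.NONE,
        # Every activator active and no repressor active.
        "all_activators_no_repressors": lambda a, r: a == Level.ALL
        and r == Level.NONE,
        # At least one activator active regardless of repressors.
        "some_activators": lambda a, r: a != Level.NONE,
    }
    pred = predicates[name]
    return find_condition({(a, r): pred(a, r) for a, r in GRID_CELLS})


@lru_cache(maxsize=None)
def semantic_index(name: str) -> int:
    """Canonical index of a commonly used template, by descriptive name.

    Recognised names: ``some_activators_no_repressors``,
    ``all_activators``, ``no_repressors``,
    ``all_activators_no_repressors``, ``some_activators``.
    """
    return _semantic(name).index


#: Index of the Eq-style "any activator suffices unless fully repressed"
#: template: AllActivators OR (NoRepressors AND NOT NoActivators).
CONDITION_DEFAULT = 5
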