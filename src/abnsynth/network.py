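"""Abstract Boolean Networks and their synchronous semantics.

An Abstract Boolean Network (ABN) bundles a set of named components, a
set of *definite* signed interactions, a set of *optional* signed
interactions, and a menu of admissible regulation conditions per
component.  Choosing a subset of the optional interactions and one
condition per component yields a :class:`ConcreteNetwork`, an ordinary
Boolean network updated synchronously: at every step each unclamped
component evaluates its assigned condition on the occupancy levels of
its effective activators and repressors.

Conventions (shared with the CNF encoding in :mod:`abnsynth.encoding`):

* a regulator class with zero effective members has level ``none``
  ("all members active" is never reported vacuously);
* a component with no effective incoming interactions and no clamp
  decays to inactive, so persistent inputs need an explicit self-loop;
* clamps (knockout / forced expression) override regulation at every
  step, including step 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .conditions import Level, RegulationCondition, condition

State = Dict[str, bool]
Trajectory = Tuple[State, ...]

ROLES = ("gene", "signal", "fate-readout")


@dataclass(frozen=True)
class Component:
    """A gene, signal or fate-readout node of the network."""

    name: str
    role: str = "gene"
    condition_menu: FrozenSet[int] = frozenset({5})

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("component name must be a non-empty string")
        if self.role not in ROLES:
            raise ValueError(f"unknown component role: {self.role!r}")
        menu = frozenset(self.condition_menu)
        if not menu:
            raise ValueError(f"component {self.name}: condition menu is empty")
        if not menu <= set(range(18)):
            raise ValueError(
                f"component {self.name}: condition menu must be a subset of 0..17"
            )
        object.__setattr__(self, "condition_menu", menu)


@dataclass(frozen=True)
class Interaction:
    """A signed directed interaction; ``sign`` True = activation."""

    source: str
    target: str
    sign: bool
    definite: bool = True

    @property
    def kind(self) -> str:
        return "activate" if self.sign else "repress"

    def __str__(self) -> str:
        arrow = "->" if self.sign else "-|"
        opt = "" if self.definite else " (optional)"
        return f"{self.source} {arrow} {self.target}{opt}"


class AbstractBooleanNetwork:
    """The tuple (components, definite edges, optional edges, menus)."""

    def __init__(
        self,
        components: Sequence[Component],
        interactions: Sequence[Interaction],
    ) -> None:
        self.components: Tuple[Component, ...] = tuple(components)
        self.interactions: Tuple[Interaction, ...] = tuple(interactions)
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        self._by_name = {c.name: c for c in self.components}
        seen = set()
        for inter in self.interactions:
            for endpoint in (inter.source, inter.target):
                if endpoint not in self._by_name:
                    raise ValueError(
                        f"interaction {inter} references unknown component "
                        f"{endpoint!r}"
                    )
            key = (inter.source, inter.target, inter.sign)
            if key in seen:
                raise ValueError(f"duplicate signed interaction: {inter}")
            seen.add(key)

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def component(self, name: str) -> Component:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown component: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def definite_interactions(self) -> Tuple[Interaction, ...]:
        return tuple(i for i in self.interactions if i.definite)

    @property
    def optional_interactions(self) -> Tuple[Interaction, ...]:
        return tuple(i for i in self.interactions if not i.definite)

    def incoming(self, name: str) -> Tuple[Interaction, ...]:
        return tuple(i for i in self.interactions if i.target == name)

    # -- sizes -----------------------------------------------------------
    @property
    def state_space_size(self) -> int:
        return 2 ** len(self.components)

    @property
    def model_space_size(self) -> int:
        """Number of concretizations: 2^|optional| * prod(menu sizes)."""
        size = 2 ** len(self.optional_interactions)
        for comp in self.components:
            size *= len(comp.condition_menu)
        return size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbstractBooleanNetwork):
            return NotImplemented
        return (
            self.components == other.components
            and self.interactions == other.interactions
        )

    def __repr__(self) -> str:
        return (
            f"AbstractBooleanNetwork({len(self.components)} components, "
            f"{len(self.definite_interactions)} definite + "
            f"{len(self.optional_interactions)} optional interactions)"
        )


class ConcreteNetwork:
    """A Boolean network drawn from an ABN.

    ``chosen_optional`` is the set of included optional interactions
    (identified by (source, target, sign) triples or Interaction
    objects); ``condition_assignment`` maps each component to a
    condition index from its menu.
    """

    def __init__(
        self,
        abn: AbstractBooleanNetwork,
        chosen_optional: Iterable[Interaction | Tuple[str, str, bool]],
        condition_assignment: Mapping[str, int],
    ) -> None:
        self.abn = abn
        optional_keys = {
            (i.source, i.target, i.sign): i for i in abn.optional_interactions
        }
        chosen: List[Interaction] = []
        for item in chosen_optional:
            key = (
                (item.source, item.target, item.sign)
                if isinstance(item, Interaction)
                else tuple(item)
            )
            if key not in optional_keys:
                raise ValueError(f"not an optional interaction of the ABN: {key}")
            chosen.append(optional_keys[key])
        self.chosen_optional: FrozenSet[Interaction] = frozenset(chosen)
        self.condition_assignment: Dict[str, int] = {}
        for comp in abn.components:
            try:
                index = condition_assignment[comp.name]
            except KeyError:
                raise ValueError(
                    f"no condition assigned to component {comp.name}"
                ) from None
            if index not in comp.condition_menu:
                raise ValueError(
                    f"condition {index} not in menu of component {comp.name}"
                )
            self.condition_assignment[comp.name] = index
        # Effective regulator lists, precomputed for the simulator.
        self._activators: Dict[str, Tuple[str, ...]] = {}
        self._repressors: Dict[str, Tuple[str, ...]] = {}
        for comp in abn.components:
            acts, reps = [], []
            for inter in abn.incoming(comp.name):
                if inter.definite or inter in self.chosen_optional:
                    (acts if inter.sign else reps).append(inter.source)
            self._activators[comp.name] = tuple(acts)
            self._repressors[comp.name] = tuple(reps)

    @property
    def effective_interactions(self) -> Tuple[Interaction, ...]:
        return tuple(
            i
            for i in self.abn.interactions
            if i.definite or i in self.chosen_optional
        )

    def activators_of(self, name: str) -> Tuple[str, ...]:
        return self._activators[name]

    def repressors_of(self, name: str) -> Tuple[str, ...]:
        return self._repressors[name]

    def condition_of(self, name: str) -> RegulationCondition:
        return condition(self.condition_assignment[name])

    def key(self) -> Tuple:
        """Canonical hashable identity (optional choice + assignment)."""
        chosen = tuple(
            sorted((i.source, i.target, i.sign) for i in self.chosen_optional)
        )
        assignment = tuple(sorted(self.condition_assignment.items()))
        return (chosen, assignment)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcreteNetwork):
            return NotImplemented
        return self.abn == other.abn and self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __repr__(self) -> str:
        return (
            f"ConcreteNetwork({len(self.chosen_optional)}/"
            f"{len(self.abn.optional_interactions)} optional interactions chosen)"
        )


# ---------------------------------------------------------------------------
# Synchronous semantics
# ---------------------------------------------------------------------------

def _occupancy(active: Sequence[bool]) -> Level:
    """Occupancy level of one regulator class; empty class -> none."""
    if not active or not any(active):
        return Level.NONE
    if all(active):
        return Level.ALL
    return Level.SOME


def classify_regulators(
    net: ConcreteNetwork, component: str, state: Mapping[str, bool]
) -> Tuple[Level, Level]:
    """Occupancy levels of a component's effective activators/repressors."""
    if component not in net.abn:
        raise KeyError(f"unknown component: {component!r}")
    acts = [state[g] for g in net.activators_of(component)]
    reps = [state[g] for g in net.repressors_of(component)]
    return _occupancy(acts), _occupancy(reps)


def evaluate_regulation(
    cond: RegulationCondition, levels: Tuple[Level, Level]
) -> bool:
    """Look up a condition table at an occupancy-grid cell."""
    return cond(*levels)


def synchronous_step(
    net: ConcreteNetwork,
    state: Mapping[str, bool],
    clamps: Optional[Mapping[str, bool]] = None,
) -> State:
    """One synchronous update; clamped components take their clamp value."""
    clamps = clamps or {}
    for name in clamps:
        if name not in net.abn:
            raise KeyError(f"clamp names unknown component: {name!r}")
    nxt: State = {}
    for comp in net.abn.components:
        name = comp.name
        if name in clamps:
            nxt[name] = bool(clamps[name])
            continue
        if not net.activators_of(name) and not net.repressors_of(name):
            nxt[name] = False
            continue
        levels = classify_regulators(net, name, state)
        nxt[name] = net.condition_of(name)(*levels)
    return nxt


def simulate(
    net: ConcreteNetwork,
    initial: Mapping[str, bool],
    length: int,
    clamps: Optional[Mapping[str, bool]] = None,
) -> Trajectory:
    """Deterministic synchronous trajectory of ``length`` states.

    The first state is ``initial`` with clamps applied; each successor
    comes from :func:`synchronous_step` under the same clamps.
    """
    if length < 1:
        raise ValueError("trajectory length must be >= 1")
    clamps = dict(clamps or {})
    for name in clamps:
        if name not in net.abn:
            raise KeyError(f"clamp names unknown component: {name!r}")
    missing = set(net.abn.names) - set(initial)
    if missing:
        raise ValueError(f"initial state misses components: {sorted(missing)}")
    state: State = {name: bool(initial[name]) for name in net.abn.names}
    state.update({k: bool(v) for k, v in clamps.items()})
    states = [state]
    for _ in range(length - 1):
        states.append(synchronous_step(net, states[-1], clamps))
    return tuple(states)
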