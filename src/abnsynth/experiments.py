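"""Experiments: perturbations plus timed Boolean observation constraints.

An experiment is a bounded scenario of ``length`` synchronous steps: a
set of knockout (KO) / forced-expression (FE) clamps applied at every
step, and a set of observation constraints, each pinning one component
to one Boolean value at one time step.  Constraints carry a *role* tag:

``initial``
    pins part of the starting state (step 0);
``intermediate``
    a mid-course observation or an input-signal specification;
``outcome``
    the phenotypic readout — the constraints that are value-flipped by
    :func:`negate_outcome` when testing the null hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Tuple

from .network import Trajectory

KO = "KO"
FE = "FE"
ROLES = ("initial", "intermediate", "outcome")


@dataclass(frozen=True)
class Perturbation:
    """A per-experiment clamp: KO (always off) or FE (always on)."""

    component: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in (KO, FE):
            raise ValueError(f"perturbation mode must be KO or FE, got {self.mode!r}")

    @property
    def value(self) -> bool:
        return self.mode == FE


@dataclass(frozen=True)
class ObservationConstraint:
    """One timed Boolean predicate: component == value at step ``time``."""

    time: int
    component: str
    value: bool
    role: str = "intermediate"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("constraint time must be >= 0")
        if self.role not in ROLES:
            raise ValueError(f"unknown constraint role: {self.role!r}")


@dataclass(frozen=True)
class Experiment:
    """A labelled scenario: length, perturbations and constraints."""

    label: str
    length: int
    perturbations: FrozenSet[Perturbation] = frozenset()
    constraints: FrozenSet[ObservationConstraint] = frozenset()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("experiment length must be >= 1")
        object.__setattr__(self, "perturbations", frozenset(self.perturbations))
        object.__setattr__(self, "constraints", frozenset(self.constraints))
        modes: Dict[str, str] = {}
        for pert in self.perturbations:
            if modes.setdefault(pert.component, pert.mode) != pert.mode:
                raise ValueError(
                    f"experiment {self.label}: conflicting KO and FE on "
                    f"{pert.component}"
                )
        for constraint in self.constraints:
            if constraint.time >= self.length:
                raise ValueError(
                    f"experiment {self.label}: constraint at step "
                    f"{constraint.time} >= length {self.length}"
                )
            mode = modes.get(constraint.component)
            if mode is not None and constraint.value != (mode == FE):
                raise ValueError(
                    f"experiment {self.label}: {constraint.component} is "
                    f"{mode} but constrained to {constraint.value}"
                )

    @property
    def outcome_constraints(self) -> Tuple[ObservationConstraint, ...]:
        return tuple(c for c in self.constraints if c.role == "outcome")

    def initial_values(self) -> Dict[str, bool]:
        """Step-0 values pinned by initial-role constraints."""
        return {
            c.component: c.value
            for c in self.constraints
            if c.time == 0 and c.role == "initial"
        }


@dataclass(frozen=True)
class ExperimentSuite:
    """An ordered collection of uniquely labelled experiments."""

    experiments: Tuple[Experiment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiments", tuple(self.experiments))
        labels = [e.label for e in self.experiments]
        if len(set(labels)) != len(labels):
            raise ValueError("experiment labels must be unique")

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    def experiment(self, label: str) -> Experiment:
        for exp in self.experiments:
            if exp.label == label:
                return exp
        raise KeyError(f"unknown experiment label: {label!r}")

    def labels(self) -> Tuple[str, ...]:
        return tuple(e.label for e in self.experiments)

    def replace_experiment(self, exp: Experiment) -> "ExperimentSuite":
        return ExperimentSuite(
            tuple(exp if e.label == exp.label else e for e in self.experiments)
        )


def compile_perturbations(exp: Experiment) -> Dict[str, bool]:
    """Clamp mapping for an experiment: KO -> False, FE -> True."""
    return {p.component: p.value for p in exp.perturbations}


def trajectory_satisfies(traj: Trajectory, exp: Experiment) -> bool:
    """True iff every observation constraint holds at its step."""
    if len(traj) != exp.length:
        raise ValueError(
            f"trajectory length {len(traj)} != experiment length {exp.length}"
        )
    return all(traj[c.time][c.component] == c.value for c in exp.constraints)


def negate_outcome(exp: Experiment) -> Experiment:
    """Flip every outcome-role constraint's value (the null hypothesis).

    Initial and intermediate constraints and the perturbations are kept
    unchanged; applying the function twice returns the original
    experiment.
    """
    if not exp.outcome_constraints:
        raise ValueError(f"experiment {exp.label} has no outcome constraints")
    flipped = frozenset(
        replace(c, value=not c.value) if c.role == "outcome" else c
        for c in exp.constraints
    )
    return replace(exp, constraints=flipped)
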