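"""Synthetic fixtures: random ABNs with a planted concrete network.

The generator emulates the structure of a real study: a random abstract
network (definite and optional signed interactions, per-component
condition menus), a hidden concretization planted inside it, and an
experiment suite whose observation constraints are sampled from
trajectories simulated under the hidden network — so the hidden network
satisfies the suite by construction and synthesis must recover it (or an
observationally equivalent sibling).

All randomness flows through one ``random.Random`` instance seeded from
``FixtureSpec.seed``, so fixtures are bit-for-bit reproducible.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .experiments import (
    FE,
    KO,
    Experiment,
    ExperimentSuite,
    ObservationConstraint,
    Perturbation,
)
from .network import (
    AbstractBooleanNetwork,
    Component,
    ConcreteNetwork,
    Interaction,
    simulate,
)
from .experiments import compile_perturbations


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic problem instance."""

    seed: int
    n_components: int = 5
    n_definite: int = 6
    n_optional: int = 3
    menu_size: int = 2
    n_experiments: int = 3
    length: int = 8
    observed_fraction: float = 0.6
    perturbation_probability: float = 0.25

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one component")
        if not 1 <= self.menu_size <= 18:
            raise ValueError("menu size must be in 1..18")
        if not 0 < self.observed_fraction <= 1:
            raise ValueError("observed fraction must be in (0, 1]")
        if self.length < 2:
            raise ValueError("experiments need at least 2 steps")
        limit = self.n_components ** 2
        if self.n_definite + self.n_optional > limit:
            raise ValueError(
                f"cannot place {self.n_definite}+{self.n_optional} edges "
                f"among {limit} ordered component pairs"
            )


def random_abn(spec: FixtureSpec) -> AbstractBooleanNetwork:
    """A reproducible random ABN; self-loops allowed, signs balanced.

    At most one signed edge is placed per ordered component pair, so a
    regulator is never simultaneously an activator and a repressor of
    the same target (which would defeat the monotonicity of the update
    templates).
    """
    rng = random.Random(spec.seed)
    names = [f"g{i}" for i in range(spec.n_components)]
    components = [
        Component(
            name=name,
            condition_menu=frozenset(rng.sample(range(18), spec.menu_size)),
        )
        for name in names
    ]
    pairs = list(itertools.product(names, names))
    picked = rng.sample(pairs, spec.n_definite + spec.n_optional)
    interactions = [
        Interaction(s, t, rng.random() < 0.5, definite=(i < spec.n_definite))
        for i, (s, t) in enumerate(picked)
    ]
    return AbstractBooleanNetwork(components, interactions)


def plant_concretization(
    spec: FixtureSpec, abn: AbstractBooleanNetwork
) -> ConcreteNetwork:
    """Sample the hidden concrete network (seeded independently of topology)."""
    rng = random.Random(spec.seed * 2 + 1)
    chosen = [i for i in abn.optional_interactions if rng.random() < 0.5]
    assignment = {
        c.name: rng.choice(sorted(c.condition_menu)) for c in abn.components
    }
    return ConcreteNetwork(abn, chosen, assignment)


def plant_and_observe(
    spec: FixtureSpec, abn: AbstractBooleanNetwork
) -> Tuple[ConcreteNetwork, ExperimentSuite]:
    """Hidden network plus a suite of observations simulated from it.

    Constraints are sampled at ``observed_fraction`` of the (step,
    component) grid; perturbed components are never observation-
    constrained.  Each experiment keeps at least one final-step
    (outcome-role) constraint so null-hypothesis machinery stays
    applicable.
    """
    hidden = plant_concretization(spec, abn)
    rng = random.Random(spec.seed * 2 + 2)
    experiments: List[Experiment] = []
    for e in range(spec.n_experiments):
        perturbations = frozenset()
        if rng.random() < spec.perturbation_probability:
            component = rng.choice(abn.names)
            perturbations = frozenset(
                {Perturbation(component, rng.choice((KO, FE)))}
            )
        clamps = compile_perturbations(
            Experiment(f"tmp", spec.length, perturbations, frozenset())
        )
        initial = {name: rng.random() < 0.5 for name in abn.names}
        traj = simulate(hidden, initial, spec.length, clamps)
        constraints: List[ObservationConstraint] = []
        observable = [n for n in abn.names if n not in clamps]
        for t in range(spec.length):
            role = (
                "initial"
                if t == 0
                else "outcome"
                if t == spec.length - 1
                else "intermediate"
            )
            for name in observable:
                if rng.random() < spec.observed_fraction:
                    constraints.append(
                        ObservationConstraint(t, name, traj[t][name], role=role)
                    )
        if not any(c.role == "outcome" for c in constraints) and observable:
            name = observable[0]
            constraints.append(
                ObservationConstraint(
                    spec.length - 1, name, traj[spec.length - 1][name], "outcome"
                )
            )
        experiments.append(
            Experiment(
                label=f"exp{e}",
                length=spec.length,
                perturbations=perturbations,
                constraints=frozenset(constraints),
            )
        )
    return hidden, ExperimentSuite(tuple(experiments))


def fully_observed_spec(seed: int, n_components: int = 4) -> FixtureSpec:
    """A rigid instance: no optional edges, singleton menus, all observed."""
    return FixtureSpec(
        seed=seed,
        n_components=n_components,
        n_definite=n_components + 2,
        n_optional=0,
        menu_size=1,
        n_experiments=2,
        length=6,
        observed_fraction=1.0,
        perturbation_probability=0.0,
    )
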