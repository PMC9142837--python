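"""The packaged C. elegans germline stem-cell ABN and experiment suites.

The core network has 24 components and 40 signed interactions covering
GLP-1 Notch signaling from the distal tip cell (DTC) through the
LST-1/SYGL-1 effectors and the FBF-1 two-state (bound/unbound) switch,
down to the three meiotic-entry pathways (GLD-1, GLD-2, SCF^PROM-1^,
plus the meiotic chromosome axis/SC proteins) and the two fate readouts
StemcellFate and MeioticDev.  Interactions with strong experimental
support are definite; redundant or hypothesized routes (the GLD-1
accumulation inputs, the SCF^PROM-1^/axis-SC repression routes and the
fate-readout wiring) are optional.  The full edge-by-edge provenance is
documented in docs/germline_network.md.

Three experimental setups differ in the DTC input signal:

``niche``
    constitutive DTC signal, sustained by a self-activating auxiliary
    signal S0; wild-type outcome is stem-cell fate;
``losing``
    a cell moving proximally: DTC on at step 0 and driven for a few
    steps by a decaying relay of auxiliary signals S1-S3, off by step
    20; wild-type outcome is meiotic entry;
``reduced``
    DTC active at step 0 only, plus a self-degrading auxiliary signal
    that transiently represses CYE-1/CDK-2; wild-type outcome is
    meiotic entry.

Each setup's suite holds the wild-type experiment plus the eight
knockout / forced-expression scenarios with their published phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

from .conditions import semantic_index
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
)

SETUPS = ("niche", "losing", "reduced")

#: Experiment length: states 0..20, so "after 20 steps" is state index 20.
EXPERIMENT_LENGTH = 21

#: The two steady final steps used to pin outcome fixpoints.
OUTCOME_STEPS = (19, 20)

# Condition shorthand (canonical indices, resolved by semantics).
_SOME = semantic_index("some_activators_no_repressors")
_NOREP = semantic_index("no_repressors")
_ALL = semantic_index("all_activators_no_repressors")
_REDUNDANT = 5  # AllActivators or (NoRepressors and some activator)

_CORE_COMPONENTS: Tuple[Tuple[str, str, Tuple[int, ...]], ...] = (
    ("DTC", "signal", (_SOME,)),
    ("LAG2", "gene", (_SOME,)),
    ("APX1", "gene", (_SOME,)),
    ("GLP1", "gene", (_REDUNDANT,)),
    ("GLP1ICD", "gene", (_REDUNDANT,)),
    ("SEL8", "gene", (_SOME,)),
    ("LAG1", "gene", (_REDUNDANT,)),
    ("HOP1", "gene", (_SOME,)),
    ("SEL12", "gene", (_REDUNDANT,)),
    ("SEL10", "gene", (_SOME,)),
    ("LST1", "gene", (_SOME,)),
    ("SYGL1", "gene", (_SOME,)),
    ("FBF1B", "gene", (_REDUNDANT,)),
    ("FBF1U", "gene", (_NOREP,)),
    ("FBF2", "gene", (_SOME,)),
    ("GLD1", "gene", (_SOME,)),
    ("GLD2", "gene", (_SOME,)),
    ("GLD3", "gene", (_SOME,)),
    ("NOS3", "gene", (_SOME,)),
    ("SCF_PROM1", "gene", (_NOREP,)),
    ("AXIS_SC", "gene", (_NOREP,)),
    ("CYE1_CDK2", "gene", (_NOREP,)),
    ("StemcellFate", "fate-readout", (_SOME,)),
    ("MeioticDev", "fate-readout", (_SOME, _ALL)),
)

# (source, target, sign, definite); True sign = activation.
_CORE_INTERACTIONS: Tuple[Tuple[str, str, bool, bool], ...] = (
    ("DTC", "APX1", True, True),
    ("DTC", "LAG2", True, True),
    ("LAG2", "GLP1", True, True),
    ("APX1", "GLP1", True, True),
    ("GLP1", "GLP1ICD", True, True),
    ("GLP1ICD", "SEL8", True, True),
    ("GLP1ICD", "LAG1", True, True),
    ("SEL8", "LAG1", True, True),
    ("GLP1", "HOP1", True, True),
    ("HOP1", "GLP1ICD", True, True),
    ("GLP1", "SEL12", True, True),
    ("SEL12", "GLP1ICD", True, True),
    ("SEL10", "GLP1ICD", False, True),
    ("SEL10", "SEL12", False, True),
    ("LAG1", "LST1", True, True),
    ("LAG1", "SYGL1", True, True),
    ("LST1", "GLD1", False, True),
    # Two-state FBF-1: LST-1/SYGL-1 binding drives FBF-1 into the bound
    # state (FBF1B) and out of the unbound state (FBF1U).
    ("LST1", "FBF1B", True, True),
    ("LST1", "FBF1U", False, True),
    ("SYGL1", "FBF1B", True, True),
    ("SYGL1", "FBF1U", False, True),
    ("FBF1B", "GLD1", False, True),
    ("LAG1", "FBF2", True, True),
    ("FBF2", "GLD1", False, True),
    ("FBF1U", "GLD3", True, True),
    ("FBF1B", "GLD3", False, True),
    ("FBF2", "GLD3", False, True),
    ("GLD3", "GLD2", True, True),
    ("SCF_PROM1", "CYE1_CDK2", False, True),
    # Fate readout wiring.
    ("GLD1", "MeioticDev", True, True),
    ("GLD2", "MeioticDev", True, True),
    ("CYE1_CDK2", "StemcellFate", True, True),
    # Optional: redundant GLD-1 accumulation inputs, the hypothesized
    # SCF^PROM-1^/axis-SC repression routes and fate wiring.
    ("NOS3", "GLD1", True, False),
    ("GLD2", "GLD1", True, False),
    ("FBF1B", "SCF_PROM1", False, False),
    ("FBF1B", "AXIS_SC", False, False),
    ("FBF2", "AXIS_SC", False, False),
    ("SCF_PROM1", "MeioticDev", True, False),
    ("AXIS_SC", "MeioticDev", True, False),
    ("MeioticDev", "StemcellFate", False, False),
)

#: Published phenotypes of the in-silico perturbation experiments.
PERTURBATION_OUTCOMES: Dict[str, Tuple[Tuple[Tuple[str, str], ...], str]] = {
    "glp1_ko": ((("GLP1", KO),), "meiotic_entry"),
    "lst1_ko": ((("LST1", KO),), "no_effect"),
    "sygl1_ko": ((("SYGL1", KO),), "no_effect"),
    "lst1_sygl1_ko": ((("LST1", KO), ("SYGL1", KO)), "meiotic_entry"),
    "gld1_gld2_ko": ((("GLD1", KO), ("GLD2", KO)), "meiosis_failure"),
    "glp1_fe": ((("GLP1", FE),), "meiosis_failure"),
    "lst1_fe": ((("LST1", FE),), "meiosis_failure"),
    "sygl1_fe": ((("SYGL1", FE),), "meiosis_failure"),
}

PERTURBATION_ORDER = tuple(PERTURBATION_OUTCOMES)


def build_germline_abn() -> AbstractBooleanNetwork:
    """The core 24-component, 40-interaction germline ABN."""
    components = [
        Component(name=name, role=role, condition_menu=frozenset(menu))
        for name, role, menu in _CORE_COMPONENTS
    ]
    interactions = [
        Interaction(source=s, target=t, sign=sign, definite=definite)
        for s, t, sign, definite in _CORE_INTERACTIONS
    ]
    return AbstractBooleanNetwork(components, interactions)


def build_setup_abn(setup: str) -> AbstractBooleanNetwork:
    """The core ABN augmented with the setup's auxiliary input signals."""
    if setup not in SETUPS:
        raise ValueError(f"unknown setup: {setup!r}")
    core = build_germline_abn()
    components = list(core.components)
    interactions = list(core.interactions)
    if setup == "niche":
        components.append(
            Component("S0", role="signal", condition_menu=frozenset({_SOME}))
        )
        interactions += [
            Interaction("S0", "S0", True, True),  # self-sustaining niche signal
            Interaction("S0", "DTC", True, True),
        ]
    elif setup == "losing":
        for name in ("S1", "S2", "S3"):
            components.append(
                Component(name, role="signal", condition_menu=frozenset({_SOME}))
            )
        interactions += [
            Interaction("S1", "S2", True, True),
            Interaction("S2", "S3", True, True),
            Interaction("S1", "DTC", True, True),
            Interaction("S2", "DTC", True, True),
            Interaction("S3", "DTC", True, True),
        ]
    else:  # reduced
        components.append(
            Component("SD", role="signal", condition_menu=frozenset({_SOME}))
        )
        interactions.append(Interaction("SD", "CYE1_CDK2", False, True))
    return AbstractBooleanNetwork(components, interactions)


def _initial_constraints(
    abn: AbstractBooleanNetwork, setup: str, perturbed: Iterable[str]
) -> Tuple[ObservationConstraint, ...]:
    """Pin the full step-0 state (perturbed components are clamped)."""
    on_at_start = {"DTC"}
    if setup == "niche":
        on_at_start.add("S0")
    elif setup == "losing":
        on_at_start.add("S1")
    else:
        on_at_start.add("SD")
    perturbed = set(perturbed)
    return tuple(
        ObservationConstraint(0, name, name in on_at_start, role="initial")
        for name in abn.names
        if name not in perturbed
    )


def _outcome_constraints(kind: str, setup: str) -> Tuple[ObservationConstraint, ...]:
    wild_type_stem = setup == "niche"
    if kind == "no_effect":
        kind = "stem_cell" if wild_type_stem else "meiotic_entry"
    constraints = []
    for step in OUTCOME_STEPS:
        if kind == "stem_cell":
            constraints.append(
                ObservationConstraint(step, "StemcellFate", True, role="outcome")
            )
            constraints.append(
                ObservationConstraint(step, "MeioticDev", False, role="outcome")
            )
        elif kind == "meiotic_entry":
            constraints.append(
                ObservationConstraint(step, "MeioticDev", True, role="outcome")
            )
            constraints.append(
                ObservationConstraint(step, "StemcellFate", False, role="outcome")
            )
        elif kind == "meiosis_failure":
            constraints.append(
                ObservationConstraint(step, "MeioticDev", False, role="outcome")
            )
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown outcome kind: {kind!r}")
    return tuple(constraints)


def _setup_constraints(setup: str) -> Tuple[ObservationConstraint, ...]:
    if setup == "losing":
        # The cell has moved out of DTC range by the end of the scenario.
        return (ObservationConstraint(20, "DTC", False, role="intermediate"),)
    return ()


def build_experiment_suite(
    setup: str,
    perturbation_set: Optional[Iterable[str]] = None,
) -> ExperimentSuite:
    """Wild type plus the requested perturbation experiments for a setup.

    ``perturbation_set`` names rows of :data:`PERTURBATION_OUTCOMES`;
    None selects all eight.
    """
    if setup not in SETUPS:
        raise ValueError(f"unknown setup: {setup!r}")
    abn = build_setup_abn(setup)
    requested = (
        tuple(PERTURBATION_ORDER)
        if perturbation_set is None
        else tuple(perturbation_set)
    )
    for label in requested:
        if label not in PERTURBATION_OUTCOMES:
            raise ValueError(f"unknown perturbation experiment: {label!r}")
    wild_type_kind = "stem_cell" if setup == "niche" else "meiotic_entry"
    experiments = [
        Experiment(
            label="wild_type",
            length=EXPERIMENT_LENGTH,
            perturbations=frozenset(),
            constraints=frozenset(
                _initial_constraints(abn, setup, ())
                + _setup_constraints(setup)
                + _outcome_constraints(wild_type_kind, setup)
            ),
        )
    ]
    for label in requested:
        perts, kind = PERTURBATION_OUTCOMES[label]
        perturbations = frozenset(Perturbation(c, m) for c, m in perts)
        perturbed = [p.component for p in perturbations]
        experiments.append(
            Experiment(
                label=label,
                length=EXPERIMENT_LENGTH,
                perturbations=perturbations,
                constraints=frozenset(
                    _initial_constraints(abn, setup, perturbed)
                    + _setup_constraints(setup)
                    + _outcome_constraints(kind, setup)
                ),
            )
        )
    return ExperimentSuite(tuple(experiments))


@dataclass(frozen=True)
class GermlineCatalog:
    """Core ABN plus per-setup augmented ABNs and experiment suites."""

    abn: AbstractBooleanNetwork
    setup_abns: Dict[str, AbstractBooleanNetwork]
    suites: Dict[str, ExperimentSuite]


def germline_catalog() -> GermlineCatalog:
    return GermlineCatalog(
        abn=build_germline_abn(),
        setup_abns={setup: build_setup_abn(setup) for setup in SETUPS},
        suites={setup: build_experiment_suite(setup) for setup in SETUPS},
    )


def reference_concretization(setup: str = "niche") -> ConcreteNetwork:
    """A hand-picked consistent model for a setup (checked in tests).

    In the niche model the SCF^PROM-1^ meiotic route is wired into
    MeioticDev and kept in check by FBF-1B; in the losing/reduced models
    the optional meiotic-entry routes into MeioticDev are left out, so
    the gld-1 gld-2 double knockout shows the published meiotic-entry
    failure.
    """
    abn = build_setup_abn(setup)
    chosen = [
        ("GLD2", "GLD1", True),
        ("FBF1B", "SCF_PROM1", False),
        ("FBF1B", "AXIS_SC", False),
        ("MeioticDev", "StemcellFate", False),
    ]
    if setup == "niche":
        chosen.append(("SCF_PROM1", "MeioticDev", True))
    assignment = {}
    for comp in abn.components:
        menu = sorted(comp.condition_menu)
        assignment[comp.name] = _SOME if comp.name == "MeioticDev" else menu[0]
    return ConcreteNetwork(abn, chosen, assignment)


def network_summary(abn: AbstractBooleanNetwork) -> Dict[str, int]:
    """Structural counts of an ABN."""
    return {
        "components": len(abn.components),
        "definite_interactions": len(abn.definite_interactions),
        "optional_interactions": len(abn.optional_interactions),
        "interactions": len(abn.interactions),
        "state_space_size": abn.state_space_size,
        "model_space_size": abn.model_space_size,
    }
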