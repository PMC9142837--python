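"""Synthesis: find concrete networks consistent with all experiments.

``solve``/``enumerate_solutions`` run the CNF encoding through the CDCL
backend and verify every returned model by independent simulation;
``brute_force_synthesize`` exhaustively enumerates concretizations and is
used as the oracle in tests; ``test_null_hypothesis`` re-solves with one
experiment's outcome constraints negated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from .encoding import ProblemEncoding
from .experiments import (
    Experiment,
    ExperimentSuite,
    compile_perturbations,
    negate_outcome,
    trajectory_satisfies,
)
from .network import (
    AbstractBooleanNetwork,
    ConcreteNetwork,
    Trajectory,
    simulate,
)

SAT = "SAT"
UNSAT = "UNSAT"

#: Cap on the exhaustive search over free initial values per experiment.
MAX_FREE_INITIAL_COMBINATIONS = 2 ** 20

#: Cap on the concretization space brute force will enumerate.
MAX_BRUTE_FORCE_SPACE = 10 ** 6


class SynthesisBackendError(RuntimeError):
    """Internal inconsistency of the solver backend (never plain UNSAT)."""


@dataclass(frozen=True)
class SolveOptions:
    solution_limit: int = 1
    length_override: Optional[int] = None
    seed: int = 0


@dataclass(frozen=True)
class SynthesisProblem:
    abn: AbstractBooleanNetwork
    suite: ExperimentSuite
    options: SolveOptions = field(default_factory=SolveOptions)

    def effective_suite(self) -> ExperimentSuite:
        override = self.options.length_override
        if override is None:
            return self.suite
        experiments = []
        for exp in self.suite:
            max_time = max((c.time for c in exp.constraints), default=-1)
            if override <= max_time:
                raise ValueError(
                    f"length override {override} clips constraints of "
                    f"experiment {exp.label}"
                )
            experiments.append(replace(exp, length=override))
        return ExperimentSuite(tuple(experiments))


@dataclass(frozen=True)
class SolutionModel:
    network: ConcreteNetwork
    witnesses: Dict[str, Trajectory]


@dataclass(frozen=True)
class SynthesisResult:
    status: str
    models: Tuple[SolutionModel, ...]
    exhaustive: bool

    @property
    def is_sat(self) -> bool:
        return self.status == SAT


# ---------------------------------------------------------------------------
# Simulation-based verification
# ---------------------------------------------------------------------------

def _witness_for_experiment(
    net: ConcreteNetwork, exp: Experiment
) -> Optional[Trajectory]:
    """A satisfying trajectory, searching free initial values exhaustively."""
    clamps = compile_perturbations(exp)
    for name in clamps:
        if name not in net.abn:
            raise ValueError(f"perturbation names unknown component: {name!r}")
    pinned = {c.component: c.value for c in exp.constraints if c.time == 0}
    free = [
        c.name
        for c in net.abn.components
        if c.name not in clamps and c.name not in pinned
    ]
    if 2 ** len(free) > MAX_FREE_INITIAL_COMBINATIONS:
        raise ValueError(
            f"experiment {exp.label}: {len(free)} free initial values exceed "
            f"the exhaustive-search bound"
        )
    base = {name: False for name in net.abn.names}
    base.update(pinned)
    for bits in itertools.product((False, True), repeat=len(free)):
        initial = dict(base)
        initial.update(zip(free, bits))
        traj = simulate(net, initial, exp.length, clamps)
        if trajectory_satisfies(traj, exp):
            return traj
    return None


def find_witnesses(
    net: ConcreteNetwork, suite: ExperimentSuite
) -> Optional[Dict[str, Trajectory]]:
    """Per-experiment witnesses, or None if some experiment fails."""
    witnesses: Dict[str, Trajectory] = {}
    for exp in suite:
        traj = _witness_for_experiment(net, exp)
        if traj is None:
            return None
        witnesses[exp.label] = traj
    return witnesses


def verify_model(net: ConcreteNetwork, suite: ExperimentSuite) -> bool:
    """True iff the network satisfies every experiment of the suite."""
    return find_witnesses(net, suite) is not None


# ---------------------------------------------------------------------------
# SAT-backed synthesis
# ---------------------------------------------------------------------------

def _decode_solution(
    encoding: ProblemEncoding,
    suite: ExperimentSuite,
    model: Dict[int, bool],
) -> SolutionModel:
    chosen, assignment = encoding.decode_choices(model)
    net = ConcreteNetwork(encoding.abn, chosen, assignment)
    witnesses: Dict[str, Trajectory] = {}
    for exp in suite:
        initial = encoding.decode_initial_state(exp, model)
        traj = simulate(net, initial, exp.length, compile_perturbations(exp))
        if not trajectory_satisfies(traj, exp):
            raise SynthesisBackendError(
                f"solver model fails re-simulation of experiment {exp.label}"
            )
        witnesses[exp.label] = traj
    return SolutionModel(network=net, witnesses=witnesses)


def enumerate_solutions(
    problem: SynthesisProblem, limit: Optional[int] = None
) -> SynthesisResult:
    """Up to ``limit`` distinct concretizations consistent with the suite.

    Distinctness is by optional-edge subset and condition assignment;
    found choices are blocked and the search repeats.  ``exhaustive`` is
    True when the whole choice space was covered.
    """
    if limit is None:
        limit = problem.options.solution_limit
    if limit < 1:
        raise ValueError("solution limit must be >= 1")
    suite = problem.effective_suite()
    encoding = ProblemEncoding(problem.abn, suite)
    models: List[SolutionModel] = []
    exhaustive = False
    while True:
        assignment = encoding.solver.solve()
        if assignment is None:
            exhaustive = True
            break
        models.append(_decode_solution(encoding, suite, assignment))
        if len(models) >= limit:
            break
        blocking = [-lit for lit in encoding.choice_literals(assignment)]
        if not blocking:
            exhaustive = True
            break
        encoding.solver.add_clause(blocking)
    status = SAT if models else UNSAT
    return SynthesisResult(
        status=status, models=tuple(models), exhaustive=exhaustive
    )


def solve(problem: SynthesisProblem) -> SynthesisResult:
    """Decide the synthesis problem; SAT results carry verified models."""
    return enumerate_solutions(problem, limit=problem.options.solution_limit)


def brute_force_synthesize(problem: SynthesisProblem) -> SynthesisResult:
    """Oracle: enumerate every concretization and verify it by simulation."""
    abn = problem.abn
    suite = problem.effective_suite()
    if abn.model_space_size > MAX_BRUTE_FORCE_SPACE:
        raise ValueError(
            f"concrete-model space {abn.model_space_size} too large for "
            f"brute force"
        )
    optional = abn.optional_interactions
    menus = [sorted(c.condition_menu) for c in abn.components]
    names = abn.names
    models: List[SolutionModel] = []
    for r in range(len(optional) + 1):
        for subset in itertools.combinations(optional, r):
            for choice in itertools.product(*menus):
                net = ConcreteNetwork(abn, subset, dict(zip(names, choice)))
                witnesses = find_witnesses(net, suite)
                if witnesses is not None:
                    models.append(SolutionModel(net, witnesses))
    status = SAT if models else UNSAT
    return SynthesisResult(status=status, models=tuple(models), exhaustive=True)


def test_null_hypothesis(
    problem: SynthesisProblem,
    experiment_label: str,
    isolate: bool = False,
    limit: Optional[int] = None,
) -> SynthesisResult:
    """Re-solve with one experiment's outcome constraints negated.

    SAT means some consistent network realizes the opposite outcome.  By
    default the other experiments' constraints are retained; with
    ``isolate`` the negated experiment is solved on its own.
    """
    flipped = negate_outcome(problem.suite.experiment(experiment_label))
    if isolate:
        suite = ExperimentSuite((flipped,))
    else:
        suite = problem.suite.replace_experiment(flipped)
    return solve(replace(problem, suite=suite)) if limit is None else (
        enumerate_solutions(replace(problem, suite=suite), limit=limit)
    )
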