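"""The synthesis engine: solve / enumerate / verify / null hypothesis."""

import pytest

from abnsynth.conditions import semantic_index
from abnsynth.experiments import (
    Experiment,
    ExperimentSuite,
    ObservationConstraint,
)
from abnsynth.fixtures import FixtureSpec, plant_and_observe, random_abn
from abnsynth.network import ConcreteNetwork
from abnsynth.synthesis import (
    SolveOptions,
    SynthesisProblem,
    brute_force_synthesize,
    enumerate_solutions,
    solve,
    verify_model,
)
from abnsynth.synthesis import test_null_hypothesis as null_hypothesis
from conftest import make_abn

SOME = semantic_index("some_activators_no_repressors")
SOME_ANY = semantic_index("some_activators")


def obs(time, component, value, role="intermediate"):
    return ObservationConstraint(time, component, value, role)


@pytest.fixture
def repression_toy():
    """A self-sustaining repressor A -| B with B on the redundancy
    template: while A is active, B cannot be (no activator exists), so
    demanding B on at a steady final step is inconsistent."""
    abn = make_abn(
        [("A", {SOME_ANY}), ("B", {5})],
        [("A", "A", True, True), ("A", "B", False, True)],
    )
    exp = Experiment(
        "steady_b_on",
        6,
        frozenset(),
        frozenset(
            {
                obs(0, "A", True, "initial"),
                obs(0, "B", False, "initial"),
                obs(5, "B", True, "outcome"),
            }
        ),
    )
    return SynthesisProblem(abn, ExperimentSuite((exp,)))


def test_unsat_toy(repression_toy):
    result = solve(repression_toy)
    assert result.status == "UNSAT"
    assert result.models == ()
    assert brute_force_synthesize(repression_toy).status == "UNSAT"
    enum = enumerate_solutions(repression_toy, limit=5)
    assert enum.status == "UNSAT" and enum.exhaustive


def test_null_of_deterministic_toy_is_sat(repression_toy):
    """With a fully pinned initial state exactly one of the experiment
    and its negation is satisfiable — here the negation."""
    result = null_hypothesis(repression_toy, "steady_b_on")
    assert result.status == "SAT"
    witness = result.models[0].witnesses["steady_b_on"]
    assert witness[5]["A"] and not witness[5]["B"]
    with pytest.raises(KeyError):
        null_hypothesis(repression_toy, "missing")


def test_empty_suite_is_sat_and_counts_solutions():
    abn = make_abn(
        [("A", {SOME}), ("B", {SOME})],
        [
            ("A", "B", True, False),
            ("B", "A", True, False),
            ("A", "B", False, False),
        ],
    )
    problem = SynthesisProblem(abn, ExperimentSuite(()))
    result = enumerate_solutions(problem, limit=100)
    assert result.status == "SAT"
    assert len(result.models) == 2 ** 3  # singleton menus: optional subsets
    assert result.exhaustive
    keys = {m.network.key() for m in result.models}
    assert len(keys) == 8


def test_solutions_pass_independent_verification():
    spec = FixtureSpec(seed=7, n_components=5, n_definite=6, n_optional=3)
    abn = random_abn(spec)
    hidden, suite = plant_and_observe(spec, abn)
    problem = SynthesisProblem(abn, suite)
    result = enumerate_solutions(problem, limit=5)
    assert result.status == "SAT"
    for model in result.models:
        assert verify_model(model.network, suite)
    assert verify_model(hidden, suite)


def test_nonsolution_fails_verification(repression_toy):
    net = ConcreteNetwork(
        repression_toy.abn, [], {"A": SOME_ANY, "B": 5}
    )
    assert not verify_model(net, repression_toy.suite)


def test_first_model_stable_across_limits():
    spec = FixtureSpec(seed=3, n_components=5, n_definite=6, n_optional=3)
    abn = random_abn(spec)
    _, suite = plant_and_observe(spec, abn)
    problem = SynthesisProblem(abn, suite, SolveOptions(seed=11))
    one = enumerate_solutions(problem, limit=1)
    five = enumerate_solutions(problem, limit=5)
    assert one.models[0].network.key() == five.models[0].network.key()


def test_oracle_equivalence_on_seeded_instances():
    """CDCL-backed synthesis agrees with exhaustive enumeration, in status
    and in the full solution set."""
    for seed in range(25):
        spec = FixtureSpec(
            seed=seed,
            n_components=4,
            n_definite=5,
            n_optional=3,
            menu_size=2,
            n_experiments=2,
            length=6,
            observed_fraction=0.5,
        )
        abn = random_abn(spec)
        _, suite = plant_and_observe(spec, abn)
        problem = SynthesisProblem(abn, suite)
        full = enumerate_solutions(problem, limit=abn.model_space_size + 1)
        oracle = brute_force_synthesize(problem)
        assert full.status == oracle.status
        assert {m.network.key() for m in full.models} == {
            m.network.key() for m in oracle.models
        }


def test_adding_experiments_never_creates_solutions():
    """Constraint sets only shrink the solution space (monotone blocking)."""
    for seed in range(15):
        spec = FixtureSpec(seed=seed, n_components=4, n_definite=5, n_optional=2)
        abn = random_abn(spec)
        _, suite = plant_and_observe(spec, abn)
        experiments = suite.experiments
        previous_sat = True
        for k in range(1, len(experiments) + 1):
            prefix = SynthesisProblem(abn, ExperimentSuite(experiments[:k]))
            status = solve(prefix).is_sat
            if not previous_sat:
                assert not status
            previous_sat = status


def test_length_override():
    spec = FixtureSpec(seed=2, n_components=4, n_definite=5, n_optional=2)
    abn = random_abn(spec)
    _, suite = plant_and_observe(spec, abn)
    problem = SynthesisProblem(
        abn, suite, SolveOptions(length_override=spec.length + 4)
    )
    assert problem.effective_suite().experiments[0].length == spec.length + 4
    bad = SynthesisProblem(abn, suite, SolveOptions(length_override=1))
    with pytest.raises(ValueError):
        bad.effective_suite()
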