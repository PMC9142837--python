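"""Synchronous semantics: regulator occupancy, stepping, trajectories."""

import random

import pytest

from abnsynth.conditions import Level, semantic_index
from abnsynth.fixtures import FixtureSpec, plant_concretization, random_abn
from abnsynth.network import (
    AbstractBooleanNetwork,
    Component,
    ConcreteNetwork,
    Interaction,
    classify_regulators,
    simulate,
    synchronous_step,
)
from conftest import make_abn

SOME = semantic_index("some_activators_no_repressors")
SOME_ANY = semantic_index("some_activators")


def two_activator_net():
    abn = make_abn(
        [("A", {SOME}), ("B", {SOME}), ("T", {SOME})],
        [("A", "T", True, True), ("B", "T", True, True)],
    )
    return ConcreteNetwork(abn, [], {"A": SOME, "B": SOME, "T": SOME})


def test_classify_all_some_none():
    net = two_activator_net()
    state = {"A": True, "B": True, "T": False}
    assert classify_regulators(net, "T", state) == (Level.ALL, Level.NONE)
    state["B"] = False
    assert classify_regulators(net, "T", state) == (Level.SOME, Level.NONE)
    state["A"] = False
    assert classify_regulators(net, "T", state) == (Level.NONE, Level.NONE)


def test_classify_degenerate_empty_classes():
    """Zero declared regulators report level none, never all."""
    net = two_activator_net()
    state = {"A": True, "B": True, "T": True}
    # A has no regulators at all.
    assert classify_regulators(net, "A", state) == (Level.NONE, Level.NONE)
    with pytest.raises(KeyError):
        classify_regulators(net, "missing", state)


def test_unchosen_optional_edges_do_not_regulate():
    abn = make_abn(
        [("A", {SOME}), ("T", {SOME})],
        [("A", "T", True, False)],
    )
    excluded = ConcreteNetwork(abn, [], {"A": SOME, "T": SOME})
    chosen = ConcreteNetwork(abn, [("A", "T", True)], {"A": SOME, "T": SOME})
    state = {"A": True, "T": False}
    assert classify_regulators(net=excluded, component="T", state=state) == (
        Level.NONE,
        Level.NONE,
    )
    assert classify_regulators(net=chosen, component="T", state=state) == (
        Level.ALL,
        Level.NONE,
    )
    # With no effective incoming interactions the target decays.
    assert synchronous_step(excluded, state)["T"] is False
    assert synchronous_step(chosen, state)["T"] is True


def test_self_loop_bistability():
    abn = make_abn([("S0", {SOME_ANY})], [("S0", "S0", True, True)])
    net = ConcreteNetwork(abn, [], {"S0": SOME_ANY})
    assert synchronous_step(net, {"S0": True})["S0"] is True
    assert synchronous_step(net, {"S0": False})["S0"] is False


def test_no_regulator_component_decays_unless_clamped():
    abn = make_abn([("X", {SOME})], [])
    net = ConcreteNetwork(abn, [], {"X": SOME})
    assert synchronous_step(net, {"X": True})["X"] is False
    assert synchronous_step(net, {"X": True}, {"X": True})["X"] is True


def test_clamps_apply_at_step_zero():
    abn = make_abn([("X", {SOME})], [])
    net = ConcreteNetwork(abn, [], {"X": SOME})
    traj = simulate(net, {"X": False}, 3, {"X": True})
    assert [s["X"] for s in traj] == [True, True, True]
    with pytest.raises(KeyError):
        synchronous_step(net, {"X": False}, {"Y": True})


def test_simulate_contract():
    net = two_activator_net()
    initial = {"A": True, "B": False, "T": False}
    assert simulate(net, initial, 1) == (initial,)
    with pytest.raises(ValueError):
        simulate(net, initial, 0)
    a = simulate(net, initial, 6)
    b = simulate(net, initial, 6)
    assert a == b  # pure function, bit-identical


def _random_nets(n_instances, start_seed=0):
    for seed in range(start_seed, start_seed + n_instances):
        spec = FixtureSpec(
            seed=seed, n_components=5, n_definite=6, n_optional=3, menu_size=3
        )
        abn = random_abn(spec)
        yield seed, plant_concretization(spec, abn)


def test_fixpoint_absorption():
    """If two consecutive states are equal, the trajectory stays there."""
    for seed, net in _random_nets(30):
        rng = random.Random(seed)
        initial = {n: rng.random() < 0.5 for n in net.abn.names}
        traj = simulate(net, initial, 12)
        for t in range(len(traj) - 1):
            if traj[t] == traj[t + 1]:
                assert all(traj[u] == traj[t] for u in range(t, len(traj)))
                break


def test_update_monotonicity_under_regulator_flips():
    """Activator off->on never deactivates a target; repressor off->on
    never activates it."""
    checked = 0
    for seed, net in _random_nets(40):
        rng = random.Random(seed + 10_000)
        for _ in range(20):
            state = {n: rng.random() < 0.5 for n in net.abn.names}
            for comp in net.abn.names:
                before = synchronous_step(net, state)[comp]
                for activator in net.activators_of(comp):
                    if not state[activator]:
                        flipped = dict(state, **{activator: True})
                        after = synchronous_step(net, flipped)[comp]
                        assert not (before and not after)
                        checked += 1
                for repressor in net.repressors_of(comp):
                    if not state[repressor]:
                        flipped = dict(state, **{repressor: True})
                        after = synchronous_step(net, flipped)[comp]
                        assert not (after and not before)
                        checked += 1
    assert checked > 1000


def test_network_validation():
    with pytest.raises(ValueError):
        make_abn([("A", {SOME}), ("A", {SOME})], [])  # duplicate names
    with pytest.raises(ValueError):
        make_abn([("A", {SOME})], [("A", "B", True, True)])  # unknown endpoint
    with pytest.raises(ValueError):
        make_abn(
            [("A", {SOME}), ("B", {SOME})],
            [("A", "B", True, True), ("A", "B", True, False)],
        )  # same signed edge both definite and optional
    with pytest.raises(ValueError):
        Component(name="A", condition_menu=frozenset())
    with pytest.raises(ValueError):
        Component(name="A", condition_menu=frozenset({42}))


def test_concretization_validation():
    abn = make_abn(
        [("A", {SOME}), ("B", {SOME, SOME_ANY})],
        [("A", "B", True, False)],
    )
    with pytest.raises(ValueError):
        ConcreteNetwork(abn, [("B", "A", True)], {"A": SOME, "B": SOME})
    with pytest.raises(ValueError):
        ConcreteNetwork(abn, [], {"A": SOME_ANY, "B": SOME})  # not in menu
    with pytest.raises(ValueError):
        ConcreteNetwork(abn, [], {"A": SOME})  # missing assignment
    assert abn.model_space_size == 2 * 2  # one optional edge, one 2-menu
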