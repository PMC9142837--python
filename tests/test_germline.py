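"""The packaged germline network and its experiment suites."""

import pytest

from abnsynth.experiments import compile_perturbations
from abnsynth.germline import (
    EXPERIMENT_LENGTH,
    PERTURBATION_ORDER,
    SETUPS,
    build_experiment_suite,
    build_germline_abn,
    build_setup_abn,
    germline_catalog,
    network_summary,
    reference_concretization,
)
from abnsynth.network import simulate
from abnsynth.synthesis import (
    SynthesisProblem,
    enumerate_solutions,
    find_witnesses,
    verify_model,
)

CORE_NOTCH = ("GLP1ICD", "SEL8", "LAG1", "LST1", "SYGL1", "FBF2")

# Source/target pairs of the literature data-collection table, after the
# two-state FBF-1 expansion (bound FBF1B / unbound FBF1U).
TABLE_ROWS = [
    ("DTC", "APX1", True),
    ("DTC", "LAG2", True),
    ("LAG2", "GLP1", True),
    ("APX1", "GLP1", True),
    ("GLP1", "GLP1ICD", True),
    ("GLP1ICD", "SEL8", True),
    ("GLP1ICD", "LAG1", True),
    ("SEL8", "LAG1", True),
    ("GLP1", "HOP1", True),
    ("HOP1", "GLP1ICD", True),
    ("GLP1", "SEL12", True),
    ("SEL12", "GLP1ICD", True),
    ("SEL10", "GLP1ICD", False),
    ("SEL10", "SEL12", False),
    ("LAG1", "LST1", True),
    ("LAG1", "SYGL1", True),
    ("LST1", "GLD1", False),
    ("FBF1B", "GLD1", False),
    ("LAG1", "FBF2", True),
    ("FBF2", "GLD1", False),
    ("FBF1U", "GLD3", True),
    ("FBF1B", "GLD3", False),
    ("FBF2", "GLD3", False),
    ("GLD3", "GLD2", True),
    ("NOS3", "GLD1", True),
    ("GLD2", "GLD1", True),
    ("FBF1B", "SCF_PROM1", False),
    ("FBF1B", "AXIS_SC", False),
    ("FBF2", "AXIS_SC", False),
    ("SCF_PROM1", "CYE1_CDK2", False),
]


@pytest.fixture(scope="module")
def abn():
    return build_germline_abn()


def test_structural_counts(abn):
    summary = network_summary(abn)
    assert summary["components"] == 24
    assert summary["interactions"] == 40
    assert summary["state_space_size"] == 16_777_216
    assert summary["definite_interactions"] + summary["optional_interactions"] == 40


def test_key_interactions_present(abn):
    edges = {(i.source, i.target, i.sign): i for i in abn.interactions}
    dtc_lag2 = edges[("DTC", "LAG2", True)]
    assert dtc_lag2.definite
    assert ("SEL10", "GLP1ICD", False) in edges  # SEL-10 represses Notch ICD
    optional = {k for k, i in edges.items() if not i.definite}
    assert ("FBF1B", "SCF_PROM1", False) in optional
    assert ("MeioticDev", "StemcellFate", False) in optional


def test_every_table_row_maps_to_an_edge(abn):
    """Each literature regulation appears in the packaged network with
    its sign; the bound/unbound FBF-1 split carries the FBF-1 rows."""
    edges = {(i.source, i.target, i.sign) for i in abn.interactions}
    for row in TABLE_ROWS:
        assert row in edges, row
    # The LST1/SYGL1 "repress FBF-1" rows appear as the two-state switch.
    for effector in ("LST1", "SYGL1"):
        assert (effector, "FBF1B", True) in edges
        assert (effector, "FBF1U", False) in edges


def test_sel10_classified_as_repressor(abn):
    net = reference_concretization("niche")
    assert "SEL10" in net.repressors_of("GLP1ICD")


def test_empty_network_summary():
    from abnsynth.network import AbstractBooleanNetwork

    empty = AbstractBooleanNetwork([], [])
    summary = network_summary(empty)
    assert summary["components"] == 0
    assert summary["state_space_size"] == 1
    assert summary["model_space_size"] == 1


def test_catalog_setups():
    catalog = germline_catalog()
    assert set(catalog.suites) == set(SETUPS)
    assert len(catalog.abn.components) == 24
    for setup in SETUPS:
        suite = catalog.suites[setup]
        assert suite.labels()[0] == "wild_type"
        assert set(suite.labels()[1:]) == set(PERTURBATION_ORDER)
        for exp in suite:
            assert exp.length == EXPERIMENT_LENGTH
            assert exp.outcome_constraints
        # auxiliary signals are additions on top of the core 24
        assert len(catalog.setup_abns[setup].components) > 24


def test_reference_models_satisfy_their_suites():
    for setup in SETUPS:
        suite = build_experiment_suite(setup)
        net = reference_concretization(setup)
        assert verify_model(net, suite), setup


def _witness(setup, label):
    suite = build_experiment_suite(setup)
    witnesses = find_witnesses(reference_concretization(setup), suite)
    return witnesses[label]


def test_niche_wild_type_reaches_stem_cell_fate():
    """Constitutive DTC signaling: StemcellFate on, MeioticDev off after
    20 steps, with the trajectory settled into a fixpoint."""
    traj = _witness("niche", "wild_type")
    final = traj[-1]
    assert final["StemcellFate"] and not final["MeioticDev"]
    assert traj[-1] == traj[-2]
    for gene in CORE_NOTCH:
        assert final[gene]


def test_glp1_knockout_silences_notch_and_enters_meiosis():
    traj = _witness("niche", "glp1_ko")
    assert all(not state["GLP1"] for state in traj)
    for gene in CORE_NOTCH:
        assert all(not state[gene] for state in traj)
    assert traj[-1]["MeioticDev"] and not traj[-1]["StemcellFate"]


def test_effector_redundancy_single_vs_double_knockout():
    for label in ("lst1_ko", "sygl1_ko"):
        final = _witness("niche", label)[-1]
        assert final["StemcellFate"] and not final["MeioticDev"]
    final = _witness("niche", "lst1_sygl1_ko")[-1]
    assert final["MeioticDev"] and not final["StemcellFate"]


def test_two_state_fbf_partner_switch():
    """Bound FBF-1 tracks LST-1/SYGL-1 presence; unbound tracks absence."""
    steady_niche = _witness("niche", "wild_type")[-1]
    assert steady_niche["LST1"] or steady_niche["SYGL1"]
    assert steady_niche["FBF1B"] and not steady_niche["FBF1U"]
    steady_losing = _witness("losing", "wild_type")[-1]
    assert not (steady_losing["LST1"] or steady_losing["SYGL1"])
    assert steady_losing["FBF1U"] and not steady_losing["FBF1B"]


def test_losing_setup_dtc_decays():
    traj = _witness("losing", "wild_type")
    assert traj[0]["DTC"] and not traj[20]["DTC"]
    assert traj[-1]["MeioticDev"] and not traj[-1]["StemcellFate"]


def test_reduced_setup_reaches_meiosis():
    traj = _witness("reduced", "wild_type")
    assert traj[0]["DTC"] and not traj[1]["DTC"]  # single-step DTC pulse
    assert traj[0]["SD"] and not traj[1]["SD"]  # self-degrading signal
    assert traj[-1]["MeioticDev"]


def test_full_niche_suite_is_satisfiable():
    problem = SynthesisProblem(
        build_setup_abn("niche"), build_experiment_suite("niche")
    )
    result = enumerate_solutions(problem, limit=3)
    assert result.status == "SAT"
    wt = result.models[0].witnesses["wild_type"][-1]
    assert wt["StemcellFate"] and not wt["MeioticDev"]


def test_unknown_setup_and_perturbation_rejected():
    with pytest.raises(ValueError):
        build_experiment_suite("distal")
    with pytest.raises(ValueError):
        build_experiment_suite("niche", ["fog2_ko"])
    with pytest.raises(ValueError):
        build_setup_abn("distal")


def test_perturbations_clamp_from_step_zero():
    suite = build_experiment_suite("niche", ["glp1_fe"])
    exp = suite.experiment("glp1_fe")
    assert compile_perturbations(exp) == {"GLP1": True}
    net = reference_concretization("niche")
    traj = simulate(
        net,
        {name: name in ("DTC", "S0") for name in net.abn.names},
        exp.length,
        compile_perturbations(exp),
    )
    assert all(state["GLP1"] for state in traj)
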