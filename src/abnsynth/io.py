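"""File formats: JSON models/suites/solutions, TSV interaction tables,
CSV trajectory tables and DOT/GraphML network export.

All formats are plain-text and versioned through a ``format_version``
field.  Readers validate eagerly and name the offending entry; writers
produce exactly what the readers accept, so write-then-read is the
identity on every document type.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import networkx as nx

from .experiments import (
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
    Trajectory,
)

FORMAT_VERSION = 1

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A document violates the expected structure."""


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return mapping[key]


def _check_version(doc: dict, where: str) -> None:
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise SchemaError(
            f"{where}: unsupported format_version {version!r} "
            f"(expected {FORMAT_VERSION})"
        )


# ---------------------------------------------------------------------------
# Model files (JSON)
# ---------------------------------------------------------------------------

_SIGNS = {"activate": True, "repress": False}
_SIGN_NAMES = {True: "activate", False: "repress"}


def model_to_dict(abn: AbstractBooleanNetwork) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "components": [
            {
                "name": c.name,
                "role": c.role,
                "condition_menu": sorted(c.condition_menu),
            }
            for c in abn.components
        ],
        "interactions": [
            {
                "source": i.source,
                "target": i.target,
                "sign": _SIGN_NAMES[i.sign],
                "definite": i.definite,
            }
            for i in abn.interactions
        ],
    }


def model_from_dict(doc: dict) -> AbstractBooleanNetwork:
    _check_version(doc, "model")
    components = []
    for k, entry in enumerate(_require(doc, "components", "model")):
        where = f"model components[{k}]"
        components.append(
            Component(
                name=_require(entry, "name", where),
                role=entry.get("role", "gene"),
                condition_menu=frozenset(
                    _require(entry, "condition_menu", where)
                ),
            )
        )
    interactions = []
    for k, entry in enumerate(_require(doc, "interactions", "model")):
        where = f"model interactions[{k}]"
        sign = _require(entry, "sign", where)
        if sign not in _SIGNS:
            raise SchemaError(
                f"{where}: sign must be 'activate' or 'repress', got {sign!r}"
            )
        interactions.append(
            Interaction(
                source=_require(entry, "source", where),
                target=_require(entry, "target", where),
                sign=_SIGNS[sign],
                definite=bool(entry.get("definite", True)),
            )
        )
    try:
        return AbstractBooleanNetwork(components, interactions)
    except ValueError as exc:
        raise SchemaError(f"model: {exc}") from exc


def write_model(abn: AbstractBooleanNetwork, path: PathLike) -> None:
    Path(path).write_text(json.dumps(model_to_dict(abn), indent=1) + "\n")


def read_model(path: PathLike) -> AbstractBooleanNetwork:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Interaction tables (TSV mirror of the data-collection table)
# ---------------------------------------------------------------------------

_TSV_REGULATES = {"act": True, "rep": False}


def read_interactions_tsv(path: PathLike) -> Tuple[Interaction, ...]:
    """Parse a Source/Regulates/Target/Definite table into interactions."""
    interactions = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        expected = {"Source", "Regulates", "Target", "Definite"}
        if reader.fieldnames is None or not expected <= set(reader.fieldnames):
            raise SchemaError(
                f"interaction table must have columns {sorted(expected)}"
            )
        for row_number, row in enumerate(reader, start=2):
            regulates = (row["Regulates"] or "").strip().lower()
            if regulates not in _TSV_REGULATES:
                raise SchemaError(
                    f"row {row_number}: Regulates must be 'act' or 'rep', "
                    f"got {row['Regulates']!r}"
                )
            definite = (row["Definite"] or "").strip().lower()
            if definite not in ("definite", "optional"):
                raise SchemaError(
                    f"row {row_number}: Definite must be 'definite' or "
                    f"'optional', got {row['Definite']!r}"
                )
            interactions.append(
                Interaction(
                    source=row["Source"].strip(),
                    target=row["Target"].strip(),
                    sign=_TSV_REGULATES[regulates],
                    definite=definite == "definite",
                )
            )
    return tuple(interactions)


def write_interactions_tsv(
    interactions: Iterable[Interaction], path: PathLike
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["Source", "Regulates", "Target", "Definite"])
        for i in interactions:
            writer.writerow(
                [
                    i.source,
                    "act" if i.sign else "rep",
                    i.target,
                    "definite" if i.definite else "optional",
                ]
            )


# ---------------------------------------------------------------------------
# Suite files (JSON)
# ---------------------------------------------------------------------------

def suite_to_dict(suite: ExperimentSuite) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "experiments": [
            {
                "label": e.label,
                "length": e.length,
                "perturbations": sorted(
                    ({"component": p.component, "mode": p.mode}
                     for p in e.perturbations),
                    key=lambda d: (d["component"], d["mode"]),
                ),
                "constraints": sorted(
                    (
                        {
                            "time": c.time,
                            "component": c.component,
                            "value": c.value,
                            "role": c.role,
                        }
                        for c in e.constraints
                    ),
                    key=lambda d: (d["time"], d["component"], d["role"]),
                ),
            }
            for e in suite
        ],
    }


def suite_from_dict(
    doc: dict, abn: Optional[AbstractBooleanNetwork] = None
) -> ExperimentSuite:
    _check_version(doc, "suite")
    experiments = []
    for k, entry in enumerate(_require(doc, "experiments", "suite")):
        where = f"suite experiments[{k}]"
        label = _require(entry, "label", where)
        try:
            exp = Experiment(
                label=label,
                length=int(_require(entry, "length", where)),
                perturbations=frozenset(
                    Perturbation(
                        component=_require(p, "component", where),
                        mode=_require(p, "mode", where),
                    )
                    for p in entry.get("perturbations", [])
                ),
                constraints=frozenset(
                    ObservationConstraint(
                        time=int(_require(c, "time", where)),
                        component=_require(c, "component", where),
                        value=bool(_require(c, "value", where)),
                        role=c.get("role", "intermediate"),
                    )
                    for c in entry.get("constraints", [])
                ),
            )
        except ValueError as exc:
            raise SchemaError(f"{where} ({label!r}): {exc}") from exc
        if abn is not None:
            for name in {c.component for c in exp.constraints} | {
                p.component for p in exp.perturbations
            }:
                if name not in abn:
                    raise SchemaError(
                        f"{where} ({label!r}): unknown component {name!r}"
                    )
        experiments.append(exp)
    try:
        return ExperimentSuite(tuple(experiments))
    except ValueError as exc:
        raise SchemaError(f"suite: {exc}") from exc


def write_suite(suite: ExperimentSuite, path: PathLike) -> None:
    Path(path).write_text(json.dumps(suite_to_dict(suite), indent=1) + "\n")


def read_suite(
    path: PathLike, abn: Optional[AbstractBooleanNetwork] = None
) -> ExperimentSuite:
    return suite_from_dict(json.loads(Path(path).read_text()), abn)


# ---------------------------------------------------------------------------
# Solution files (JSON): a concrete network with its ABN
# ---------------------------------------------------------------------------

def solution_to_dict(net: ConcreteNetwork) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "model": model_to_dict(net.abn),
        "chosen_optional": sorted(
            [i.source, i.target, _SIGN_NAMES[i.sign]]
            for i in net.chosen_optional
        ),
        "condition_assignment": dict(sorted(net.condition_assignment.items())),
    }


def solution_from_dict(doc: dict) -> ConcreteNetwork:
    _check_version(doc, "solution")
    abn = model_from_dict(_require(doc, "model", "solution"))
    chosen = [
        (s, t, _SIGNS[sign])
        for s, t, sign in _require(doc, "chosen_optional", "solution")
    ]
    try:
        return ConcreteNetwork(
            abn, chosen, _require(doc, "condition_assignment", "solution")
        )
    except ValueError as exc:
        raise SchemaError(f"solution: {exc}") from exc


def write_solution(net: ConcreteNetwork, path: PathLike) -> None:
    Path(path).write_text(json.dumps(solution_to_dict(net), indent=1) + "\n")


def read_solution(path: PathLike) -> ConcreteNetwork:
    return solution_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Trajectory tables (CSV)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryTable:
    """Rows = time steps, columns = components, cells 0/1."""

    columns: Tuple[str, ...]
    rows: Tuple[Tuple[int, ...], ...]

    def to_csv(self) -> str:
        lines = ["step," + ",".join(self.columns)]
        for step, row in enumerate(self.rows):
            lines.append(f"{step}," + ",".join(str(v) for v in row))
        return "\n".join(lines) + "\n"


def activation_order(traj: Trajectory) -> Tuple[str, ...]:
    """Components by first-activation time; never-active last; ties by name."""
    names = sorted(traj[0])
    length = len(traj)

    def first_on(name: str) -> int:
        for t, state in enumerate(traj):
            if state[name]:
                return t
        return length

    return tuple(sorted(names, key=lambda n: (first_on(n), n)))


def render_trajectory_table(
    traj: Trajectory, ordering: Optional[Sequence[str]] = None
) -> TrajectoryTable:
    """Gene-activity table of one witness trajectory.

    Default column ordering follows the order of first activation, the
    way simulation tables are usually displayed.
    """
    columns = tuple(ordering) if ordering is not None else activation_order(traj)
    missing = set(columns) ^ set(traj[0])
    if missing:
        raise ValueError(f"ordering does not match components: {sorted(missing)}")
    rows = tuple(
        tuple(int(state[name]) for name in columns) for state in traj
    )
    return TrajectoryTable(columns=columns, rows=rows)


def write_trajectory_csv(
    traj: Trajectory,
    path: PathLike,
    ordering: Optional[Sequence[str]] = None,
) -> None:
    Path(path).write_text(render_trajectory_table(traj, ordering).to_csv())


def read_trajectory_csv(path: PathLike) -> Trajectory:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split(",")
    if header[0] != "step":
        raise SchemaError("trajectory table must start with a 'step' column")
    columns = header[1:]
    states = []
    for line in lines[1:]:
        cells = line.split(",")
        values = cells[1:]
        if len(values) != len(columns):
            raise SchemaError(f"trajectory row {cells[0]}: wrong cell count")
        if any(v not in ("0", "1") for v in values):
            raise SchemaError(f"trajectory row {cells[0]}: cells must be 0/1")
        states.append({c: v == "1" for c, v in zip(columns, values)})
    return tuple(states)


# ---------------------------------------------------------------------------
# Network export (DOT / GraphML)
# ---------------------------------------------------------------------------

def to_dot(abn: AbstractBooleanNetwork) -> str:
    """Graphviz document: activation arrowheads, repression T-bars,
    optional interactions dashed."""
    lines = ["digraph abn {"]
    for c in abn.components:
        lines.append(f'  "{c.name}" [shape=box];')
    for i in abn.interactions:
        attrs = [f'arrowhead={"normal" if i.sign else "tee"}']
        if not i.definite:
            attrs.append("style=dashed")
        lines.append(f'  "{i.source}" -> "{i.target}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml_graph(abn: AbstractBooleanNetwork) -> "nx.MultiDiGraph":
    graph = nx.MultiDiGraph()
    for c in abn.components:
        graph.add_node(c.name, role=c.role)
    for i in abn.interactions:
        graph.add_edge(
            i.source,
            i.target,
            sign="activate" if i.sign else "repress",
            definite=i.definite,
        )
    return graph


def export_network(
    abn: AbstractBooleanNetwork, path: PathLike, format: str = "dot"
) -> None:
    format = format.lower()
    if format == "dot":
        Path(path).write_text(to_dot(abn))
    elif format == "graphml":
        nx.write_graphml(to_graphml_graph(abn), str(path))
    else:
        raise ValueError(f"unknown export format: {format!r}")
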