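"""Bounded-trajectory CNF encoding of a synthesis problem.

Each experiment's synchronous transition relation is unrolled over its
length; the optional-interaction selector variables and per-component
condition selectors are shared across experiments, while free initial
values are per-experiment.  Expressions are built through a small
Tseitin layer (:class:`CnfBuilder`) that folds Boolean constants and
hashes repeated gates, so components whose update cone contains no
choice variable collapse to constants and contribute no clauses — for
fully pinned initial states only the cone of influence of the choice
variables remains symbolic.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple, Union

from .conditions import GRID_CELLS, Level, condition
from .experiments import Experiment, ExperimentSuite, compile_perturbations
from .network import AbstractBooleanNetwork, Component, Interaction
from .sat import SATSolver

Expr = Union[bool, int]  # folded constant or CNF literal

EdgeKey = Tuple[str, str, bool]


class CnfBuilder:
    """Tseitin gate builder with constant folding and structural hashing."""

    def __init__(self, solver: SATSolver) -> None:
        self.solver = solver
        self._and_cache: Dict[Tuple[int, ...], int] = {}
        self.unsatisfiable = False

    def new_var(self) -> int:
        return self.solver.new_var()

    @staticmethod
    def NOT(x: Expr) -> Expr:
        return (not x) if isinstance(x, bool) else -x

    def AND(self, *xs: Expr) -> Expr:
        lits: List[int] = []
        for x in xs:
            if x is False:
                return False
            if x is True:
                continue
            lits.append(x)
        unique = sorted(set(lits), key=abs)
        for lit in unique:
            if -lit in unique:
                return False
        if not unique:
            return True
        if len(unique) == 1:
            return unique[0]
        key = tuple(unique)
        cached = self._and_cache.get(key)
        if cached is not None:
            return cached
        gate = self.new_var()
        for lit in unique:
            self.solver.add_clause([-gate, lit])
        self.solver.add_clause([gate] + [-lit for lit in unique])
        self._and_cache[key] = gate
        return gate

    def OR(self, *xs: Expr) -> Expr:
        return self.NOT(self.AND(*(self.NOT(x) for x in xs)))

    def assert_true(self, x: Expr) -> None:
        if x is True:
            return
        if x is False:
            self.unsatisfiable = True
            self.solver.add_clause([])
            return
        self.solver.add_clause([x])

    def exactly_one(self, lits: List[int]) -> None:
        self.solver.add_clause(list(lits))
        for i in range(len(lits)):
            for j in range(i + 1, len(lits)):
                self.solver.add_clause([-lits[i], -lits[j]])


class ProblemEncoding:
    """CNF of one ABN against one experiment suite."""

    def __init__(
        self,
        abn: AbstractBooleanNetwork,
        suite: ExperimentSuite,
    ) -> None:
        self.abn = abn
        self.suite = suite
        self.solver = SATSolver()
        self.builder = CnfBuilder(self.solver)
        # Shared choice variables.
        self.edge_vars: Dict[EdgeKey, int] = {}
        for inter in abn.optional_interactions:
            self.edge_vars[(inter.source, inter.target, inter.sign)] = (
                self.builder.new_var()
            )
        self.condition_vars: Dict[str, Dict[int, int]] = {}
        for comp in abn.components:
            menu = sorted(comp.condition_menu)
            if len(menu) == 1:
                continue
            selectors = {index: self.builder.new_var() for index in menu}
            self.condition_vars[comp.name] = selectors
            self.builder.exactly_one(list(selectors.values()))
        # Branch on choice variables first, in a fixed order.
        self.solver.priority = sorted(self.edge_vars.values()) + [
            v
            for selectors in self.condition_vars.values()
            for v in sorted(selectors.values())
        ]
        # Per-experiment free initial value variables.
        self.free_initial_vars: Dict[str, Dict[str, int]] = {}
        for exp in suite:
            self._encode_experiment(exp)

    # -- per-experiment unrolling -----------------------------------------
    def _encode_experiment(self, exp: Experiment) -> None:
        b = self.builder
        clamps = compile_perturbations(exp)
        pinned: Dict[str, bool] = {}
        for constraint in exp.constraints:
            if constraint.time != 0:
                continue
            prev = pinned.setdefault(constraint.component, constraint.value)
            if prev != constraint.value:
                b.assert_true(False)
        state: Dict[str, Expr] = {}
        free: Dict[str, int] = {}
        for comp in self.abn.components:
            name = comp.name
            if name in clamps:
                state[name] = clamps[name]
            elif name in pinned:
                state[name] = pinned[name]
            else:
                var = b.new_var()
                free[name] = var
                state[name] = var
        self.free_initial_vars[exp.label] = free
        states: List[Dict[str, Expr]] = [state]
        for _ in range(exp.length - 1):
            states.append(self._encode_step(states[-1], clamps))
        for constraint in exp.constraints:
            value = states[constraint.time][constraint.component]
            b.assert_true(value if constraint.value else b.NOT(value))

    def _encode_step(
        self, state: Dict[str, Expr], clamps: Dict[str, bool]
    ) -> Dict[str, Expr]:
        nxt: Dict[str, Expr] = {}
        for comp in self.abn.components:
            if comp.name in clamps:
                nxt[comp.name] = clamps[comp.name]
            else:
                nxt[comp.name] = self._encode_update(comp, state)
        return nxt

    def _encode_update(self, comp: Component, state: Dict[str, Expr]) -> Expr:
        b = self.builder
        incoming = self.abn.incoming(comp.name)
        if not incoming:
            return False
        act_edges = [i for i in incoming if i.sign]
        rep_edges = [i for i in incoming if not i.sign]
        a_levels = self._level_exprs(act_edges, state)
        r_levels = self._level_exprs(rep_edges, state)
        menu = sorted(comp.condition_menu)
        if len(menu) == 1:
            result = self._table_expr(menu[0], a_levels, r_levels)
        else:
            selectors = self.condition_vars[comp.name]
            result = b.OR(
                *(
                    b.AND(selectors[index], self._table_expr(index, a_levels, r_levels))
                    for index in menu
                )
            )
        optional = [i for i in incoming if not i.definite]
        if len(optional) == len(incoming):
            # All regulators optional: with none chosen the effective edge
            # set is empty and the component decays.
            guard = b.OR(*(self._sel(i) for i in optional))
            result = b.AND(guard, result)
        return result

    def _sel(self, inter: Interaction) -> int:
        return self.edge_vars[(inter.source, inter.target, inter.sign)]

    def _level_exprs(
        self, edges: List[Interaction], state: Dict[str, Expr]
    ) -> Dict[Level, Expr]:
        """none/some/all occupancy exprs for one regulator class."""
        b = self.builder
        activity = [
            state[i.source]
            if i.definite
            else b.AND(self._sel(i), state[i.source])
            for i in edges
        ]
        saturated = [
            state[i.source]
            if i.definite
            else b.OR(b.NOT(self._sel(i)), state[i.source])
            for i in edges
        ]
        none_expr = b.NOT(b.OR(*activity))  # empty class folds to True
        all_expr = b.AND(b.AND(*saturated), b.NOT(none_expr))
        some_expr = b.AND(b.NOT(none_expr), b.NOT(all_expr))
        return {Level.NONE: none_expr, Level.SOME: some_expr, Level.ALL: all_expr}

    def _table_expr(
        self,
        index: int,
        a_levels: Dict[Level, Expr],
        r_levels: Dict[Level, Expr],
    ) -> Expr:
        b = self.builder
        table = condition(index).table
        terms = [
            b.AND(a_levels[a], r_levels[r]) for a, r in GRID_CELLS if table[(a, r)]
        ]
        return b.OR(*terms)

    # -- model decoding ----------------------------------------------------
    def choice_literals(self, model: Dict[int, bool]) -> List[int]:
        """The choice-variable assignment of a model, as literals."""
        lits = []
        for var in self.edge_vars.values():
            lits.append(var if model[var] else -var)
        for selectors in self.condition_vars.values():
            for var in selectors.values():
                lits.append(var if model[var] else -var)
        return lits

    def decode_choices(
        self, model: Dict[int, bool]
    ) -> Tuple[List[EdgeKey], Dict[str, int]]:
        chosen = [key for key, var in self.edge_vars.items() if model[var]]
        assignment: Dict[str, int] = {}
        for comp in self.abn.components:
            menu = sorted(comp.condition_menu)
            if len(menu) == 1:
                assignment[comp.name] = menu[0]
            else:
                selectors = self.condition_vars[comp.name]
                assignment[comp.name] = next(
                    index for index, var in selectors.items() if model[var]
                )
        return chosen, assignment

    def decode_initial_state(
        self, exp: Experiment, model: Dict[int, bool]
    ) -> Dict[str, bool]:
        """Full initial state of one experiment under a model."""
        clamps = compile_perturbations(exp)
        pinned = {
            c.component: c.value for c in exp.constraints if c.time == 0
        }
        free = self.free_initial_vars[exp.label]
        initial: Dict[str, bool] = {}
        for comp in self.abn.components:
            name = comp.name
            if name in clamps:
                initial[name] = clamps[name]
            elif name in free:
                initial[name] = model[free[name]]
            else:
                initial[name] = pinned[name]
        return initial
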