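"""A compact CDCL SAT solver used as the synthesis backend.

Conflict-driven clause learning with two watched literals per clause,
first-UIP conflict analysis and backjumping.  Branching follows a static
variable order (an optional priority list first, then ascending variable
index) with saved-phase value selection, which makes every run bit-for-bit
deterministic.  The bounded-synthesis encodings produced by
:mod:`abnsynth.encoding` define every non-choice variable functionally
from the choice and free-initial variables, so unit propagation carries
almost all of the work and the static order is effective.

Clauses are lists of non-zero integer literals (``v`` / ``-v``).  The
solver is incremental in the simple sense: clauses may be added between
calls to :meth:`SATSolver.solve`; every call restarts the search from
scratch but keeps previously learned clauses.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence


class SATSolver:
    """CDCL solver over integer literals."""

    def __init__(self) -> None:
        self.num_vars = 0
        self.clauses: List[List[int]] = []
        self._has_empty_clause = False
        # Assignment state (rebuilt per solve call).
        self._value: List[int] = [0]  # per var: 0 unassigned, 1 true, -1 false
        self._level: List[int] = [0]
        self._reason: List[Optional[int]] = [None]
        self._phase: List[bool] = [False]
        self._trail: List[int] = []
        self._trail_lim: List[int] = []
        self._qhead = 0
        self._watches: Dict[int, List[int]] = {}
        self.priority: List[int] = []  # vars branched on first, in order

    # -- construction ----------------------------------------------------
    def new_var(self) -> int:
        self.num_vars += 1
        self._value.append(0)
        self._level.append(0)
        self._reason.append(None)
        self._phase.append(False)
        return self.num_vars

    def add_clause(self, lits: Iterable[int]) -> None:
        """Add a clause; duplicates removed, tautologies dropped."""
        seen = set()
        clause: List[int] = []
        for lit in lits:
            if lit == 0 or abs(lit) > self.num_vars:
                raise ValueError(f"literal out of range: {lit}")
            if -lit in seen:
                return  # tautology
            if lit not in seen:
                seen.add(lit)
                clause.append(lit)
        if not clause:
            self._has_empty_clause = True
        self.clauses.append(clause)

    # -- assignment helpers ----------------------------------------------
    def _lit_value(self, lit: int) -> int:
        v = self._value[abs(lit)]
        return v if lit > 0 else -v

    def _enqueue(self, lit: int, reason: Optional[int]) -> None:
        var = abs(lit)
        self._value[var] = 1 if lit > 0 else -1
        self._level[var] = len(self._trail_lim)
        self._reason[var] = reason
        self._trail.append(lit)

    def _cancel_until(self, level: int) -> None:
        while self._trail_lim and len(self._trail_lim) > level:
            lim = self._trail_lim.pop()
            while len(self._trail) > lim:
                lit = self._trail.pop()
                var = abs(lit)
                self._phase[var] = lit > 0
                self._value[var] = 0
                self._reason[var] = None
        self._qhead = len(self._trail)

    # -- propagation ------------------------------------------------------
    def _watch(self, lit: int, ci: int) -> None:
        self._watches.setdefault(lit, []).append(ci)

    def _attach_all(self) -> Optional[int]:
        """Rebuild watches and enqueue top-level units; None on conflict."""
        self._watches = {}
        units: List[int] = []
        for ci, clause in enumerate(self.clauses):
            if not clause:
                return None
            if len(clause) == 1:
                units.append(clause[0])
            else:
                self._watch(clause[0], ci)
                self._watch(clause[1], ci)
        for lit in units:
            val = self._lit_value(lit)
            if val == -1:
                return None
            if val == 0:
                self._enqueue(lit, None)
        return -1  # sentinel: ok

    def _propagate(self) -> Optional[int]:
        """Exhaust unit propagation; return conflicting clause index."""
        while self._qhead < len(self._trail):
            lit = self._trail[self._qhead]
            self._qhead += 1
            neg = -lit
            watchers = self._watches.get(neg, [])
            kept: List[int] = []
            i = 0
            n = len(watchers)
            while i < n:
                ci = watchers[i]
                i += 1
                clause = self.clauses[ci]
                if clause[0] == neg:
                    clause[0], clause[1] = clause[1], clause[0]
                first = clause[0]
                if self._lit_value(first) == 1:
                    kept.append(ci)
                    continue
                moved = False
                for k in range(2, len(clause)):
                    if self._lit_value(clause[k]) != -1:
                        clause[1], clause[k] = clause[k], clause[1]
                        self._watch(clause[1], ci)
                        moved = True
                        break
                if moved:
                    continue
                kept.append(ci)
                if self._lit_value(first) == -1:
                    kept.extend(watchers[i:])
                    self._watches[neg] = kept
                    return ci
                self._enqueue(first, ci)
            self._watches[neg] = kept
        return None

    # -- conflict analysis -------------------------------------------------
    def _analyze(self, confl: int) -> List[int]:
        """First-UIP learned clause; asserting literal at position 0."""
        learnt: List[int] = []
        seen = [False] * (self.num_vars + 1)
        counter = 0
        p = 0
        cur_level = len(self._trail_lim)
        trail_idx = len(self._trail) - 1
        reason_lits: Sequence[int] = self.clauses[confl]
        while True:
            for q in reason_lits:
                if q == p:
                    continue
                var = abs(q)
                if not seen[var] and self._level[var] > 0:
                    seen[var] = True
                    if self._level[var] >= cur_level:
                        counter += 1
                    else:
                        learnt.append(q)
            while not seen[abs(self._trail[trail_idx])]:
                trail_idx -= 1
            p = self._trail[trail_idx]
            trail_idx -= 1
            seen[abs(p)] = False
            counter -= 1
            if counter == 0:
                break
            reason = self._reason[abs(p)]
            assert reason is not None
            reason_lits = self.clauses[reason]
        learnt.insert(0, -p)
        return learnt

    # -- branching ---------------------------------------------------------
    def _pick_branch_var(self) -> Optional[int]:
        for var in self.priority:
            if self._value[var] == 0:
                return var
        for var in range(1, self.num_vars + 1):
            if self._value[var] == 0:
                return var
        return None

    # -- main loop ----------------------------------------------------------
    def solve(self) -> Optional[Dict[int, bool]]:
        """Search; returns a full model dict (var -> bool) or None (UNSAT)."""
        if self._has_empty_clause:
            return None
        self._trail = []
        self._trail_lim = []
        self._qhead = 0
        for var in range(1, self.num_vars + 1):
            self._value[var] = 0
            self._reason[var] = None
        if self._attach_all() is None:
            return None
        while True:
            confl = self._propagate()
            if confl is not None:
                if not self._trail_lim:
                    return None
                learnt = self._analyze(confl)
                if len(learnt) == 1:
                    backjump = 0
                else:
                    backjump = max(self._level[abs(q)] for q in learnt[1:])
                self._cancel_until(backjump)
                if len(learnt) == 1:
                    self.clauses.append(learnt)
                    self._enqueue(learnt[0], None)
                else:
                    # watch the asserting literal and one at the backjump level
                    k = max(
                        range(1, len(learnt)),
                        key=lambda i: self._level[abs(learnt[i])],
                    )
                    learnt[1], learnt[k] = learnt[k], learnt[1]
                    ci = len(self.clauses)
                    self.clauses.append(learnt)
                    self._watch(learnt[0], ci)
                    self._watch(learnt[1], ci)
                    self._enqueue(learnt[0], ci)
            else:
                var = self._pick_branch_var()
                if var is None:
                    return {
                        v: self._value[v] == 1
                        for v in range(1, self.num_vars + 1)
                    }
                self._trail_lim.append(len(self._trail))
                self._enqueue(var if self._phase[var] else -var, None)


def solve_clauses(
    clauses: Iterable[Iterable[int]], num_vars: int
) -> Optional[Dict[int, bool]]:
    """One-shot convenience wrapper around :class:`SATSolver`."""
    solver = SATSolver()
    for _ in range(num_vars):
        solver.new_var()
    for clause in clauses:
        solver.add_clause(clause)
    return solver.solve()
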