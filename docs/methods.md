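# Methods

## Model class

An **abstract Boolean network** (ABN) is a tuple ⟨G, E, E?, R⟩: named
components G, definite signed interactions E, optional signed
interactions E?, and for each component a non-empty menu R_g of
admissible regulation conditions.  A **concretization** picks a subset
of E? and one condition per component, yielding an ordinary Boolean
network; the concrete-model space has size 2^|E?| · ∏_g |R_g|.

Dynamics are synchronous: q′(g) = R_g(q) for every g simultaneously.  A
regulation condition sees only the occupancy of g's effective
activators and repressors, coarsened to none/some/all; the 18 admissible
conditions are exactly the monotone non-constant tables on that 3×3
grid (docs/regulation_conditions.md).  Monotonicity gives the model
class its central guarantee: turning an activator on can never switch a
target off on the next step, and turning a repressor on can never
switch it on.

Three conventions close the semantics (all property-tested):

* an empty regulator class has occupancy `none`, never `all`;
* a component whose effective incoming edge set is empty decays to
  inactive — persistent inputs therefore need an explicit self-loop,
  which is also how the constitutive niche signal S0 is modeled;
* knockout (KO) and forced-expression (FE) clamps override regulation at
  every step including step 0.

Because the conditions are memoryless, a state equal to its successor is
a fixpoint and the system stays there; experiments pin outcomes at two
consecutive final steps (19 and 20 of a 21-state trajectory) to assert a
settled profile.

## Experiments and synthesis

An **experiment** is a bounded scenario: length k (default 21, so "time
step 20" is addressable), KO/FE clamps, and timed observation
constraints (component, step, Boolean value).  Constraints carry a role
tag — initial, intermediate, or outcome — which is artifact metadata:
the **null-hypothesis test** re-solves the problem with one experiment's
outcome constraints value-flipped, and the role tag is what makes that
negation mechanical.  Input-signal specifications (e.g. "DTC off by
step 20") are tagged intermediate so they are never flipped.

**Synthesis** asks whether one concretization satisfies every experiment
of a suite simultaneously, with per-experiment freedom only in initial
values not pinned by constraints.  The encoding unrolls each
experiment's transition relation over its length into CNF via a Tseitin
gate builder; optional-edge selectors and one-hot condition selectors
are shared across experiments.  The builder folds constants and hashes
repeated gates, so with fully pinned initial states only the cone of
influence of the choice variables stays symbolic — for the germline
suites this collapses thousands of state variables to a few hundred
gates.  The backend is a small conflict-driven clause-learning (CDCL)
SAT solver written for this package (two watched literals, first-UIP
learning, backjumping, static branching order preferring choice
variables), fully deterministic across runs.  Solutions are enumerated
by blocking the choice-variable assignment of each model found;
distinctness is by optional-edge subset plus condition assignment.

Every model returned by the solver is re-simulated and checked against
the suite before it is reported; a discrepancy raises a backend error
distinct from UNSAT.  An independent oracle, `brute_force_synthesize`,
enumerates the whole concretization space and verifies each candidate
purely by simulation (searching free initial values exhaustively,
bounded at 2^20 combinations); solver and oracle are cross-checked for
identical status and identical solution sets on 100 seeded random
instances in the test suite.

## The germline model

docs/germline_network.md documents the 24 components, the 40 edges with
their provenance, the condition menus and the three DTC-signal setups.
Two modeling points deserve emphasis:

* **Two-state FBF-1.**  FBF-1's partner-dependent switch is encoded as
  two mutually exclusive state components: LST-1/SYGL-1 drive FBF1B
  (bound, repressive toward the meiotic-entry pathways) and shut off
  FBF1U (unbound, promoting GLD-3).  FBF1U uses the activator-blind
  `no_repressors` condition, so it is the default state when no partner
  is present.
* **Setup choice for the null-hypothesis pattern.**  The downstream
  germline circuit is feed-forward (a DAG), so for a fixed
  concretization the steady state is a function of the input signal
  regime alone.  Under the constitutive-DTC (niche) setup, GLD-1 and
  GLD-2 do not feed back upstream, so a gld-1 gld-2 double knockout
  reaches the same steady MeioticDev inputs as wild type and the
  opposite-outcome variant of that experiment is structurally
  infeasible.  The alternative mechanism — SCF^PROM-1^ and the axis/SC
  proteins sustaining meiotic entry with GLD-1 and GLD-2 both off —
  exists exactly in the losing-signal setup, where FBF-1B is off at
  steady state and the optional repression routes are released.  The
  package therefore evaluates the knockout/overexpression phenotype
  matrix on the niche suite and the null-hypothesis pattern on the
  losing suite; both retained-constraints and isolated null modes are
  available (`--isolate` on the CLI), and on the losing suite they
  agree.

Wild-type initial states start with every component off except the DTC
and the setup's trigger signal, which matches the cascade reading of the
published simulation tables (genes activate in order of their distance
from the signal).  Perturbed components are clamped instead of
constrained.

## Synthetic fixtures

`abnsynth.fixtures` generates random ABNs (sizes, edge counts, menu
sizes and observation density set by `FixtureSpec`) with a planted
hidden concretization; observation suites are sampled from trajectories
simulated under the hidden network, so the planted network satisfies its
suite by construction and must appear in the exhaustive solution set.
One signed edge is placed per ordered component pair — a regulator that
both activates and represses the same target would defeat template
monotonicity.  Initial states are sampled uniformly; observed cells are
tagged initial/intermediate/outcome by their step.  All randomness flows
through one `random.Random` seeded from the spec, and the seed-1
topology is frozen as a golden file so PRNG drift cannot silently move
the tests.  Default sizes (5–6 components, ~9 edges of which 3–4
optional, menus of 2–3, 3 experiments of 8 steps, 60 % observation
density) keep the concretization space small enough for the brute-force
oracle while leaving genuine search freedom.

What the fixtures do not emulate: biological topology (no scale-free
structure, no modules), measurement noise (observations are exact), and
dosage or timing effects.  Passing the recovery harness shows the
engine is sound and complete on this model class, not that the germline
reconstruction is biologically unique.

## Numerical and degenerate-input choices

* Trajectories are 0-indexed; k-state experiments address steps 0..k−1.
* A constraint at step 0 pins the initial value outright (conflicting
  step-0 constraints make the problem UNSAT at encoding time).
* Enumeration order is backend-deterministic; tests assert set-level
  equality of solution sets, never order.
* The brute-force oracle refuses concretization spaces above 10^6 and
  free-initial searches above 2^20 combinations rather than silently
  truncating.
* UNSAT is reported without a minimal core; the CDCL backend learns
  clauses but does not extract cores.

## Problem sizes

The shipped suites and tests use: germline suites of 9 experiments × 21
states over 25–27 components (0.1–0.5 s per solve); 100-seed oracle and
recovery harnesses at 5 components (≈25 s together); the monotonicity
property at ≥10,000 regulator flips (≈2 s).  The full test suite runs in
well under a minute on one CPU.

## Known limitations

Asynchronous updates, multi-valued logic, quantitative/partial
knockouts and spatial (multicellular) context are out of scope.  The
germline reconstruction fixes the 40-edge roster and menus described
above; externally published model files for this system can serve as an
optional cross-check but are never a dependency, and where the
literature underdetermines a detail (the native ordering of the 18
templates, the S1–S3 signal semantics, the exact 40-edge roster) the
package's choice is documented here and in docs/germline_network.md.
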