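# abnsynth

Synthesis of Boolean gene-regulatory networks from experimental
constraints, packaged with a model of the *Caenorhabditis elegans*
germline stem-cell fate decision.

## The problem

In the adult *C. elegans* gonad, the distal tip cell (DTC) acts as a
stem-cell niche: its signal activates GLP-1 Notch in nearby germ cells
and keeps them undifferentiated, while cells that move out of range
enter meiotic development.  Which wiring of the known and hypothesized
genetic interactions is actually consistent with the published
knockout and overexpression phenotypes?  `abnsynth` answers this with
automated reasoning over **abstract Boolean networks** (ABNs): a
network template ⟨G, E, E?, R⟩ with definite interactions E, optional
interactions E?, and a menu R_g of admissible update rules per
component.  A concrete Boolean network is obtained by choosing a subset
of E? and one rule per component; the engine finds all concretizations
whose synchronous dynamics, q′(g) = R_g(q) for all g simultaneously,
satisfy every encoded experiment — or proves that none exists.

Update rules come from 18 **regulation conditions**: the monotone,
non-constant Boolean tables over the none/some/all occupancy grid of a
component's activators and repressors.  Index 5, for example, is

    AllActivators(c,q) ∨ (NoRepressors(c,q) ∧ ¬NoActivators(c,q))

the natural rule for redundant inputs.  Experiments are bounded
scenarios: knockout (KO) / forced-expression (FE) clamps plus timed
observation predicates such as *(e, 0, DTC, ⊤) ∧ (e, 20, DTC, ⊥)* — the
DTC signal on at step 0 and gone by step 20.  A **null-hypothesis test**
flips an experiment's outcome constraints and asks whether any
consistent network realizes the opposite phenotype.

The bundled germline model has 24 components and 40 interactions
(32 definite, 8 optional) spanning the core Notch pathway, the
redundant LST-1/SYGL-1 effectors, a two-state (bound/unbound) FBF-1,
and the GLD-1, GLD-2 and SCF^PROM-1^/axis-SC meiotic-entry pathways,
with suites for three DTC-signal setups (`niche`, `losing`, `reduced`).
See `docs/germline_network.md` for the edge-by-edge roster and
`docs/methods.md` for the method.

## Worked example

```python
from abnsynth.germline import (
    build_setup_abn, build_experiment_suite, build_germline_abn,
    network_summary,
)
from abnsynth.synthesis import (
    SynthesisProblem, enumerate_solutions, test_null_hypothesis,
)

print(network_summary(build_germline_abn()))
# {'components': 24, 'definite_interactions': 32,
#  'optional_interactions': 8, 'interactions': 40,
#  'state_space_size': 16777216, 'model_space_size': 512}

# Wild type + 8 KO/FE experiments under constitutive DTC signaling.
problem = SynthesisProblem(
    build_setup_abn("niche"), build_experiment_suite("niche")
)
result = enumerate_solutions(problem, limit=10)
print(result.status, len(result.models))
# SAT 10

final = result.models[0].witnesses["wild_type"][-1]
print({k: int(final[k]) for k in ("GLP1", "LST1", "StemcellFate", "MeioticDev")})
# {'GLP1': 1, 'LST1': 1, 'StemcellFate': 1, 'MeioticDev': 0}

# Can any consistent network contradict a published phenotype?
losing = SynthesisProblem(
    build_setup_abn("losing"), build_experiment_suite("losing")
)
print(test_null_hypothesis(losing, "gld1_gld2_ko").status)  # SAT
print(test_null_hypothesis(losing, "glp1_ko").status)       # UNSAT
```

The niche problem is satisfiable: each returned model pairs a concrete
network with one witness trajectory per experiment, and in every model
the witnesses reproduce the published phenotype matrix (meiotic entry
for GLP-1 KO and the *lst-1 sygl-1* double KO, preserved stem-cell fate
for either single effector KO, failure to enter meiosis for the
*gld-1 gld-2* double KO and for GLP-1/LST-1/SYGL-1 overexpression).
The null-hypothesis pattern singles out the *gld-1 gld-2* double
knockout: only there does some consistent network realize the opposite
outcome — its witness enters meiosis with GLD-1 and GLD-2 both off,
driven by the optional SCF^PROM-1^/axis-SC routes — while every other
perturbation's null hypothesis is unsatisfiable.

## Command line

```
abnsynth germline --out-dir models/           # write packaged model files
abnsynth synth models/germline_niche.json models/suite_niche.json --limit 5
abnsynth nullhyp models/germline_losing.json models/suite_losing.json \
    --experiment gld1_gld2_ko                 # exit 0 = SAT, 1 = UNSAT
abnsynth simulate models/reference_solution_niche.json \
    models/suite_niche.json --experiment wild_type --csv wt.csv
abnsynth export models/germline_core.json --format dot -o germline.dot
abnsynth fixtures --seed 7 --out-dir fx/      # synthetic planted instance
```

`synth`/`nullhyp` exit 0 on SAT and 1 on UNSAT (2 on usage errors).

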