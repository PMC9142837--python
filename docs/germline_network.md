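# The packaged germline network, edge by edge

The core abstract Boolean network has 24 components and 40 signed
interactions (32 definite, 8 optional), a reconstruction of the
published stem-cell-fate / meiotic-entry decision circuit from its
printed data-collection table and module descriptions.  The literature
table lists 30 regulations; the counts below show how they expand to 40
edges.

## Components (24)

DTC, LAG2, APX1, GLP1, GLP1ICD, SEL8, LAG1, HOP1, SEL12, SEL10 (core
Notch signaling); LST1, SYGL1 (redundant effectors); FBF1B, FBF1U (the
bound and unbound molecular states of FBF-1), FBF2; GLD1, GLD2, GLD3,
NOS3 (GLD-1/GLD-2 meiotic-entry pathways and GLD-1 accumulation);
SCF_PROM1, AXIS_SC (SCF^PROM-1^ pathway and meiotic chromosome
axis/synaptonemal-complex proteins); CYE1_CDK2; StemcellFate and
MeioticDev (fate readouts).

Auxiliary input signals (S0; S1–S3; SD) are setup-level additions and do
not count toward the 24.

## Edge table

| # | edge | status | provenance |
|---|---|---|---|
| 1 | DTC → APX1 | definite | literature row |
| 2 | DTC → LAG2 | definite | literature row |
| 3 | LAG2 → GLP1 | definite | literature row |
| 4 | APX1 → GLP1 | definite | literature row |
| 5 | GLP1 → GLP1ICD | definite | literature row |
| 6 | GLP1ICD → SEL8 | definite | literature row |
| 7 | GLP1ICD → LAG1 | definite | literature row |
| 8 | SEL8 → LAG1 | definite | literature row |
| 9 | GLP1 → HOP1 | definite | literature row |
| 10 | HOP1 → GLP1ICD | definite | literature row |
| 11 | GLP1 → SEL12 | definite | literature row |
| 12 | SEL12 → GLP1ICD | definite | literature row |
| 13 | SEL10 ⊣ GLP1ICD | definite | literature row |
| 14 | SEL10 ⊣ SEL12 | definite | literature row |
| 15 | LAG1 → LST1 | definite | literature row |
| 16 | LAG1 → SYGL1 | definite | literature row |
| 17 | LST1 ⊣ GLD1 | definite | literature row |
| 18 | LST1 → FBF1B | definite | "LST1 rep FBF1", two-state expansion |
| 19 | LST1 ⊣ FBF1U | definite | "LST1 rep FBF1", two-state expansion |
| 20 | SYGL1 → FBF1B | definite | "SYGL1 rep FBF1", two-state expansion |
| 21 | SYGL1 ⊣ FBF1U | definite | "SYGL1 rep FBF1", two-state expansion |
| 22 | FBF1B ⊣ GLD1 | definite | "FBF1 rep GLD1" (bound state) |
| 23 | LAG1 → FBF2 | definite | literature row |
| 24 | FBF2 ⊣ GLD1 | definite | literature row |
| 25 | FBF1U → GLD3 | definite | "FBF act GLD3" (unbound state) |
| 26 | FBF1B ⊣ GLD3 | definite | "FBF1 and FBF2 rep GLD3" |
| 27 | FBF2 ⊣ GLD3 | definite | "FBF1 and FBF2 rep GLD3" |
| 28 | GLD3 → GLD2 | definite | literature row |
| 29 | SCF_PROM1 ⊣ CYE1_CDK2 | definite | literature row |
| 30 | GLD1 → MeioticDev | definite | fate readout (meiotic-entry pathway) |
| 31 | GLD2 → MeioticDev | definite | fate readout (meiotic-entry pathway) |
| 32 | CYE1_CDK2 → StemcellFate | definite | fate readout (proliferative fate) |
| 33 | NOS3 → GLD1 | optional | redundant GLD-1 accumulation input |
| 34 | GLD2 → GLD1 | optional | redundant GLD-1 accumulation input |
| 35 | FBF1B ⊣ SCF_PROM1 | optional | hypothesized repression route |
| 36 | FBF1B ⊣ AXIS_SC | optional | hypothesized repression route |
| 37 | FBF2 ⊣ AXIS_SC | optional | hypothesized repression route |
| 38 | SCF_PROM1 → MeioticDev | optional | parallel meiotic-entry route |
| 39 | AXIS_SC → MeioticDev | optional | parallel meiotic-entry route |
| 40 | MeioticDev ⊣ StemcellFate | optional | fate mutual exclusion |

Rows "LST1 rep FBF1" and "SYGL1 rep FBF1" of the literature table are
realized through the two-state FBF-1 model: binding of either effector
drives FBF-1 into the bound state (activation of FBF1B, edges 18/20) and
out of the unbound state (repression of FBF1U, edges 19/21); the bound
state carries the repressive FBF-1 edges (22, 26, 35, 36) while the
unbound state promotes GLD-3 (25).  "FBF1 and FBF2" rows contribute one
edge per paralog.  The six fate-readout edges (30–32, 38–40) complete
the circuit to the printed total of 40.

Definite vs optional follows the published criterion: well-characterized
interactions with strong experimental support are definite; redundant or
hypothesized routes are optional and subject to synthesis.

## Condition menus

Every component carries a singleton menu chosen to express its
documented logic (see docs/regulation_conditions.md for indices):
redundant-input components (GLP1, GLP1ICD, LAG1, SEL12, FBF1B) use
index 5; single-input genes use `some_activators_no_repressors`;
derepression-driven components (FBF1U, SCF_PROM1, AXIS_SC, CYE1_CDK2)
use `no_repressors`; MeioticDev carries a two-entry menu
{`some_activators_no_repressors`, `all_activators_no_repressors`} so the
solver can weigh the parallel meiotic-entry routes.  The resulting
concrete-model space is 2^8 × 2 = 512 networks.

## Experimental setups

| setup | DTC input | wild-type outcome |
|---|---|---|
| niche | constitutive, via self-activating auxiliary signal S0 | StemcellFate |
| losing | on at step 0, sustained ~3 steps by decaying relay S1→S2→S3, constrained off at step 20 | MeioticDev |
| reduced | on at step 0 only; auxiliary self-degrading signal SD ⊣ CYE1_CDK2 | MeioticDev |

All experiments run for 21 states (steps 0–20); step-0 values of every
unperturbed component are pinned (all off except the DTC and the
setup's auxiliary trigger), and outcomes are constrained at steps 19
and 20 to pin a steady final profile.
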