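# The 18 regulation-condition templates

A component's update depends only on the occupancy level of its
effective activators and repressors, each coarsened to
`none < some < all`.  A regulation condition is a Boolean table over the
3×3 grid of (activator level, repressor level) that is non-decreasing in
the activator level, non-increasing in the repressor level, and not
constant.  Of the 512 possible grid tables, 20 are monotone and 2 of
those are constant, leaving exactly 18 templates.

Ordering: the 18 tables are sorted by their 9-bit truth table read in
activator-major cell order `(none,none), (none,some), (none,all),
(some,none), …, (all,all)` with false before true, and the table

```
AllActivators ∨ (NoRepressors ∧ ¬NoActivators)
```

is pinned at index 5 (under this canonical sort it already lands there,
so the pinning swap is the identity).  The table below is generated by
`abnsynth.conditions.enumerate_regulation_conditions()` and asserted in
the test suite.

Degenerate convention: a regulator class with zero effective members has
level `none` — "all activators active" is never reported vacuously, so a
component whose activators are absent cannot switch on through an
all-activators clause, and a component with an empty effective incoming
edge set decays to inactive (persistent inputs need a self-loop).

| index | a=none,r=none | a=none,r=some | a=none,r=all | a=some,r=none | a=some,r=some | a=some,r=all | a=all,r=none | a=all,r=some | a=all,r=all |
|---|---|---|---|---|---|---|---|---|---|
| 0 | 0 | 0 | 0 | 0 | 0 | 0 | 1 | 0 | 0 |
| 1 | 0 | 0 | 0 | 0 | 0 | 0 | 1 | 1 | 0 |
| 2 | 0 | 0 | 0 | 0 | 0 | 0 | 1 | 1 | 1 |
| 3 | 0 | 0 | 0 | 1 | 0 | 0 | 1 | 0 | 0 |
| 4 | 0 | 0 | 0 | 1 | 0 | 0 | 1 | 1 | 0 |
| 5 | 0 | 0 | 0 | 1 | 0 | 0 | 1 | 1 | 1 |
| 6 | 0 | 0 | 0 | 1 | 1 | 0 | 1 | 1 | 0 |
| 7 | 0 | 0 | 0 | 1 | 1 | 0 | 1 | 1 | 1 |
| 8 | 0 | 0 | 0 | 1 | 1 | 1 | 1 | 1 | 1 |
| 9 | 1 | 0 | 0 | 1 | 0 | 0 | 1 | 0 | 0 |
| 10 | 1 | 0 | 0 | 1 | 0 | 0 | 1 | 1 | 0 |
| 11 | 1 | 0 | 0 | 1 | 0 | 0 | 1 | 1 | 1 |
| 12 | 1 | 0 | 0 | 1 | 1 | 0 | 1 | 1 | 0 |
| 13 | 1 | 0 | 0 | 1 | 1 | 0 | 1 | 1 | 1 |
| 14 | 1 | 0 | 0 | 1 | 1 | 1 | 1 | 1 | 1 |
| 15 | 1 | 1 | 0 | 1 | 1 | 0 | 1 | 1 | 0 |
| 16 | 1 | 1 | 0 | 1 | 1 | 0 | 1 | 1 | 1 |
| 17 | 1 | 1 | 0 | 1 | 1 | 1 | 1 | 1 | 1 |

Frequently used templates, by semantics (see
`abnsynth.conditions.semantic_index`):

| name | index | reads |
|---|---|---|
| all_activators_no_repressors | 0 | AND of activators, vetoed by any repressor |
| all_activators | 2 | AND of activators, repressor-blind |
| some_activators_no_repressors | 3 | OR of activators, vetoed by any repressor |
| index 5 | 5 | all activators, or some activators with no repressors |
| some_activators | 8 | OR of activators, repressor-blind |
| no_repressors | 9 | on unless repressed (activator-blind) |
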