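# Methods

## Setting

A metabolic network is a stoichiometric matrix `S ∈ R^(m×n)` with flux
bounds `l ≤ v ≤ u` and a set `Irrev` of irreversible reactions
(`l_i ≥ 0`). Two flux spaces matter:

- the **flux polyhedron** `C = {v | S v = 0, l ≤ v ≤ u}` — used by the
  MILP, FVA and essentiality;
- the **flux cone** `C0 = {v | S v = 0, v_i ≥ 0 for i ∈ Irrev}` — used
  for blockedness and flux coupling. `C0` is a cone, so LP tests box it
  into `[-1, 1]` without changing which fluxes can be nonzero.

A **subnetwork** is a reaction subset `A`; fluxes outside `A` are fixed
to zero. A reaction is *active* in a flux vector when `|v_i| ≥ δ` for a
small threshold `δ` (default `1e-4`, recommended range `1e-6 … 1e-4`).

## Requirements

A reduction scenario demands that the subnetwork support

1. **protected reactions** `P^Rxn`: each can carry `|v_i| ≥ δ`;
2. **protected metabolites** `P^Met`: each keeps an active reaction
   touching it (metabolites already touched by a protected reaction are
   covered by construction and need no constraint of their own);
3. **functionalities** `F = {f_1, …, f_k}`: linear systems
   `D_f v ≤ d_f`, each satisfiable by *its own* flux vector inside the
   subnetwork;
4. **degrees of freedom** `dof(A) = |A| − rank(S[:, A]) ≥ dof_min`.

Fraction-of-optimum functionalities ("≥ γ of the maximal biomass flux,
optionally under fixing constraints") are resolved into explicit rows by
one LP before building the MILP.

## Single-copy MILP (MinNW-0)

One flux vector `v`, binary `a_i` per reaction (plus `ā_i` for reversible
reactions, flagging backward activity):

```
irreversible:  δ a_i          ≤ v_i ≤ M a_i
reversible:    δ a_i − M ā_i  ≤ v_i ≤ M a_i − δ ā_i ,   a_i + ā_i ≤ 1
protected rxn: a_i = 1  (irreversible)  /  a_i + ā_i = 1  (reversible)
protected met: Σ_{i ∈ Rxn_m} (a_i + ā_i) ≥ 1
minimize       Σ (a_i + ā_i)
```

All functionality rows bind the single copy, so contradictory conditions
(e.g. `v_o2 ≥ 0.1` and `v_o2 = 0`) make MinNW-0 infeasible. That is not a
bug of the encoding but a fact about single flux distributions — and the
reason for the multi-copy formulation.

## Multi-copy MILP (minNW)

One flux copy `v^j` per functionality plus copy 0 for the protected
sets; per-copy binaries `a_i^j, ā_i^j` with the same activity links as
above, and **aggregated** binaries `a_i` tied by

```
a_i ≤ Σ_j (a_i^j + ā_i^j) ≤ c · a_i      (c = number of indicator slots)
minimize Σ_i a_i
```

so `a_i = 1` iff reaction `i` is active in *some* copy. Copy `j ≥ 1`
carries the rows `D_j v^j ≤ d_j`; copy 0 carries the protected-set
constraints. The active set of the optimal solution is
`A = {i | a_i = 1}`.

## Class-level variables (minNW_rep)

Reactions `r, s` are **partially coupled** over `C0` when `v_r = 0 ⇔
v_s = 0`; this is an equivalence relation whose classes are computed by

1. seeding: rows of a nullspace basis of `S` that are proportional with
   nonzero ratio imply `v_r = λ v_s` on all of `C0` — merged without LPs;
2. definitional LP tests between seed representatives (`max/min v_r`
   over `C0 ∩ {v_s = 0}` boxed into `[-1,1]`), with union-find
   transitivity pruning.

All members of a class are active or inactive together in every
subnetwork, so minNW_rep uses one binary family per class, weighting the
objective with class sizes: `min Σ |[r]| a_[r]`. The representative of a
class is chosen irreversible whenever the class contains an irreversible
member; members whose sign convention can disagree with the
representative get *zero-links* only (`inactive ⇒ v = 0`), since their
nonzeroness when the class is active already follows from coupling —
a shared `δ`-sign constraint for them would be unsound.

`minNW_rep` requires a blocked-free network; `preprocess_network`
removes dead ends and blocked reactions first, and `project_scenario`
restricts a scenario to the reduced network (exact, because removed
reactions carry zero flux in every steady state).

## Encodings

Both materialize `a_i = 0 ⇒ v_i = 0` and `a_i = 1 ⇒ v_i ≥ δ`
(resp. `ā_i = 1 ⇒ v_i ≤ −δ`):

- **bigM**: the textbook rows above with a single global constant
  `M = max(1000, max finite |bound|)`; infinite bounds are capped at `M`
  in the encoding only, never in the model.
- **indicator** (default): the same implications compiled with each
  reaction's own finite bounds `U_i = min(u_i, M)`, `L_i = max(l_i, −M)`
  as tight constants — the standard reformulation that
  indicator-capable solvers apply internally. Much better conditioned,
  since `δ/U_i` is far larger than `δ/M`.

## Enumeration, dof filter

Alternative minima are enumerated by **integer cuts**: after each
solution with activity pattern `Z`,

```
Σ_{i: Z_i=0} a_i + Σ_{i: Z_i=1} (1 − a_i) ≥ 1
```

forbids exactly that pattern. Enumeration stops with a completeness
certificate (`exhausted=True`) as soon as the post-cut optimum strictly
exceeds the minimum size, or the problem becomes infeasible. Solutions
with `dof < dof_min` are cut but not counted; the reported minimum size
is the smallest among dof-passing solutions. In class space the cuts act
on class binaries, which separates the same solution families because
active sets are unions of classes.

## Solver robustness

The only MILP backend is GLPK (via swiglpk); all plain LPs go through
scipy's HiGHS, keeping oracle LPs independent of the MILP path. Three
GLPK behaviours required explicit handling, all rooted in δ-scale
coefficients sitting near solver tolerances:

1. the MIP presolver silently drops `v − δa ≥ 0` rows → presolve off,
   explicit relaxation solve;
2. the default integer tolerance `1e-5` accepts a binary at `δ/U` as
   integral → `tol_int = 1e-9`;
3. in bigM mode (`δ/M = 1e-7`) branch-and-bound occasionally accepts an
   incumbent whose binary assignment is infeasible → every incumbent is
   re-verified by a cold-started LP with binaries fixed; verified
   incumbents yield polished witnesses, unverifiable ones are removed by
   a no-good cut and the MILP is re-solved (sound: only infeasible
   patterns are cut).

Every returned solution is additionally cross-checked in Python:
witnesses satisfy steady state and functionality rows to `1e-6`,
activity flags match the witness fluxes, and per-link implication
semantics hold.

## Independent oracle

`fixtures.brute_force_minimum_subnetworks` re-derives minimum
subnetworks without the MILP (guarded to ≤ 16 reactions): subsets are
enumerated size-ascending; a subset is feasible when each functionality
admits an LP witness vanishing outside it, the protected sets admit a
joint witness (searching over sign/choice combinations), every member
can reach `|v| ≥ δ` on some copy, and joint per-copy witnesses confirm
simultaneous activity (maximal assignment first, then exclusive demands
plus greedy completion). Candidate and necessity pre-filters (reactions
never δ-activatable; reactions whose removal breaks a copy) keep the
search tractable. The acceptance suite shows exact agreement of solution
*families* on 100 seeded random networks.

## Supporting analyses

- **FVA**: per-reaction flux ranges over `C` (optionally under extra
  rows).
- **Essential reactions**: knockout (`v_i = 0`) drops the maximal
  objective below `p%` of its optimum (default `p = 20`). Every reaction
  essential at level `p` belongs to every minimum subnetwork whose
  scenario demands ≥ `p%` of that optimum — verified in the acceptance
  suite.
- **Comparison report**: core (intersection) and union across enumerated
  minima, per-reaction occurrence counts, and exact mutually-exclusive /
  always-together pair patterns among non-core reactions.
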