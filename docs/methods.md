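# Methods

This note records the models, algorithms, defaults, and design choices
behind `gemcurate`, and what its synthetic test beds do and do not show
about real genome-scale reconstructions.

## The underlying model

A metabolic model is a stoichiometric matrix `S` (metabolites × reactions),
flux bounds `LB_j ≤ v_j ≤ UB_j` in mmol gDW⁻¹ h⁻¹, a boolean
gene–protein–reaction (GPR) rule per reaction, and designated biomass and
ATP-maintenance (ATPM) reactions. Flux balance analysis (FBA) maximizes
the biomass flux subject to steady state (`S v = 0`) and the bounds.
Conventions follow BiGG practice: the global bound is 1000, irreversible
reactions have `LB = 0`, and uptake through an exchange written as
`met_e ↔` is negative flux, so an uptake limit `L` sets `LB = −L`.

Media are applied by closing every exchange, opening the listed uptakes
(glucose 10, oxygen 2 in the genome-scale presets; trace vitamins and
auxotrophy supplements at a low configurable level, default 0.5 — low
enough not to act as a carbon source at toy scale), and fixing ATPM
(default 1). A strain background (e.g. the his3/leu2/met15/ura3
auxotrophic background of the reference yeast screens) is recorded on the
model and unioned into every deletion query.

**Viability.** A mutant is called non-growing (NG) when its biomass
optimum is *strictly* below 1% of the wild-type optimum, with an absolute
guard of 1e-6 against LP noise. Strictness at equality is a choice; the
threshold itself (1%) is the standard in-silico lethality cutoff.

## GPR logic and the gene-indicator bound encoding

GPR rules are parsed into AND/OR trees (AND binds tighter; keywords are
case-insensitive). Deletion semantics are plain boolean evaluation with
deleted genes false; an empty rule is always active; a reaction with no
rule receives a *fictitious* always-active gene so that suppression
machinery treats every reaction uniformly.

To let binary gene indicators `w_k ∈ {0,1}` act directly on fluxes
without auxiliary per-reaction binaries, each rule is converted to CNF
(clauses = gene sets; the rule is active iff every clause keeps one
active gene) and each clause `C` of reaction `j` contributes the row

    (Σ_{k∈C} w_k)·LB_j ≤ v_j ≤ (Σ_{k∈C} w_k)·UB_j.

Whenever some clause has more than one gene, the plain row
`LB_j ≤ v_j ≤ UB_j` is added, because a summed coefficient > 1 loosens
the clause row beyond the true bounds; the rows are implemented exactly
in this summed form rather than as `min(1, Σw)`. With all genes active
the feasible interval is exactly `[LB_j, UB_j]`; with any clause fully
knocked out it collapses to `[0, 0]`. This equivalence is enforced by an
exhaustive 2^g property test for rules of up to 8 genes.

CNF conversion distributes OR over AND and can blow up; it is capped
(default 16 genes / 256 clauses). Past the cap, the affected reaction
falls back to a reaction-level indicator (its fictitious gene) with a
warning. A degenerate corner: a reaction with `LB_j > 0` (a forced flux)
under a fully knocked-out multi-gene clause yields an infeasible LP
rather than `v_j = 0`; both outcomes mean "no growth", and forced-flux
reactions (ATPM) are never given gene rows in the solvers here.

## Screens

Essentiality screens test every gene (or clamp every reaction) with one
LP each; results with identical inactivated-reaction sets share a cached
LP. SL-pair enumeration is exhaustive over pairs of individually viable
genes with two *provably neutral* prunings: genes in no GPR cannot
matter, and a pair whose inactivated-reaction set equals one member's own
inherits that member's viable verdict. Pruned and unpruned enumeration
are asserted equal on the test fixtures. A bilevel SL search could reuse
the suppression machinery; exhaustive enumeration is the reference
because it is exact and desk-tractable at the scales involved.

## Gap detection

Blocked reactions are found by per-reaction flux variability (max and
min LPs); metabolite status by a temporary unit sink (producibility) and
source (consumability) per metabolite. This LP sweep is the exactly
verifiable equivalent of the classical MILP gap-finding formulation, and
is preferred here for that reason. A problem metabolite is *downstream*
if repairing some other single problem metabolite (adding its sink or
source) clears it, and a *root* otherwise; adding sinks for all
no-consumption roots provably clears the downstream flags on the test
networks.

## Mismatch taxonomy and metrics

Single-gene comparisons concatenate the in-silico and in-vivo verdicts:
GG, NGG, GNG, NGNG (prediction first). Pairs use G / ES (a gene
essential) / SL (only the pair lethal) on both sides, giving nine
labels; the diagonal is consistent. Metrics, as percentages rounded
half-up to two decimals:

    specificity = #NGNG / (#NGNG + #GNG)
    sensitivity (TVR) = #GG / (#GG + #NGG)
    FVR = 100% − specificity
    pair specificity = #SLSL / (#SLSL + #ESSL + #GSL)

Calls naming genes absent from the model are excluded from the
denominators and reported separately. Empty denominators leave a metric
undefined (reported as absent, never 0).

## Restoration (falsely lethal mutants)

A mutant NG in silico but viable in vivo points to missing capability.
Candidates: (i) relaxing an irreversibility (`LB 0 → −1000`), (ii) a
reaction from a flat candidate database (KEGG-style equations, TSV
`id <TAB> equation`), (iii) generated transports (compartment ↔ cytosol)
and exchanges. One binary per candidate gates its flux with big-M = 1000
— the global bound, so gating is exact, not approximate. The MILP
minimizes the number of enabled candidates subject to the mutant
reaching the viability threshold; all minimal-cardinality solutions are
enumerated with integer cuts (capped at 10 per mismatch) and each is
re-verified by plain FBA on the edited model. Medium-level fixes
(opening an uptake, stubbing an exchange/transport pair for an
internal-only compound) are handled separately so that a wrong *medium
description* is not "fixed" by editing the network.

Auxotrophy rescue checks use the model's existing import machinery by
default: a compound that exists only inside the cell cannot be imported,
so the in-silico rescue fails and the case is reported inconsistent —
the restoration engine can then propose the missing exchange/transport
pair. An `add_missing_routes` flag gives the post-restoration semantics.

## Suppression (falsely viable mutants): the bilevel search

A mutant viable in silico but lethal in vivo calls for regulatory or
structural suppression. The search problem is bilevel:

    min_w  [ max_v  v_biomass  s.t.  S v = 0, GPR bound rows(w), bounds ]
    s.t.   Σ_k (1 − w_k) ≤ n,   w binary,

with `n ≤ 2` by default. The inner LP is dualized; the products of `w`
with inner duals are linearized exactly by standard binary big-M rows,
with all duals bounded by a cap (default 1e4). Because outer and dual
both minimize, strong duality needs no explicit constraint: the joint
minimum over `(w, duals)` of the dual objective equals the minimum over
`w` of the inner optimum. Choices the formulation leaves open, decided
here:

- **Dual cap.** Bounded duals keep the MILP bounded even when some `w`
  makes the inner LP infeasible (ATPM unsatisfiable — which *is* a
  lethal outcome). A post-hoc check warns if a dual with nonzero
  objective weight lands within 1% of the cap; cost-free duals (on dead
  reactions) may float to the cap harmlessly.
- **Minimal cardinality.** Rather than a tie-breaking secondary
  objective, the budget is iterated n = 1, 2, …; the first cardinality
  admitting a solution is minimal by construction, and same-cardinality
  alternates are enumerated with integer cuts.
- **Candidate universe.** All genes of active reactions, minus the
  mutant's own deletions and the strain background (suppressing those is
  vacuous or contradicts the strain); bare reactions join through their
  fictitious genes (exchanges, biomass, ATPM exempt). Candidates whose
  lone suppression already kills the *wild type* are excluded: they
  would flip every correct viable prediction and can never be global.
- **Verification.** Every solution is re-solved by direct FBA with the
  suppressions applied; the reported inner optimum must agree within
  1e-6 (the strong-duality check in the test suite).

Reaction-level suppression is the same machinery with one indicator per
candidate reaction. For `n ≤ 2` an exhaustive subset enumerator over the
identical candidate universe doubles as an independent oracle and as a
fallback when MILP numerics are suspect.

## Modifications, vetting, batch curation

Every proposed correction is a typed `Modification` (suppression,
addition, relaxation, GPR rewrite, biomass substitute or proxy pool,
medium component) carrying a provenance tag
(`supported` / `uncorroborated` / `rejected`) for the human
literature-vetting loop; machine-found fixes default to uncorroborated.
Application returns an edited copy plus a snapshot inverse, so edits
roll back exactly.

A modification is **global** when a full re-screen against the phenotype
table flips no previously correct prediction, and **conditional**
otherwise; verdicts are tracked per medium, since a suppression can be
conditional in a poor medium yet global in a rich one (the poor medium
forces the suppressed function to back up another route).

`batch_curate` visits mismatch classes in a fixed order — NGG, GNG, GSL,
ESSL, SLG, SLES — restoration engines for the falsely lethal classes,
suppression engines for the falsely viable ones, lexicographic gene
order within a class. Only global, non-rejected modifications are
accepted, and the working model is re-baselined after each acceptance,
so curation is sequential and order-dependent by design (the order is
fixed and logged; replay is deterministic). Under the global-only rule
the specificity metrics cannot decrease — a property the suite asserts.

## The synthetic generator

`generate_fixture` composes motifs on a glucose-fed linear backbone with
an ATPM drain, one biomass precursor per planted feature: a unique
essential gene; an OR-isozyme SL pair; a parallel-pathway SL pair; a
blocked dead-end chain rooted in a no-consumption metabolite; a falsely
lethal mutant with a matching database rescue; a falsely viable mutant
fixed by suppressing its isozyme partner; a falsely viable pair fixed by
suppressing a gene-free bypass. Decoy genes gate only redundant backbone
bridges, so they can never create unplanned lethals. Matching
experimental calls are emitted so classification yields exactly the
planted mismatch classes. Generation is deterministic per seed
(byte-identical SBML), and the planted truth is re-derived by the
exhaustive screens before a fixture is returned — a fixture that fails
its own audit raises instead of lying.

What the generator does *not* emulate: genome-scale size (tens of genes,
not ~900), realistic biomass stoichiometry, cofactor and redox coupling,
more than three compartments, measurement noise or genuinely ambiguous
GPRs. Passing tests therefore demonstrate algorithmic correctness
(optimality, equivalence with enumeration, metric identities), not
predictive accuracy on real reconstructions; the benchmark harness
accepts a user-supplied genome-scale SBML model and phenotype tables for
that purpose and never downloads them itself.

Problem sizes in the shipped tests and acceptance script — fixtures of
≤ 15 genes / ~20 reactions, 20–50 seeds, 200 random GPR rules — were
chosen so every optimizer can be checked against exhaustive enumeration
exactly.

## Numerical choices

- LP/MILP solver: HiGHS via `scipy.optimize` (`linprog` / `milp`),
  sparse constraints, deterministic variable order (model order for
  reactions, sorted candidates).
- Viability: strict `<` with absolute tolerance 1e-6 on biomass.
- Flux-zero tolerance in gap detection: 1e-9.
- Big-M: 1000 (the global flux bound) for candidate gating; dual cap 1e4
  in the bilevel MILP with the post-hoc cap check.
- Percentages: two decimals, rounded half-up.
- Gene identifiers are compared case-sensitively and never renamed;
  compartment suffixes (`_c`, `_e`, …) are preserved verbatim.

## Known limitations

- CNF conversion of adversarial deep GPRs can exceed the clause cap; the
  reaction then participates only at reaction level (with a warning).
- The root/downstream split repairs one metabolite at a time; metabolite
  pairs that only clear jointly are both reported as roots.
- `batch_curate` covers the six growth-mismatch classes; auxotrophy
  inconsistencies are handled by `auxotrophy_check` / `resolve_medium`
  per case rather than inside the batch loop.
- No parsimonious FBA, MOMA/ROOM, flux variability beyond gap detection,
  or triple-and-higher lethals.
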