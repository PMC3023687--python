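# gemcurate

Reconciling genome-scale metabolic models with gene essentiality and
synthetic-lethality data.

Constraint-based metabolic models predict mutant growth by flux balance
analysis (FBA): maximize the biomass flux `v_biomass` subject to steady
state `S v = 0` and bounds `LB_j ≤ v_j ≤ UB_j`, with a gene deletion
acting through the reaction's boolean gene–protein–reaction (GPR) rule.
Screened against experimental knockout data, such models are often far
better at predicting *viable* mutants than *lethal* ones, and every
disagreement is a curation lead. `gemcurate` is a toolkit for working
those leads systematically:

- **Screens** — single-gene / single-reaction essentiality (1% of
  wild-type biomass as the viability threshold) and exhaustive
  synthetic-lethal (SL) pair enumeration.
- **Classification** — mismatch taxonomy GG/NGG/GNG/NGNG for single
  deletions and G/ES/SL pairs (GSL, ESSL, SLG, SLES, …) for double
  deletions, with specificity = #NGNG/(#NGNG+#GNG), sensitivity,
  FVR, and pair specificity = #SLSL/(#SLSL+#ESSL+#GSL).
- **Gap detection** — blocked reactions and no-production /
  no-consumption metabolites, with root vs downstream assignment.
- **Restoration** — a falsely lethal mutant (NGG) is fixed by the
  fewest model additions: irreversibility relaxations, candidate
  database reactions, transports and exchanges, found by MILP with
  exact big-M gating and integer-cut enumeration of alternates.
- **Suppression** — a falsely viable mutant (GNG/GSL) is fixed by the
  minimal set of gene or reaction suppressions that drops its biomass
  below threshold. Gene-level search solves the bilevel program

      min_w [ max_v v_biomass : S v = 0, (Σ_{k∈C} w_k)·LB_j ≤ v_j ≤ (Σ_{k∈C} w_k)·UB_j ]
      s.t. Σ_k (1 − w_k) ≤ n,  w ∈ {0,1}

  by dualizing the inner LP into a single MILP — gene binaries act
  directly on flux bounds through per-CNF-clause rows, with no
  auxiliary reaction binaries.
- **Vetting and curation** — every proposed edit is re-screened against
  the full phenotype table and classed *global* (flips no correct
  prediction) or *conditional*, per medium; `batch_curate` resolves a
  mismatch list in a fixed order accepting only global fixes, so
  accuracy can only improve.
- **Fixtures** — a deterministic generator of toy networks with planted
  essentials, SL pairs, dead ends, and fixable mismatches, audited
  against exhaustive oracles at generation time.

## Worked example

```python
from gemcurate import (apply_medium, essential_genes, find_sl_pairs,
                       generate_fixture, min_gene_suppressions)
from gemcurate.fixtures import FixtureSpec

fx = generate_fixture(FixtureSpec(seed=1))
model = apply_medium(fx.model, fx.medium)

screen = essential_genes(model)
print(sorted(screen.essential_genes))        # ['gE0', 'gN0']
pairs = find_sl_pairs(model, single_screen=screen)
print(sorted(map(sorted, pairs.pairs)))
# [['gGi0', 'gGm0'], ['gIa0', 'gIb0'], ['gPa0', 'gPb0']]

# gGm0 grows in silico but is lethal in vivo (a GNG): find the fix
for sol in min_gene_suppressions(model, ("gGm0",), n=2):
    print(sorted(sol.suppressed), round(sol.verified_biomass, 3))
# ['gGi0'] 0.0
```

The screen says genes `gE0` and `gN0` are essential in this toy (each
uniquely makes a biomass precursor) and finds three SL pairs. The
falsely viable mutant `gGm0` survives in silico through its isozyme
partner; suppressing that partner (`gGi0`) drives the mutant's biomass
to 0 — below the 1% viability threshold — and is the unique one-gene
fix, which vetting then classifies as global.

The `examples/` directory has one short script per capability
(screens, classification, gaps, restoration, suppression, batch
curation); each prints what it computes and asserts the planted ground
truth. A thin CLI mirrors the library:

```sh
gemcurate fixtures --seed 1 --out suite/
gemcurate screen essential --model suite/model.xml --medium suite/medium.cfg
gemcurate suppress --model suite/model.xml --medium suite/medium.cfg \
    --delete gGm0 --level gene
gemcurate benchmark --seed 1 --curate          # fixtures-only smoke run
```

Genome-scale runs take a user-supplied SBML model (fbc or legacy notes
GPRs) plus phenotype tables; nothing is downloaded by the package.

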