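"""Fixing a falsely viable mutant (GNG/GSL) by minimal suppressions.

The bilevel program minimizes, over binary gene-activity indicators
w_k with at most n suppressions, the mutant's inner FBA optimum; gene
indicators reach the fluxes through summed-indicator GPR bound rows,
and the bilevel problem is collapsed to one MILP by LP duality.  Every
solution is re-verified by a direct FBA (a strong-duality check).
"""

from gemcurate import apply_medium, min_gene_suppressions, min_reaction_suppressions
from gemcurate.fixtures import isozyme_triple_fixture, ump_salvage_fixture

# three isozymes on an essential reaction; two deleted -> suppress the third
fx = isozyme_triple_fixture()
model = apply_medium(fx.model, fx.medium)
pair = fx.ground_truth["target_pair"]
for sol in min_gene_suppressions(model, pair, n=2):
    print(f"gene-level fix for {pair}: suppress {sorted(sol.suppressed)} "
          f"(biomass {sol.verified_biomass:.3f}, duality gap "
          f"{abs(sol.biomass - sol.verified_biomass):.2e})")

# a gene-free salvage bypass sustains a falsely viable pair;
# reaction-level search pinpoints it (and hints the reaction may be
# erroneously included, since nothing encodes it)
fx = ump_salvage_fixture()
model = apply_medium(fx.model, fx.medium)
for sol in min_reaction_suppressions(model, fx.ground_truth["target_pair"], n=2):
    rid = next(iter(sol.suppressed))
    bare = fx.model.reaction(rid).gpr.is_empty
    print(f"reaction-level fix: suppress {rid} "
          f"({'no gene association - possibly mis-included' if bare else 'gene-backed'})")
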