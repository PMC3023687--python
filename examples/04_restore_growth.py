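"""Fixing a falsely lethal mutant (NGG) by minimal model additions.

The planted mutant is lethal in silico but grows in vivo, so the model
is missing a capability.  The restoration MILP switches on the fewest
candidate additions — irreversibility relaxations, database reactions,
transports, exchanges — that lift the mutant back over the viability
threshold, and re-verifies each solution by plain FBA.
"""

from gemcurate import apply_medium, build_candidate_pool, generate_fixture, restore_growth
from gemcurate.fixtures import FixtureSpec

fixture = generate_fixture(FixtureSpec(seed=1))
model = apply_medium(fixture.model, fixture.medium)

(genes, planted_fix), = fixture.ground_truth["mismatches"]["NGG"]
pool = build_candidate_pool(fixture.model, db_reactions=fixture.db_reactions)
print(f"mutant: {genes}; candidate pool size: {len(pool)}")

solutions = restore_growth(model, genes, pool, max_additions=2)
for sol in solutions:
    ids = ", ".join(c.id for c in sol.additions)
    print(f"  additions: [{ids}]  biomass after: {sol.verified_biomass:.3f}")

# the planted resolution is the single matching database reaction
assert any(
    {c.id for c in sol.additions} == {f"db:{planted_fix['reaction_id']}"}
    for sol in solutions
)
print("the planted database reaction is recovered as a minimal fix")
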