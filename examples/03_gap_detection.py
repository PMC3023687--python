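"""Finding blocked reactions and dead-end metabolites.

A reaction is blocked when no feasible steady-state flux can pass
through it; the usual culprit is a metabolite that nothing consumes
(or nothing produces).  Problem metabolites are split into roots —
whose repair (an added sink or source) clears the dependents — and
downstream casualties.
"""

from gemcurate import find_blocked_reactions, find_gap_metabolites, generate_fixture
from gemcurate.fixtures import FixtureSpec

fixture = generate_fixture(FixtureSpec(seed=1, n_blocked_chains=2))
report = find_gap_metabolites(fixture.model)

print("blocked reactions:", ", ".join(sorted(report.blocked_reactions)))
print("no-consumption metabolites:")
for met in sorted(report.no_consumption):
    print(f"  {met}\t{report.root_flags[met]}")

# Under a fixed medium more reactions can be blocked than under open
# uptake (e.g. a transporter whose substrate the medium lacks).
from gemcurate import apply_medium

constrained = apply_medium(fixture.model, fixture.medium)
fixed = find_blocked_reactions(constrained, "fixed_medium")
anyu = find_blocked_reactions(constrained, "any_uptake")
print(f"\nblocked under the fixed medium: {len(fixed)}; under any uptake: {len(anyu)}")
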