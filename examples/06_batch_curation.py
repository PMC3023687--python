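"""Batch curation with global-only acceptance.

Walks the classified mismatch list in a fixed order (falsely lethal
singles, falsely viable singles, then the pair classes), proposes
fixes with the restoration/suppression engines, vets each fix against
the whole phenotype table, and accepts only *global* modifications —
those that flip no correct prediction.  Conditional fixes are kept as
hypotheses.  Under this rule the accuracy metrics can only improve.
"""

from gemcurate import generate_fixture
from gemcurate.edits import batch_curate
from gemcurate.fixtures import FixtureSpec

fixture = generate_fixture(FixtureSpec(seed=1))
ledger = batch_curate(
    fixture.model, fixture.calls, [fixture.medium],
    db_reactions=fixture.db_reactions,
)

print("class  genes              verdict      accepted  modification")
for e in ledger.entries:
    mods = "; ".join(m.describe() for m in e.modifications) or "-"
    print(f"{e.mismatch_label:6s} {','.join(e.mismatch_genes):18s} "
          f"{e.verdict:12s} {str(e.accepted):9s} {mods}")

b, a = ledger.metrics_before, ledger.metrics_after
print(f"\nspecificity:      {b.specificity}% -> {a.specificity}%")
print(f"pair specificity: {b.double_specificity}% -> {a.double_specificity}%")
assert a.specificity >= b.specificity
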