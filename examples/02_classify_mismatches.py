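"""Classifying model-vs-experiment (mis)matches and computing metrics.

Compares in-silico deletion verdicts with experimental growth calls.
Single-gene outcomes are GG / NGG / GNG / NGNG (prediction first);
gene pairs use G / ES / SL on both sides.  Specificity is the fraction
of experimentally lethal mutants the model also calls lethal;
FVR (false viable rate) is its complement.
"""

from gemcurate import (
    apply_medium,
    classify_records,
    compute_metrics,
    essential_genes,
    find_sl_pairs,
    generate_fixture,
)
from gemcurate.fixtures import FixtureSpec

fixture = generate_fixture(FixtureSpec(seed=1))
model = apply_medium(fixture.model, fixture.medium)
screen = essential_genes(model)
sl = find_sl_pairs(model, single_screen=screen)

records, skipped = classify_records(
    fixture.calls, screen, sl, model_genes=model.genes
)
print("genes\t\tin-silico\tin-vivo\tclass")
for r in records:
    print(f"{','.join(r.genes):16s}{r.in_silico:8s}{r.in_vivo:8s}{r.label}")

metrics = compute_metrics(records)
print(f"\nspecificity: {metrics.specificity}%   (lethal calls the model got right)")
print(f"sensitivity: {metrics.sensitivity}%   (viable calls the model got right)")
print(f"FVR:         {metrics.fvr}%   (= 100% - specificity)")
print(f"pair specificity: {metrics.double_specificity}%")
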