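"""Score the two bundled product records and print their scorecards.

Each row shows the four domain scores and the composite:
adjusted efficacy (Hedges' g x significance multiplier), engagement
(fraction adhering to core modules), evidence quality (class-of-evidence
score), safety penalty, and cDTI = the product of the first three with
(1 - penalty). Higher is better everywhere except the penalty column.
"""

from cdti import builtin_fixture, score_record

header = f"{'Product':<10} {'AdjEff':>7} {'Engage':>7} {'Quality':>7} {'SafPen':>7} {'cDTI':>6}"
print(header)
for name in ("reset_o", "ct132"):
    card = score_record(builtin_fixture(name))
    print(
        f"{card.product_name:<10} {card.adjusted_efficacy:>7.4f} {card.engagement:>7.3f} "
        f"{card.evidence_quality:>7.2f} {card.safety_penalty:>7.2f} {card.cdti:>6.3f}"
    )
    quality = card.provenance["evidence_quality"]
    print(f"           Class {quality['class']}; safety tier: {card.provenance['safety']['tier_used']}")
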