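"""Compare two scored products: composite ratio and per-domain deltas.

The ratio is taken on the rounded 3-decimal composites, so it matches what
a reader computes from the printed scorecards; percent_of is the same ratio
expressed as a percentage.
"""

from cdti import builtin_fixture, compare_scorecards, score_record

ct132 = score_record(builtin_fixture("ct132"))
reset_o = score_record(builtin_fixture("reset_o"))
cmp = compare_scorecards(ct132, reset_o)

print(f"{cmp.product_a}: cDTI {cmp.cdti_a:.3f}   {cmp.product_b}: cDTI {cmp.cdti_b:.3f}")
print(f"ratio {cmp.ratio:.2f} ({cmp.percent_of}% of the comparator's composite)")
print("per-domain deltas (a - b):")
for domain, delta in cmp.domain_deltas.items():
    print(f"  {domain:<18} {delta:+.4f}")
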