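"""Score a hand-built record whose efficacy comes from raw group statistics.

When a trial publishes arm means, SDs and sizes instead of a ready-made
effect size, the efficacy engine computes Hedges' g itself (pooled-SD
Cohen's d with the small-sample correction) and normalizes the sign so that
positive means benefit — here the endpoint is symptom days, where lower is
better, so the negative raw difference becomes a positive effect.
"""

from cdti import TrialEvidenceRecord, score_record

record = TrialEvidenceRecord(
    product_name="demo-pdt",
    indication="insomnia",
    efficacy={
        "group_means": [7.1, 9.0],   # treatment vs control symptom days
        "group_sds": [4.2, 4.5],
        "group_ns": [120, 118],
        "benefit_direction": "lower_better",
        "p_value": 0.004,
    },
    engagement={"tier": "digital_usage", "proportion": 0.74},
    design={
        "randomized": True,
        "concealed_allocation": True,
        "patient_blinded": False,
        "assessor_blinded": True,
        "control_type": "active_comparator",
        "objective_or_masked_outcome": True,
        "retention_ge_80pct": True,
        "defined_primary_outcome": True,
        "explicit_eligibility": True,
        "methodological_deficiency": False,
    },
    safety={"tier": "delta_teae", "treatment_teae_rate": 0.12, "control_teae_rate": 0.15},
)

card = score_record(record)
eff = card.provenance["efficacy"]
print(f"Hedges' g (benefit-positive, from {eff['smd_source']}): {eff['smd']:.4f}")
print(f"significance tier: {eff['significance_tier']} (x{eff['multiplier']})")
print(f"adjusted efficacy {card.adjusted_efficacy:.4f}, engagement {card.engagement:.3f}")
print(f"evidence Class {card.provenance['evidence_quality']['class']} "
      f"(score {card.evidence_quality:.2f}), safety penalty {card.safety_penalty:.2f} "
      "(negative arm difference floors at zero)")
print(f"cDTI = {card.cdti:.3f}")
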