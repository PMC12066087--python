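{
  "product_name": "CT-132",
  "indication": "episodic migraine",
  "efficacy": {
    "reported_smd": 0.3,
    "mean_diff": -0.9,
    "total_n": 568,
    "benefit_direction": "lower_better",
    "p_value": 0.005
  },
  "engagement": {
    "tier": "module_completion",
    "proportion": 0.897,
    "adherence_threshold_note": "protocol-specified adherence threshold: task completion on at least 70% of days"
  },
  "design": {
    "randomized": true,
    "concealed_allocation": true,
    "patient_blinded": true,
    "assessor_blinded": true,
    "control_type": "sham_or_digital_placebo",
    "objective_or_masked_outcome": true,
    "retention_ge_80pct": true,
    "defined_primary_outcome": true,
    "explicit_eligibility": true,
    "methodological_deficiency": false,
    "noninferiority_criteria_unmet": false,
    "hybrid_pivotal_phase_only": false
  },
  "safety": {
    "tier": "pdt_related_teae",
    "pdt_related_rate": 0.0,
    "related_sae_present": false
  },
  "sources": [
    "FDA 510(k) summary for CT-132",
    "ReMMi-D pivotal randomized, double-blind, sham-controlled trial publication (monthly migraine days endpoint, ITT n=568)",
    "ClinicalTrials.gov registration for ReMMi-D"
  ]
}
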