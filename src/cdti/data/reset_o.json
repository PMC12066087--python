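{
  "product_name": "reSET-O",
  "indication": "opioid use disorder",
  "efficacy": {
    "reported_smd": 0.179,
    "mean_diff": 5.5,
    "total_n": 170,
    "benefit_direction": "higher_better",
    "p_value": 0.214
  },
  "engagement": {
    "tier": "module_completion",
    "completed_mean": 42.2,
    "available_total": 67
  },
  "design": {
    "randomized": true,
    "concealed_allocation": null,
    "patient_blinded": false,
    "assessor_blinded": null,
    "control_type": "usual_care",
    "objective_or_masked_outcome": true,
    "retention_ge_80pct": true,
    "defined_primary_outcome": true,
    "explicit_eligibility": true,
    "methodological_deficiency": true,
    "noninferiority_criteria_unmet": false,
    "hybrid_pivotal_phase_only": false
  },
  "safety": {
    "tier": "missing",
    "related_sae_present": null
  },
  "sources": [
    "FDA De Novo / clinician brief summary for reSET-O",
    "Pivotal randomized usual-care-controlled trial publication (longest continuous abstinence endpoint, n=170)",
    "ICER 2020 review of reSET-O"
  ]
}
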