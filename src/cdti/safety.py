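"""Safety penalty: tiered TEAE extraction, zero-flooring, SAE surcharge.

The safety domain is a penalty in [0, 1] entering the composite as
``1 - penalty``. Extraction follows a strict hierarchy:

1. PDT-related TEAE rate (events adjudicated/attributed to the device) —
   applied directly as the penalty;
2. delta-TEAE — treatment-arm minus control-arm TEAE rate;
3. treatment-only TEAE rate, when no control safety data exist;
4. nothing reported — a conservative default penalty of 0.20 is imputed.

A negative delta (fewer events on treatment than control) floors the penalty
at zero: no bonus is awarded for apparent safety benefit. A serious adverse
event plausibly related to the PDT adds a fixed 0.50 surcharge on top of
whatever base applies, including the imputed 0.20. When sources disagree on
the rate for the selected tier, the most conservative (highest) is applied.
Raw rates are used without normalization; the total is clamped to [0, 1] so
``1 - penalty`` stays non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import SafetyEvidence, SafetyTier

__all__ = [
    "SafetyPenalty",
    "select_safety_source",
    "safety_penalty",
    "IMPUTED_SAFETY_PENALTY",
    "SAE_SURCHARGE",
]

#: conservative default penalty when no TEAE data were reported
IMPUTED_SAFETY_PENALTY = 0.20
#: fixed surcharge for a PDT-related serious adverse event
SAE_SURCHARGE = 0.50


@dataclass(frozen=True)
class SafetyPenalty:
    penalty: float
    tier_used: SafetyTier
    sae_surcharge_applied: bool
    imputed: bool
    base_penalty: float = 0.0


def select_safety_source(evidence: SafetyEvidence) -> SafetyTier:
    """Pick the highest-priority safety tier whose data are present."""
    if evidence.pdt_related_rate is not None:
        return SafetyTier.pdt_related_teae
    if evidence.treatment_teae_rate is not None and evidence.control_teae_rate is not None:
        return SafetyTier.delta_teae
    if evidence.treatment_teae_rate is not None:
        return SafetyTier.treatment_only_teae
    return SafetyTier.missing


def _conservative(rate: float, evidence: SafetyEvidence) -> float:
    if evidence.alternate_rates:
        return max(rate, *evidence.alternate_rates)
    return rate


def safety_penalty(evidence: SafetyEvidence) -> SafetyPenalty:
    """Compute the safety penalty for one record's evidence."""
    tier = select_safety_source(evidence)
    imputed = False
    if tier is SafetyTier.pdt_related_teae:
        base = _conservative(evidence.pdt_related_rate, evidence)
    elif tier is SafetyTier.delta_teae:
        base = _conservative(
            evidence.treatment_teae_rate - evidence.control_teae_rate, evidence
        )
    elif tier is SafetyTier.treatment_only_teae:
        base = _conservative(evidence.treatment_teae_rate, evidence)
    else:
        base = IMPUTED_SAFETY_PENALTY
        imputed = True

    base = max(0.0, base)  # no bonus for apparent safety benefit
    surcharge = evidence.related_sae_present is True
    penalty = base + (SAE_SURCHARGE if surcharge else 0.0)
    penalty = min(1.0, penalty)
    return SafetyPenalty(
        penalty=penalty,
        tier_used=tier,
        sae_surcharge_applied=surcharge,
        imputed=imputed,
        base_penalty=base,
    )
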