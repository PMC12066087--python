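"""Composite Digital Therapeutic Index: combine the four domain scores.

The composite is multiplicative:

    cDTI = adjusted efficacy x engagement x evidence quality x (1 - safety penalty)

scaled 0 to 1, where higher is better and a zero in any domain zeroes the
index. Domain scores are rounded to their reported precision (efficacy 4
decimals, engagement 3, composite 3) before any ratio is taken, so printed
scorecards and their comparatives are internally consistent. A composite
above 1 (possible only when the adjusted efficacy itself exceeds ~1.12) is
clamped and flagged rather than rescaled.

The radar ("therapeutic fingerprint") export reports the four axes with the
safety axis inverted (1 - penalty) so that larger is better on every axis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Optional

from .efficacy import score_efficacy
from .engagement import engagement_score
from .evidence_quality import classify_trial
from .records import TrialEvidenceRecord
from .safety import safety_penalty

__all__ = [
    "CdtiScorecard",
    "ScorecardComparison",
    "compute_cdti",
    "score_record",
    "compare_scorecards",
    "radar_data",
    "RADAR_AXES",
]

#: radar axis order: all four are oriented so larger is better
RADAR_AXES = ("efficacy", "engagement", "evidence_quality", "inverted_safety")

_ALLOWED_QUALITY_SCORES = (1.00, 0.75, 0.50, 0.25)


@dataclass(frozen=True)
class CdtiScorecard:
    """The four domain scores and the composite for one product."""

    product_name: str
    adjusted_efficacy: float
    engagement: float
    evidence_quality: float
    safety_penalty: float
    inverted_safety: float
    cdti: float
    clamped: bool = False
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class ScorecardComparison:
    """Ratio/percent comparison of two scorecards plus per-domain deltas."""

    product_a: str
    product_b: str
    cdti_a: float
    cdti_b: float
    ratio: Optional[float]
    percent_of: Optional[int]
    ratio_undefined: bool
    domain_deltas: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def compute_cdti(
    adjusted_efficacy: float,
    engagement: float,
    evidence_quality: float,
    safety_penalty: float,
) -> tuple[float, bool]:
    """Multiplicative composite, rounded to 3 decimals and clamped to [0, 1].

    Returns ``(cdti, clamped)`` where ``clamped`` flags a composite that had
    to be truncated at 1.
    """
    if not 0.0 <= engagement <= 1.0:
        raise ValueError(f"engagement must lie in [0, 1], got {engagement}")
    if not 0.0 <= safety_penalty <= 1.0:
        raise ValueError(f"safety penalty must lie in [0, 1], got {safety_penalty}")
    if not any(abs(evidence_quality - s) < 1e-9 for s in _ALLOWED_QUALITY_SCORES):
        raise ValueError(
            f"evidence quality must be one of {_ALLOWED_QUALITY_SCORES}, got {evidence_quality}"
        )
    if adjusted_efficacy < 0:
        raise ValueError(f"adjusted efficacy must be >= 0, got {adjusted_efficacy}")
    raw = adjusted_efficacy * engagement * evidence_quality * (1.0 - safety_penalty)
    value = round(raw, 3)
    clamped = value > 1.0
    return (min(value, 1.0), clamped)


def score_record(record: TrialEvidenceRecord) -> CdtiScorecard:
    """Run the four domain engines on a record and assemble the scorecard."""
    eff = score_efficacy(record.efficacy)
    eng = engagement_score(record.engagement)
    quality = classify_trial(record.design)
    saf = safety_penalty(record.safety)

    adjusted = round(eff.adjusted, 4)
    cdti, clamped = compute_cdti(adjusted, eng.value, quality.score, saf.penalty)
    return CdtiScorecard(
        product_name=record.product_name,
        adjusted_efficacy=adjusted,
        engagement=eng.value,
        evidence_quality=quality.score,
        safety_penalty=saf.penalty,
        inverted_safety=1.0 - saf.penalty,
        cdti=cdti,
        clamped=clamped,
        provenance={
            "indication": record.indication,
            "efficacy": {
                "smd": eff.smd,
                "raw_smd": eff.raw_smd,
                "smd_source": eff.smd_source,
                "significance_tier": eff.tier.label.value,
                "multiplier": eff.tier.multiplier,
                "notes": eff.notes,
            },
            "engagement": {"tier_used": eng.tier_used.value, "imputed": eng.imputed},
            "evidence_quality": {
                "class": quality.class_label.value,
                "downgrade_reasons": quality.downgrade_reasons,
            },
            "safety": {
                "tier_used": saf.tier_used.value,
                "base_penalty": saf.base_penalty,
                "sae_surcharge_applied": saf.sae_surcharge_applied,
                "imputed": saf.imputed,
            },
        },
    )


def compare_scorecards(a: CdtiScorecard, b: CdtiScorecard) -> ScorecardComparison:
    """Compare two scorecards: composite ratio, percent-of, per-domain deltas.

    The ratio is taken on the rounded 3-decimal composites and reported to 2
    decimals; ``percent_of`` is the ratio as a percentage (rounded to an
    integer), i.e. 1287 means a.cdti is 12.87x b.cdti. A zero denominator
    yields an undefined ratio, never infinity.
    """
    undefined = b.cdti == 0
    ratio = None if undefined else round(a.cdti / b.cdti, 2)
    percent = None if undefined else round(ratio * 100)
    deltas = {
        "adjusted_efficacy": round(a.adjusted_efficacy - b.adjusted_efficacy, 4),
        "engagement": round(a.engagement - b.engagement, 3),
        "evidence_quality": round(a.evidence_quality - b.evidence_quality, 2),
        "safety_penalty": round(a.safety_penalty - b.safety_penalty, 3),
        "cdti": round(a.cdti - b.cdti, 3),
    }
    return ScorecardComparison(
        product_a=a.product_name,
        product_b=b.product_name,
        cdti_a=a.cdti,
        cdti_b=b.cdti,
        ratio=ratio,
        percent_of=percent,
        ratio_undefined=undefined,
        domain_deltas=deltas,
    )


def radar_data(scorecard: CdtiScorecard) -> tuple[float, float, float, float]:
    """Four radar axis values: efficacy, engagement, evidence quality,
    inverted safety (1 - penalty). Larger is better on every axis."""
    return (
        scorecard.adjusted_efficacy,
        scorecard.engagement,
        scorecard.evidence_quality,
        scorecard.inverted_safety,
    )
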