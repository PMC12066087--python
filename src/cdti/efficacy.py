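"""Adjusted efficacy: Hedges' g, benefit-direction normalization, and the
tiered statistical-significance multiplier.

The efficacy domain score is the standardized mean difference (SMD) on the
trial's prespecified primary endpoint, expressed as Hedges' g (a small-sample
bias-corrected Cohen's d), normalized so positive values always mean benefit,
then scaled by a multiplier keyed to the endpoint's p-value:

====================  ==========  ==========
significance            p range   multiplier
====================  ==========  ==========
very high             p < 0.001      1.15
high                  0.001–0.01     1.10
significant           0.01–0.05      1.00
not significant       p >= 0.05      0.50
====================  ==========  ==========

Tier boundaries are half-open on the left: p = 0.001 falls in the 1.10 tier,
p = 0.01 in the 1.00 tier, p = 0.05 in the 0.50 tier. When no p-value is
available, significance inferred from a confidence interval or the authors'
interpretation earns the neutral 1.00 multiplier; with no information at all
the result is assumed non-significant (0.50). The adjusted score is floored
at zero so a harmful effect cannot push the composite negative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from .records import (
    BenefitDirection,
    EfficacyEvidence,
    SignificanceInference,
)

__all__ = [
    "TierLabel",
    "SignificanceTier",
    "EfficacyScore",
    "EfficacyConsistencyError",
    "compute_hedges_g",
    "hedges_correction",
    "normalize_direction",
    "significance_tier",
    "adjusted_efficacy",
    "score_efficacy",
    "TIER_MULTIPLIERS",
]


class TierLabel(str, enum.Enum):
    very_high = "very_high"
    high = "high"
    significant = "significant"
    not_significant = "not_significant"


#: label -> multiplier mapping; the 1.15 entry is the maximum adjustment cap.
TIER_MULTIPLIERS: dict[TierLabel, float] = {
    TierLabel.very_high: 1.15,
    TierLabel.high: 1.10,
    TierLabel.significant: 1.00,
    TierLabel.not_significant: 0.50,
}


@dataclass(frozen=True)
class SignificanceTier:
    label: TierLabel
    multiplier: float

    def __post_init__(self):
        if not math.isclose(self.multiplier, TIER_MULTIPLIERS[self.label]):
            raise ValueError(
                f"tier {self.label.value} must carry multiplier "
                f"{TIER_MULTIPLIERS[self.label]}, got {self.multiplier}"
            )

    @classmethod
    def from_label(cls, label: TierLabel) -> "SignificanceTier":
        return cls(label, TIER_MULTIPLIERS[label])


@dataclass(frozen=True)
class EfficacyScore:
    """Outcome of the efficacy engine for one record.

    ``smd`` is benefit-positive; ``adjusted = max(0, smd * multiplier)``.
    ``raw_smd`` retains the signed value before flooring, for provenance.
    """

    smd: float
    tier: SignificanceTier
    adjusted: float
    raw_smd: float = 0.0
    smd_source: str = "reported"
    notes: list[str] = field(default_factory=list)


class EfficacyConsistencyError(ValueError):
    """Reported SMD and SMD recomputed from raw statistics disagree."""


def hedges_correction(df: int) -> float:
    """Small-sample bias correction J = 1 - 3/(4*df - 1)."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def compute_hedges_g(
    mean_a: float,
    mean_b: float,
    sd_a: float,
    sd_b: float,
    n_a: int,
    n_b: int,
) -> float:
    """Hedges' g for two independent groups.

    g = J * d with d = (mean_a - mean_b) / s_pooled,
    s_pooled = sqrt(((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2)),
    and J = 1 - 3/(4 (n_a + n_b - 2) - 1). The sign follows mean_a - mean_b.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        raise ZeroDivisionError("degenerate variance: both group SDs are zero")
    df = n_a + n_b - 2
    s_pooled = math.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df)
    d = (mean_a - mean_b) / s_pooled
    return hedges_correction(df) * d


def normalize_direction(smd: float, benefit_direction: BenefitDirection) -> float:
    """Flip the SMD sign so positive always means therapeutic benefit.

    For a lower-is-better endpoint (e.g. monthly migraine days) a treatment
    that reduces the endpoint has a negative raw SMD; normalization returns
    the benefit-positive value.
    """
    direction = BenefitDirection(benefit_direction)
    if direction is BenefitDirection.lower_better:
        return -smd
    return smd


def significance_tier(
    p_value: Optional[float] = None,
    inference: Optional[SignificanceInference] = None,
) -> SignificanceTier:
    """Map a p-value (or a fallback significance inference) to its tier."""
    if p_value is not None:
        if not 0.0 <= p_value <= 1.0:
            raise ValueError(f"p-value must lie in [0, 1], got {p_value}")
        if p_value < 0.001:
            return SignificanceTier.from_label(TierLabel.very_high)
        if p_value < 0.01:
            return SignificanceTier.from_label(TierLabel.high)
        if p_value < 0.05:
            return SignificanceTier.from_label(TierLabel.significant)
        return SignificanceTier.from_label(TierLabel.not_significant)
    if inference in (
        SignificanceInference.ci_excludes_null,
        SignificanceInference.reported_significant,
    ):
        # significant, but the exact tier is unknowable: use the neutral 1.00
        return SignificanceTier.from_label(TierLabel.significant)
    return SignificanceTier.from_label(TierLabel.not_significant)


def adjusted_efficacy(smd_benefit_positive: float, tier: SignificanceTier) -> float:
    """max(0, smd * multiplier); the floor keeps the composite in [0, 1]."""
    return max(0.0, smd_benefit_positive * tier.multiplier)


_CONSISTENCY_TOL = 0.005


def _smd_from_raw(evidence: EfficacyEvidence) -> Optional[tuple[float, str]]:
    """Benefit-positive SMD from raw statistics, if a computable path exists."""
    if (
        evidence.group_means is not None
        and evidence.group_sds is not None
        and evidence.group_ns is not None
    ):
        g = compute_hedges_g(
            evidence.group_means[0],
            evidence.group_means[1],
            evidence.group_sds[0],
            evidence.group_sds[1],
            evidence.group_ns[0],
            evidence.group_ns[1],
        )
        return normalize_direction(g, evidence.benefit_direction), "group_statistics"
    if evidence.mean_diff is not None and evidence.sd_pooled is not None:
        if evidence.group_ns is not None:
            df = evidence.group_ns[0] + evidence.group_ns[1] - 2
        elif evidence.total_n is not None:
            df = evidence.total_n - 2
        else:  # unreachable under schema validation
            return None
        d = evidence.mean_diff / evidence.sd_pooled
        g = hedges_correction(df) * d
        return normalize_direction(g, evidence.benefit_direction), "mean_difference"
    return None


def score_efficacy(evidence: EfficacyEvidence) -> EfficacyScore:
    """Run the full efficacy pipeline on one record's evidence.

    A curated ``reported_smd`` is used as-is (it is benefit-positive by
    curation convention). When raw statistics are the only path, Hedges' g is
    computed and direction-normalized here. If both are present and disagree
    by more than 0.005, an :class:`EfficacyConsistencyError` is raised rather
    than silently preferring one.
    """
    notes: list[str] = []
    raw = _smd_from_raw(evidence)
    if evidence.reported_smd is not None:
        smd, source = evidence.reported_smd, "reported"
        if raw is not None:
            recomputed, _ = raw
            if abs(recomputed - smd) > _CONSISTENCY_TOL:
                raise EfficacyConsistencyError(
                    f"reported SMD {smd} disagrees with SMD {recomputed:.4f} "
                    f"recomputed from raw statistics (tolerance {_CONSISTENCY_TOL})"
                )
            notes.append("reported SMD cross-checked against raw statistics")
    elif raw is not None:
        smd, source = raw
        notes.append(f"SMD computed from {source.replace('_', ' ')}")
    else:  # unreachable under schema validation
        raise ValueError("no sufficient statistics for an SMD")

    tier = significance_tier(evidence.p_value, evidence.significance_inference)
    if evidence.p_value is None:
        notes.append(
            "no exact p-value; significance "
            + (
                "inferred from CI/interpretation"
                if tier.label is TierLabel.significant
                else "assumed non-significant"
            )
        )
    return EfficacyScore(
        smd=smd,
        tier=tier,
        adjusted=adjusted_efficacy(smd, tier),
        raw_smd=smd,
        smd_source=source,
        notes=notes,
    )
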