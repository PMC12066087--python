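"""Engagement score: best-available adherence metric on a 0-1 scale.

Engagement is the proportion of participants completing the digital
intervention or adhering to its core therapeutic modules. Trials report this
heterogeneously, so extraction follows a four-level hierarchy that prefers
objective, reproducible measures:

1. objective module/task completion (counts or percentage completed),
2. digital usage data (logins, sessions, time-on-task) as a proxy,
3. clinician-assessed adherence,
4. study-defined treatment completion, a last-resort proxy.

All tiers normalize to a plain fraction; the tier label is recorded as
provenance but carries no discount. When no metric is reported at all, a
neutral 0.50 is imputed to minimize the bias introduced by missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import EngagementEvidence, EngagementTier

__all__ = ["EngagementScore", "select_engagement_source", "engagement_score", "IMPUTED_ENGAGEMENT"]

#: neutral midpoint assigned when no engagement metric was reported
IMPUTED_ENGAGEMENT = 0.50


@dataclass(frozen=True)
class EngagementScore:
    value: float
    tier_used: EngagementTier
    imputed: bool


def select_engagement_source(evidence: EngagementEvidence) -> EngagementTier:
    """Pick the highest-priority engagement tier with data present.

    Objective completion counts always win; otherwise the proportion counts
    for whichever tier the curator declared it under; with no data the tier
    is ``missing``.
    """
    if evidence.completed_mean is not None and evidence.available_total is not None:
        return EngagementTier.module_completion
    if evidence.proportion is not None:
        return evidence.tier
    return EngagementTier.missing


def engagement_score(evidence: EngagementEvidence) -> EngagementScore:
    """Engagement fraction in [0, 1], rounded to 3 decimals.

    Completion counts divide out (e.g. a mean of 42.2 of 67 modules gives
    0.630); a pre-normalized proportion passes through; a fully missing
    metric imputes the neutral 0.50.
    """
    tier = select_engagement_source(evidence)
    if tier is EngagementTier.missing:
        return EngagementScore(IMPUTED_ENGAGEMENT, EngagementTier.missing, imputed=True)
    if (
        tier is EngagementTier.module_completion
        and evidence.completed_mean is not None
        and evidence.available_total is not None
    ):
        if evidence.available_total == 0:
            raise ZeroDivisionError("available_total must be positive")
        value = evidence.completed_mean / evidence.available_total
    else:
        value = evidence.proportion
    return EngagementScore(round(value, 3), tier, imputed=False)
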