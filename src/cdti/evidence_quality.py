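"""Class-of-evidence rule engine: adapted AAN grading of PDT trial designs.

Trials are graded Class I (highest rigor) through Class IV using an adapted
American Academy of Neurology Class of Evidence framework, then mapped to a
numeric evidence-quality score:

    Class I  -> 1.00   randomized, concealed allocation, defined primary
                       outcome, explicit eligibility, >=80% retention, and
                       true double-blinding (patient AND outcome assessor)
                       against a sham/digital-placebo or blinded active
                       comparator
    Class II -> 0.75   as Class I but lacking full double-blinding, rescued
                       by masked assessment or an objective primary outcome,
                       with no methodological deficiency
    Class III-> 0.50   controlled but lacking adequate randomization,
                       masking or objectivity; waitlist controls; usual-care
                       controls with a methodological deficiency
    Class IV -> 0.25   no concurrent control (single-arm pre-post) or
                       otherwise below Class III

Additional grading rules: a non-inferiority trial that failed comparator
similarity / eligibility matching / observed-case requirements is downgraded
one class; when two sources grade the same trial differently the more
conservative (lower) class is assigned. Hybrid designs are graded on the
pivotal randomized phase only — the curator supplies that phase's features
and sets ``hybrid_pivotal_phase_only``.

Unknown (``None``) flags resolve conservatively: a quality feature that
cannot be established counts as absent, and an unassessable methodological-
deficiency judgement counts as a deficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import ClassLabel, ControlType, DesignFeatures

__all__ = ["EvidenceClass", "classify_trial", "class_score", "CLASS_SCORES"]

#: Class of Evidence -> numeric evidence-quality score
CLASS_SCORES: dict[ClassLabel, float] = {
    ClassLabel.I: 1.00,
    ClassLabel.II: 0.75,
    ClassLabel.III: 0.50,
    ClassLabel.IV: 0.25,
}

_RANK = {ClassLabel.I: 1, ClassLabel.II: 2, ClassLabel.III: 3, ClassLabel.IV: 4}
_BY_RANK = {v: k for k, v in _RANK.items()}


@dataclass(frozen=True)
class EvidenceClass:
    class_label: ClassLabel
    score: float
    downgrade_reasons: list[str] = field(default_factory=list)


def class_score(class_label: ClassLabel) -> float:
    """Numeric score for a class label (I/II/III/IV -> 1.00/0.75/0.50/0.25)."""
    return CLASS_SCORES[ClassLabel(class_label)]


def _quality(flag: bool | None) -> bool:
    # unknown quality feature counts as absent
    return bool(flag)


def _deficient(flag: bool | None) -> bool:
    # unknown deficiency judgement counts as deficient
    return flag is not False


def _base_class(design: DesignFeatures, reasons: list[str]) -> ClassLabel:
    control = design.control_type
    if control is ControlType.none:
        reasons.append("no concurrent control group (single-arm / pre-post)")
        return ClassLabel.IV
    if control is ControlType.waitlist:
        reasons.append("waitlist control: no active comparator, high expectancy-bias risk")
        return ClassLabel.III

    base_rigor = (
        _quality(design.randomized)
        and _quality(design.concealed_allocation)
        and _quality(design.defined_primary_outcome)
        and _quality(design.explicit_eligibility)
        and _quality(design.retention_ge_80pct)
    )
    double_blind = _quality(design.patient_blinded) and _quality(design.assessor_blinded)
    blindable_control = control in (
        ControlType.sham_or_digital_placebo,
        ControlType.active_comparator,
    )
    if base_rigor and double_blind and blindable_control:
        return ClassLabel.I
    if (
        base_rigor
        and (_quality(design.assessor_blinded) or _quality(design.objective_or_masked_outcome))
        and not _deficient(design.methodological_deficiency)
    ):
        reasons.append("lacking full double-blinding; masked/objective outcome retained")
        return ClassLabel.II
    if control is ControlType.usual_care and _deficient(design.methodological_deficiency):
        reasons.append("usual-care control with methodological deficiency")
        return ClassLabel.III
    reasons.append("controlled but lacking adequate randomization, masking or objectivity")
    return ClassLabel.III


def _downgrade(label: ClassLabel, steps: int = 1) -> ClassLabel:
    return _BY_RANK[min(_RANK[label] + steps, 4)]


def classify_trial(design: DesignFeatures) -> EvidenceClass:
    """Grade a trial design into an :class:`EvidenceClass`.

    Deterministic: the same features always yield the same class. Every
    downgrade or conservative resolution is recorded in
    ``downgrade_reasons``.
    """
    reasons: list[str] = []
    label = _base_class(design, reasons)

    if design.noninferiority_criteria_unmet is True:
        downgraded = _downgrade(label)
        reasons.append(
            "non-inferiority criteria unmet: automatic downgrade "
            f"{label.value} -> {downgraded.value}"
        )
        label = downgraded

    if design.conflicting_source_classes is not None:
        worst_source = _BY_RANK[max(_RANK[ClassLabel(c)] for c in design.conflicting_source_classes)]
        if _RANK[worst_source] > _RANK[label]:
            reasons.append(
                "conflicting source classifications: assigned the more "
                f"conservative Class {worst_source.value}"
            )
            label = worst_source

    return EvidenceClass(label, CLASS_SCORES[label], reasons)
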