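"""Trial-evidence records: the curated input schema for cDTI scoring.

A :class:`TrialEvidenceRecord` holds everything the scoring engines need for
one prescription digital therapeutic (PDT): primary-endpoint statistics,
engagement metrics at one of four hierarchy tiers, trial-design features, and
safety data at one of four hierarchy tiers. Records are curated by a human
from regulatory summaries, registries and pivotal-trial publications; this
module only validates, reads and writes them.

Conventions enforced here:

* rates and proportions are fractions in ``[0, 1]``, never percentages —
  values above 1 are rejected rather than rescaled;
* trial-design flags are three-state (``true`` / ``false`` / ``null`` for
  unknown); downstream classification treats unknown conservatively;
* unknown keys are schema errors, not warnings — curated evidence must be
  exact.
"""

from __future__ import annotations

import enum
import json
import random
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

__all__ = [
    "BenefitDirection",
    "SignificanceInference",
    "EngagementTier",
    "ControlType",
    "SafetyTier",
    "ClassLabel",
    "EfficacyEvidence",
    "EngagementEvidence",
    "DesignFeatures",
    "SafetyEvidence",
    "TrialEvidenceRecord",
    "RecordFormatError",
    "load_record",
    "write_record",
    "builtin_fixture",
    "generate_random_record",
    "json_schema",
    "FIXTURE_NAMES",
]


class RecordFormatError(ValueError):
    """Raised when a record file cannot be parsed in its declared format."""


class BenefitDirection(str, enum.Enum):
    """Which direction of the primary endpoint means clinical benefit."""

    higher_better = "higher_better"
    lower_better = "lower_better"


class SignificanceInference(str, enum.Enum):
    """Fallback significance judgement when no exact p-value is reported."""

    ci_excludes_null = "ci_excludes_null"
    reported_significant = "reported_significant"
    unknown = "unknown"


class EngagementTier(str, enum.Enum):
    """Engagement extraction hierarchy, best (most objective) first."""

    module_completion = "module_completion"
    digital_usage = "digital_usage"
    clinician_assessed = "clinician_assessed"
    treatment_completion = "treatment_completion"
    missing = "missing"


class ControlType(str, enum.Enum):
    sham_or_digital_placebo = "sham_or_digital_placebo"
    active_comparator = "active_comparator"
    usual_care = "usual_care"
    waitlist = "waitlist"
    none = "none"


class SafetyTier(str, enum.Enum):
    """Safety extraction hierarchy, best (most attributable) first."""

    pdt_related_teae = "pdt_related_teae"
    delta_teae = "delta_teae"
    treatment_only_teae = "treatment_only_teae"
    missing = "missing"


class ClassLabel(str, enum.Enum):
    """Adapted class-of-evidence label, Class I (highest rigor) to IV."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EfficacyEvidence(_StrictModel):
    """Primary-endpoint statistics for the efficacy domain.

    At least one sufficient-statistic path must be present:

    1. ``reported_smd`` — a curated, already benefit-positive Hedges' g;
    2. ``mean_diff`` + ``sd_pooled`` + sample sizes (``group_ns`` or
       ``total_n``);
    3. full group statistics (``group_means``, ``group_sds``, ``group_ns``).
    """

    reported_smd: Optional[float] = None
    mean_diff: Optional[float] = None
    sd_pooled: Optional[float] = Field(default=None, gt=0)
    group_means: Optional[tuple[float, float]] = None
    group_sds: Optional[tuple[float, float]] = None
    group_ns: Optional[tuple[int, int]] = None
    total_n: Optional[int] = Field(default=None, ge=4)
    benefit_direction: BenefitDirection = BenefitDirection.higher_better
    p_value: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    significance_inference: Optional[SignificanceInference] = None

    @field_validator("group_sds")
    @classmethod
    def _sds_positive(cls, v):
        if v is not None and (v[0] <= 0 or v[1] <= 0):
            raise ValueError("group SDs must be > 0")
        return v

    @field_validator("group_ns")
    @classmethod
    def _ns_at_least_two(cls, v):
        if v is not None and (v[0] < 2 or v[1] < 2):
            raise ValueError("group sample sizes must be >= 2")
        return v

    @model_validator(mode="after")
    def _sufficient_statistics(self):
        has_reported = self.reported_smd is not None
        has_mean_diff = (
            self.mean_diff is not None
            and self.sd_pooled is not None
            and (self.group_ns is not None or self.total_n is not None)
        )
        has_groups = (
            self.group_means is not None
            and self.group_sds is not None
            and self.group_ns is not None
        )
        if not (has_reported or has_mean_diff or has_groups):
            raise ValueError(
                "efficacy evidence needs reported_smd, or mean_diff with "
                "sd_pooled and sample sizes, or full group statistics"
            )
        return self


class EngagementEvidence(_StrictModel):
    """Engagement metric at the best tier the trial reported.

    ``completed_mean`` / ``available_total`` carry objective module-completion
    counts (means are allowed, e.g. 42.2 of 67 modules); ``proportion`` carries
    an already-normalized fraction for any tier. ``tier = missing`` means the
    trial reported no usable engagement metric at all.
    """

    tier: EngagementTier = EngagementTier.missing
    completed_mean: Optional[float] = Field(default=None, ge=0)
    available_total: Optional[float] = Field(default=None, gt=0)
    proportion: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    adherence_threshold_note: Optional[str] = None

    @model_validator(mode="after")
    def _tier_requirements(self):
        has_counts = self.completed_mean is not None and self.available_total is not None
        if self.completed_mean is not None and self.available_total is None:
            raise ValueError("completed_mean requires available_total")
        if has_counts and self.completed_mean > self.available_total:
            raise ValueError("completed_mean must not exceed available_total")
        if self.tier is EngagementTier.missing:
            if has_counts or self.proportion is not None or self.completed_mean is not None:
                raise ValueError("tier 'missing' must carry no metric fields")
        elif self.tier is EngagementTier.module_completion:
            if not has_counts and self.proportion is None:
                raise ValueError(
                    "module_completion needs completed_mean/available_total or proportion"
                )
        else:
            if self.proportion is None and not has_counts:
                raise ValueError(f"tier '{self.tier.value}' needs a proportion")
        return self


class DesignFeatures(_StrictModel):
    """Trial-design features feeding the class-of-evidence rule engine.

    Boolean flags are three-state: ``None`` means the curator could not
    establish the feature, and the classifier resolves it conservatively
    (as the deficient value).
    """

    randomized: Optional[bool] = None
    concealed_allocation: Optional[bool] = None
    patient_blinded: Optional[bool] = None
    assessor_blinded: Optional[bool] = None
    control_type: ControlType = ControlType.none
    objective_or_masked_outcome: Optional[bool] = None
    retention_ge_80pct: Optional[bool] = None
    defined_primary_outcome: Optional[bool] = None
    explicit_eligibility: Optional[bool] = None
    methodological_deficiency: Optional[bool] = None
    noninferiority_criteria_unmet: Optional[bool] = None
    hybrid_pivotal_phase_only: Optional[bool] = None
    conflicting_source_classes: Optional[tuple[ClassLabel, ClassLabel]] = None


class SafetyEvidence(_StrictModel):
    """Tiered treatment-emergent adverse-event (TEAE) evidence.

    ``alternate_rates`` may carry rates for the selected tier reported by
    other sources (e.g. a regulatory summary disagreeing with the trial
    publication); the penalty engine applies the most conservative (highest).
    """

    tier: SafetyTier = SafetyTier.missing
    pdt_related_rate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    treatment_teae_rate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    control_teae_rate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    related_sae_present: Optional[bool] = None
    alternate_rates: Optional[list[float]] = None

    @field_validator("alternate_rates")
    @classmethod
    def _alternates_in_unit_interval(cls, v):
        if v is not None and any(r < 0 or r > 1 for r in v):
            raise ValueError("alternate rates must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _tier_requirements(self):
        if self.tier is SafetyTier.pdt_related_teae and self.pdt_related_rate is None:
            raise ValueError("pdt_related_teae tier requires pdt_related_rate")
        if self.tier is SafetyTier.delta_teae and (
            self.treatment_teae_rate is None or self.control_teae_rate is None
        ):
            raise ValueError("delta_teae tier requires both arm TEAE rates")
        if self.tier is SafetyTier.treatment_only_teae and self.treatment_teae_rate is None:
            raise ValueError("treatment_only_teae tier requires treatment_teae_rate")
        if self.tier is SafetyTier.missing and any(
            v is not None
            for v in (self.pdt_related_rate, self.treatment_teae_rate, self.control_teae_rate)
        ):
            raise ValueError("tier 'missing' must carry no rate fields")
        return self


class TrialEvidenceRecord(_StrictModel):
    """The full curated evidence record for one product."""

    product_name: str = Field(min_length=1)
    indication: str = ""
    efficacy: EfficacyEvidence
    engagement: EngagementEvidence = EngagementEvidence()
    design: DesignFeatures = DesignFeatures()
    safety: SafetyEvidence = SafetyEvidence()
    sources: list[str] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# IO


def load_record(path: str | Path, format: str | None = None) -> TrialEvidenceRecord:
    """Read and validate a record from a JSON or YAML file.

    ``format`` is ``"json"`` or ``"yaml"``; when omitted it is inferred from
    the file suffix (``.json`` vs ``.yaml``/``.yml``).

    Raises :class:`RecordFormatError` on a parse failure (naming the line
    where possible) and pydantic's ``ValidationError`` on a schema violation.
    """
    path = Path(path)
    if format is None:
        format = "yaml" if path.suffix.lower() in {".yaml", ".yml"} else "json"
    if format not in {"json", "yaml"}:
        raise ValueError(f"unknown record format: {format!r}")
    text = path.read_text()
    if format == "json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise RecordFormatError(
                f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}"
            ) from exc
    else:
        try:
            payload = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark is not None else ""
            raise RecordFormatError(f"{path}: invalid YAML{where}") from exc
    if not isinstance(payload, dict):
        raise RecordFormatError(f"{path}: expected a mapping at the top level")
    return TrialEvidenceRecord.model_validate(payload)


def write_record(record: TrialEvidenceRecord, path: str | Path, format: str | None = None) -> None:
    """Serialize a record to JSON or YAML, omitting unset optional fields."""
    path = Path(path)
    if format is None:
        format = "yaml" if path.suffix.lower() in {".yaml", ".yml"} else "json"
    payload = record.model_dump(mode="json", exclude_none=True)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "yaml":
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        raise ValueError(f"unknown record format: {format!r}")


FIXTURE_NAMES = ("reset_o", "ct132")


def builtin_fixture(name: str) -> TrialEvidenceRecord:
    """Return one of the two curated built-in records.

    ``reset_o`` is the first-generation opioid-use-disorder PDT (reported
    Hedges' g 0.179, p = 0.214, mean 42.2 of 67 modules completed, Class III
    design features, no systematic safety reporting). ``ct132`` is the
    second-generation episodic-migraine PDT (reported Hedges' g 0.300,
    p = 0.005, 89.7% task completion, Class I design features, zero
    PDT-related TEAEs).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    text = resources.files("cdti.data").joinpath(f"{name}.json").read_text()
    return TrialEvidenceRecord.model_validate(json.loads(text))


def json_schema() -> dict:
    """JSON-Schema document for :class:`TrialEvidenceRecord` (draft 2020-12)."""
    return TrialEvidenceRecord.model_json_schema()


# ---------------------------------------------------------------------------
# Random records for property testing


def generate_random_record(seed: int) -> TrialEvidenceRecord:
    """Generate a random but always-valid record, deterministic per seed.

    Exercises every engagement and safety tier, every control type and all
    three flag states with nonzero probability, so a modest corpus of seeds
    covers the whole rule space.
    """
    rng = random.Random(seed)

    def tristate() -> Optional[bool]:
        return rng.choice([True, True, False, None])

    # efficacy: pick one sufficient-statistic path
    direction = rng.choice(list(BenefitDirection))
    path = rng.choice(["reported", "mean_diff", "groups"])
    eff_kwargs: dict = {"benefit_direction": direction}
    if path == "reported":
        eff_kwargs["reported_smd"] = round(rng.uniform(-0.2, 1.2), 3)
    elif path == "mean_diff":
        eff_kwargs["mean_diff"] = round(rng.uniform(-5, 5), 2)
        eff_kwargs["sd_pooled"] = round(rng.uniform(0.5, 10), 2)
        eff_kwargs["total_n"] = rng.randint(10, 600)
    else:
        eff_kwargs["group_means"] = (round(rng.uniform(0, 20), 2), round(rng.uniform(0, 20), 2))
        eff_kwargs["group_sds"] = (round(rng.uniform(0.5, 8), 2), round(rng.uniform(0.5, 8), 2))
        eff_kwargs["group_ns"] = (rng.randint(5, 300), rng.randint(5, 300))
    if rng.random() < 0.8:
        eff_kwargs["p_value"] = round(rng.random(), 4)
    elif rng.random() < 0.5:
        eff_kwargs["significance_inference"] = rng.choice(list(SignificanceInference))

    eng_tier = rng.choice(list(EngagementTier))
    eng_kwargs: dict = {"tier": eng_tier}
    if eng_tier is EngagementTier.module_completion:
        total = rng.randint(5, 100)
        eng_kwargs["available_total"] = total
        eng_kwargs["completed_mean"] = round(rng.uniform(0, total), 1)
    elif eng_tier is not EngagementTier.missing:
        eng_kwargs["proportion"] = round(rng.random(), 3)

    design = DesignFeatures(
        randomized=tristate(),
        concealed_allocation=tristate(),
        patient_blinded=tristate(),
        assessor_blinded=tristate(),
        control_type=rng.choice(list(ControlType)),
        objective_or_masked_outcome=tristate(),
        retention_ge_80pct=tristate(),
        defined_primary_outcome=tristate(),
        explicit_eligibility=tristate(),
        methodological_deficiency=rng.choice([True, False, False, None]),
        noninferiority_criteria_unmet=rng.choice([True, False, False, False, None]),
        conflicting_source_classes=(
            (rng.choice(list(ClassLabel)), rng.choice(list(ClassLabel)))
            if rng.random() < 0.15
            else None
        ),
    )

    saf_tier = rng.choice(list(SafetyTier))
    saf_kwargs: dict = {
        "tier": saf_tier,
        "related_sae_present": rng.choice([True, False, False, False, None]),
    }
    if saf_tier is SafetyTier.pdt_related_teae:
        saf_kwargs["pdt_related_rate"] = round(rng.random() * 0.5, 3)
    elif saf_tier is SafetyTier.delta_teae:
        saf_kwargs["treatment_teae_rate"] = round(rng.random(), 3)
        saf_kwargs["control_teae_rate"] = round(rng.random(), 3)
    elif saf_tier is SafetyTier.treatment_only_teae:
        saf_kwargs["treatment_teae_rate"] = round(rng.random(), 3)
    if saf_tier is not SafetyTier.missing and rng.random() < 0.2:
        saf_kwargs["alternate_rates"] = [round(rng.random(), 3) for _ in range(rng.randint(1, 3))]

    return TrialEvidenceRecord(
        product_name=f"synthetic-pdt-{seed}",
        indication=rng.choice(
            ["episodic migraine", "opioid use disorder", "insomnia", "major depressive disorder"]
        ),
        efficacy=EfficacyEvidence(**eff_kwargs),
        engagement=EngagementEvidence(**eng_kwargs),
        design=design,
        safety=SafetyEvidence(**saf_kwargs),
        sources=[f"synthetic source {seed}"],
    )
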