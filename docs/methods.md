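# Methods

## Model

The Composite Digital Therapeutic Index treats a product's trial evidence as
four independent domain scores combined multiplicatively:

    cDTI = adjusted efficacy × engagement × evidence quality × (1 − safety penalty)

The multiplicative form is deliberate: a zero in any domain — no measurable
effect, no engagement, or a saturated safety penalty — zeroes the index, so
strength in one domain cannot compensate for the absence of another. The
index lives on a 0–1 scale; since the significance multiplier can reach
1.15, an adjusted efficacy above ≈1.12 together with perfect scores
elsewhere could push the raw product above 1, in which case the composite
is clamped to 1 and flagged (`clamped=True`) rather than rescaled. No
bundled or realistic record approaches this region.

All scoring is closed-form arithmetic on one curated record; there is no
estimation, fitting, or randomness anywhere in the pipeline.

### Efficacy

The effect size is the standardized mean difference on the prespecified
primary endpoint, as Hedges' g: Cohen's d on the pooled SD multiplied by
the small-sample correction J = 1 − 3/(4·df − 1), df = n₁ + n₂ − 2. This is
the common approximation to the exact gamma-function correction; for the
sample sizes of registrational trials the two differ in the fourth decimal
or beyond. Three input paths are accepted, in order of preference as
curated: a reported (already benefit-positive) g; a mean difference with
pooled SD and sample sizes; or full per-arm means/SDs/ns. When both a
reported g and a computable raw path are present they are cross-checked and
a disagreement beyond 0.005 (the rounding grain of a 3-decimal published
effect size) is an error, never a silent preference.

Directionality is normalized so positive always means benefit: for
lower-is-better endpoints (e.g. monthly migraine days) the sign of the
computed g is flipped. A reported g is assumed already benefit-positive by
curation convention.

The significance multiplier is a step function of the primary-endpoint
p-value — 1.15 / 1.10 / 1.00 / 0.50 over the tiers p<0.001, [0.001, 0.01),
[0.01, 0.05), and ≥0.05 — with half-open boundaries (p = 0.01 earns 1.00).
When no exact p-value exists, significance inferred from a confidence
interval or the authors' interpretation earns the neutral 1.00 (the tier
cannot be pinned down more finely, and 1.00 is the most conservative
"significant" choice); with no information at all the endpoint is assumed
non-significant. The adjusted score is floored at zero so a harmful effect
cannot make the composite negative; the signed value is kept in the
scorecard provenance.

### Engagement

Engagement is a plain fraction in [0, 1] extracted under a four-tier
hierarchy preferring objective measures: module/task completion, then
digital usage, then clinician-assessed adherence, then study completion as
a last resort. Objective completion counts (possibly fractional means, e.g.
42.2 of 67 modules) always win over a pre-normalized proportion attached to
a lower tier. All tiers are treated as commensurable fractions — the tier
label is provenance, not a discount — because no tier-specific weighting is
part of the model. A record with no engagement metric imputes the neutral
midpoint 0.50. Scores are rounded to 3 decimals at the domain level so that
printed scorecards and the composite computed from them agree exactly.

### Evidence quality

Trial designs are graded with an adapted American Academy of Neurology
Class of Evidence scheme and mapped I→1.00, II→0.75, III→0.50, IV→0.25.
The decision procedure, in order: no concurrent control → IV; waitlist
control → III; full rigor (randomization, concealed allocation, defined
primary outcome, explicit eligibility, ≥80% retention) with true double
blinding (patient **and** assessor) against a sham/digital-placebo or
blindable active comparator → I; full rigor without double blinding but
with masked assessment or an objective outcome and no asserted
methodological deficiency → II; any remaining controlled design → III.
Two downgrades follow: a non-inferiority trial that failed its comparator
similarity / eligibility / observed-case requirements drops one class, and
when two sources grade the same trial differently the lower class stands.
Every downgrade or conservative resolution is recorded as a reason string
on the result.

Three-state flags: design features are true/false/unknown. Unknown quality
features count as absent and an unknown deficiency judgement counts as a
deficiency — missing design information can only hurt the grade. The one
exception is `noninferiority_criteria_unmet`, which asserts a demonstrated
failure specific to non-inferiority designs; an unknown there is treated as
no downgrade, since most trials are superiority trials for which the flag
is inapplicable and a conservative default would downgrade every record
that never mentions it.

The usual-care Class II/III ambiguity is resolved by an explicit curated
`methodological_deficiency` flag rather than a hidden rule: whether, say,
the absence of patient blinding is disqualifying depends on how
engagement-sensitive the endpoint is, which is a judgement only the curator
can make. Hybrid designs (RCT phase plus open-label extension) are graded
on the pivotal randomized phase only; the curator supplies that phase's
features and sets `hybrid_pivotal_phase_only` as provenance.

### Safety

The penalty follows a strict extraction hierarchy: device-attributed TEAE
rate; else treatment-minus-control TEAE difference; else treatment-only
TEAE rate; else an imputed default of 0.20. A negative difference floors at
zero — no bonus for apparent safety benefit. A serious adverse event
plausibly related to the device adds a fixed 0.50 on top of whatever base
applies (including the imputed 0.20); multiple related SAEs do not stack —
the surcharge marks the presence of device-related serious harm, not its
count. When sources disagree on the selected tier's rate the highest
candidate applies (`alternate_rates`). Rates are used raw, without
normalization, and the total is clamped to [0, 1] so that 1 − penalty stays
non-negative. An unknown `related_sae_present` applies no surcharge: the
surcharge asserts a specific adjudicated event, and generic uncertainty
about safety is already what the 0.20 imputation covers.

### Comparison and radar export

Comparatives are computed on the rounded 3-decimal composites (ratio to 2
decimals, percent as ratio × 100 rounded to an integer), so they match what
a reader derives from the printed scorecards; the unrounded ratio for the
two bundled records would differ in the first decimal. `percent_of` is the
percentage *ratio*, not the percentage increase, and is named accordingly.
A zero comparator composite yields an undefined ratio, never infinity.

The radar ("therapeutic fingerprint") export reports the four axes in the
fixed order efficacy, engagement, evidence quality, inverted safety
(1 − penalty), all oriented so larger is better. The CSV/JSON data export
is the tested surface; the matplotlib rendering is a convenience.

## Rounding protocol

Domain scores are rounded to their reported precision before composition
and comparison: adjusted efficacy to 4 decimals, engagement to 3, the
composite to 3. This makes every printed scorecard internally consistent —
the composite equals the product of the printed domain values — at the cost
of sub-millesimal precision no decision would turn on.

## Records and missing data

Records are strict: unknown keys are errors, rates above 1 are rejected
rather than rescaled to fractions, and each engagement/safety tier requires
exactly its fields. The two bundled records carry reported effect sizes
directly because their publications do not print the pooled SDs needed to
recompute g from the reported mean differences; the raw-statistics path is
exercised by tests and the examples instead.

The synthetic-record generator (`generate_random_record`) produces valid
records covering every tier, control type and flag state, for property
testing: serialization round-trips, bound and monotonicity checks, and
single-flag degradation of the classifier. It emulates the *structure* of
curated evidence, not its empirical distribution — effect sizes, rates and
flags are drawn independently and uniformly, with no correlation between,
say, design rigor and effect size as real portfolios would show. Passing
property tests therefore demonstrates that the engines respect their
invariants over the whole input space, not that the index is calibrated
against any real PDT population.

## Numerical and degenerate cases

Both group SDs zero is a degenerate-variance error; groups below n = 2 are
rejected; an engagement denominator of zero is an error. Evidence-quality
scores are validated against the four allowed values with a 1e−9 tolerance.
All arithmetic is double-precision; the Hedges' g implementation matches an
independently written textbook formula to 1e−12 across the tested range.

## Limitations

The index inherits the limitations of its inputs: single-trial,
registration-stage evidence; heuristic significance multipliers and class
scores; engagement metrics of different kinds treated as commensurable
fractions; and conservative imputation (0.50 engagement, 0.20 safety) that
can dominate a sparse record. Domain weighting, durability adjustment,
severity-weighted safety, score tiers, uncertainty bands and real-world
evidence integration are out of scope. The package scores curated records;
it does not extract evidence from regulatory documents or registries.
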