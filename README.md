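# cdti — Composite Digital Therapeutic Index

`cdti` scores prescription digital therapeutics (PDTs) — FDA-regulated,
software-based treatments delivered via smartphone — from curated
registrational-trial evidence. Regulatory clearance alone says little about
how two PDTs compare: trials differ in effect size, adherence, design rigor
and safety reporting. This package turns a structured evidence record for
one product into four domain scores and a single composite on a 0–1 scale,
for use by health-technology assessors, payers, and researchers
benchmarking digital therapeutics.

## The index

For a product with adjusted efficacy $E$, engagement $A$, evidence quality
$Q$, and safety penalty $S$:

$$\mathrm{cDTI} = E \times A \times Q \times (1 - S)$$

- **Adjusted efficacy** $E = \max(0,\; g \cdot m(p))$, where $g$ is the
  benefit-positive standardized mean difference on the primary endpoint
  (Hedges' g, the small-sample–corrected Cohen's d:
  $g = d\,[1 - 3/(4\,\mathrm{df}-1)]$ with pooled SD and
  $\mathrm{df}=n_1+n_2-2$), and $m(p)$ is a significance multiplier:
  1.15 for $p<0.001$, 1.10 for $0.001\le p<0.01$, 1.00 for
  $0.01\le p<0.05$, and 0.50 for $p\ge 0.05$ or unknown significance.
- **Engagement** $A \in [0,1]$: the proportion of participants completing
  core therapeutic modules, extracted under a four-level hierarchy
  (module completion > digital usage > clinician-assessed > treatment
  completion), with a neutral 0.50 imputed when nothing was reported.
- **Evidence quality** $Q \in \{1.00, 0.75, 0.50, 0.25\}$: an adapted
  American Academy of Neurology Class of Evidence grading (Class I–IV) of
  the pivotal trial's design features, requiring true double-blinding
  against a sham/digital-placebo for Class I.
- **Safety penalty** $S \in [0,1]$: the PDT-related TEAE rate, or the
  treatment-minus-control TEAE difference, or the treatment-only rate, or a
  default 0.20 when unreported; floored at zero (no bonus), plus a fixed
  0.50 surcharge for a device-related serious adverse event.

## Worked example

```python
from cdti import builtin_fixture, score_record, compare_scorecards

ct132 = score_record(builtin_fixture("ct132"))      # episodic-migraine PDT
reset_o = score_record(builtin_fixture("reset_o"))  # opioid-use-disorder PDT
print(reset_o.adjusted_efficacy, reset_o.engagement,
      reset_o.evidence_quality, reset_o.safety_penalty, reset_o.cdti)
# 0.0895 0.63 0.5 0.2 0.023
print(ct132.cdti)                                   # 0.296
print(compare_scorecards(ct132, reset_o).ratio)     # 12.87
```

For reSET-O, the non-significant primary endpoint (g = 0.179, p = 0.214)
is halved to 0.0895; a mean 42.2 of 67 modules completed gives engagement
0.630; the open-label usual-care design grades Class III (0.50); missing
safety reporting imputes a 0.20 penalty — composite 0.023. CT-132's
significant endpoint (g = 0.300, p = 0.005) earns the 1.10 multiplier
(0.330); engagement is 0.897; the double-blind sham-controlled design is
Class I (1.00); zero device-related adverse events give penalty 0.00 —
composite 0.296, 12.87× the reSET-O composite.

The same pipeline is available from the shell:

```sh
cdti score --fixture ct132                       # JSON scorecard
cdti compare --fixture ct132 --fixture reset_o   # ratio + per-domain deltas
cdti radar --fixture ct132 --plot fingerprint.png
```

`examples/` holds one short script per capability: scoring the bundled
records, comparing products, scoring a record built from raw group
statistics, and exporting the radar "therapeutic fingerprint".

Record files are JSON or YAML documents validated against the schema in
`schema/trial_evidence_record.schema.json`; see `src/cdti/data/*.json` for
the two bundled records.

## Documentation

`docs/methods.md` describes the scoring model, its assumptions, the
conservative handling of missing data, and known limitations.
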