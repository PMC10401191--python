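# anctriage

A desk-scale library and CLI for traffic-light triage of antenatal and
postnatal home visits. Each visit's measurements — blood pressure and heart
rate (with the shock index HR/SBP), haemoglobin, and an optional 2-hour
non-fasting OGTT glucose — are classified GREEN / YELLOW / RED for three
priority conditions (raised BP, anaemia, gestational diabetes), composed into
an overall severity, and turned into ordered referral/counselling
recommendations plus missing-ANC-practice prompts.

The package also ships:

* **validation** — a two-step check of the rules engine against a
  structurally independent oracle (an if/else decision tree written straight
  from the threshold config): a 200-case clinical fixture covering every
  decision-table band, then 10,000 boundary-enriched random cases. Exit is
  non-zero unless both reach a 100% match. Mutation checks confirm that
  moving any single band edge by one resolution step breaks agreement.
* **cohort_sim** — a synthetic two-arm, four-cluster trial cohort (100
  women per arm, three protocol visits each). Continuous variables are
  moment-matched truncated normals; dichotomised counts (anaemia, raised BP,
  GDM, screening flags, loss to follow-up) are enforced exactly by
  rank-based assignment, so summary percentages recompute without noise.
* **trial_metrics** — retention, per-condition prevalence, visit fidelity,
  screening coverage, per-cluster recruitment rates, and a baseline/end-line
  arm-comparison table with Welch p-values.

## CLI

```sh
# triage a batch of visits (exit 1 if any visit is RED)
anctriage assess --participants participants.csv --visits visits.csv --out assessments.csv

# two-step engine-vs-oracle validation (exit 1 on any mismatch)
anctriage validate --seed 42 --n 10000 --out report.json
anctriage validate --seed 42 --mutate bp.sbp_yellow   # demonstrate sensitivity

# simulate the default two-arm cohort and summarise it
anctriage simulate --out cohort/ --seed 1
anctriage summarize --in cohort/ --out cohort/
```

Inputs are CSV or JSON-lines (`.jsonl`); see `records.PARTICIPANT_COLUMNS`
and `records.VISIT_COLUMNS` for the schemas. Dates are ISO-8601; missing
optional numerics are empty/null. A `height_cm` column is accepted in place
of `height_m` and converted. Invalid rows are collected and reported
together with row indexes, never silently dropped.

Threshold band edges live in `src/anctriage/config/thresholds.yaml`
(`--thresholds` overrides them at run time); every band is lower-inclusive,
so a value exactly at an edge takes the more severe colour. Recommendation
texts are in `src/anctriage/config/recommendations.yaml`.

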