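# mhq — a scoring engine for the Mental Health Quotient

The Mental Health Quotient (MHQ) is a 47-item self-report instrument for
the *general population*: unlike disorder-specific screens (PHQ-9, GAD-7,
…) it spans the full range from clinical dysfunction to thriving, mixing
**spectrum items** (27 functions that run from life asset to severe
impairment, e.g. *sleep quality*, rated 9→1) with **problem items** (20
pure detractions, e.g. *nightmares*, rated 1→9). This package implements
the complete scoring engine as a configurable, testable library with a
command-line interface, for researchers who want to score MHQ-style
response data, stress-test the scoring algebra, or simulate population
cohorts.

## The scoring model

For item *i* with rating *r<sub>i</sub>* ∈ {1…9} and threshold
*N<sub>i</sub>* ∈ {2…6}:

1. **Threshold rescaling** — problem items: *x<sub>i</sub> = N<sub>i</sub> −
   r<sub>i</sub>*; spectrum items: *x<sub>i</sub> = r<sub>i</sub> −
   N<sub>i</sub>*. Negative *x<sub>i</sub>* marks clinical-risk severity.
2. **Nonlinear negative weighting** — *v<sub>i</sub> = x<sub>i</sub>* if
   *x<sub>i</sub> ≥ 0*, else *v<sub>i</sub> = −w<sub>i</sub>
   |x<sub>i</sub>|<sup>γ<sub>i</sub></sup>*, so grave items (suicidal
   thoughts, aggression, hallucinations…) pull the score down more than
   mild ones at the same rescaled value.
3. **Aggregation and asymmetric normalization** — the intermediate score
   *S = Σ v<sub>i</sub>* maps piecewise-linearly onto the MHQ scale:
   *S ≥ 0* → 200·*S*/*S*<sub>max</sub> ∈ [0, 200]; *S < 0* → −1 −
   99·*S*/*S*<sub>min</sub> ∈ [−100, −1]. The compressed negative window
   deliberately mitigates the distress of a very negative result.
4. **Levels** — rounded scores fall into six bands: clinical [−100, −51],
   at-risk [−50, −1], enduring [0, 50], managing [51, 100], succeeding
   [101, 150], thriving [151, 200].

On top of this the package computes six **subcategory scores** (core
cognition, complex cognition, mood & outlook, drive & motivation, social
self, mind-body; weighted averages with core items at 1.0 and secondary
items at 0.5, normalized to [−50, 100]), a rule-based **DSM-5 symptom
mapper** for 10 disorders (severe = rescaled value < 0; per-disorder
symptom percentages and criterion-derived diagnostic indications), the
study's **QC exclusion pipeline** with an attribution ledger, and a
**synthetic-cohort generator** driven by a latent well-being factor.

The production instrument's per-item thresholds and weights are
proprietary; this package ships a fully documented default parameter table
(`src/mhq/data/default_bank.yaml`) built from the published construction
rules, and every value is overridable. See `docs/methods.md`.

## Worked example

```python
import mhq
from mhq.cohort import CohortSpec, generate_cohort
from mhq.reporting import summarize_cohort

bank = mhq.load_item_bank()                       # default 47-item table
cohort = generate_cohort(CohortSpec(n=2000, seed=42), bank=bank)
kept, ledger = mhq.apply_exclusions(cohort)       # QC pipeline
scores = mhq.score_responses(kept, bank)          # mhq, level, 6 subscores
summary = summarize_cohort(scores, kept, ledger=ledger)
print(summary.n, round(summary.mean_mhq, 1), round(summary.negative_proportion, 3))
```

prints `1690 81.7 0.221`: of 2000 simulated respondents, 310 were excluded
by QC (105 completed in under 7 minutes, 69 were duplicate submissions,
…), the kept cohort's mean MHQ is 81.7, and 22.1% score in the negative
(clinical-risk) range. Scoring a single kept respondent:

```python
record = kept.iloc[0].to_dict()
result = mhq.score_record(record, bank)
print(round(result.mhq, 1), result.level)         # 42.3 enduring
```

— an overall score of 42.3 places this respondent in the *enduring* band
(0–50), with subscores around 19–22 in every domain. Their diagnostic
profile (`mhq.build_profile(record, bank)`) shows 2/15 (13%) of bipolar
symptoms and 2/20 (10%) of PTSD symptoms met, with every diagnostic
indication negative — severe symptoms too few and too scattered to meet
any disorder's criterion rule.

The same pipeline is available from the shell:

```bash
mhq simulate --n 2000 --seed 42 --output cohort.csv
mhq clean    --input cohort.csv --output kept.csv --ledger ledger.json
mhq score    --input kept.csv --output scores.csv --diagnostics
mhq summarize --scores scores.csv --records kept.csv --output summary.json
mhq report   --input kept.csv --row 0 --output report.md
```

The estimator classes (`MHQScorer`, `ResponseCleaner`, `DSMMapper`) follow
scikit-learn conventions (`fit`/`transform`, `get_params`) and compose
with sklearn pipelines.

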