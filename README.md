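# rwemcda

A multi-criteria decision analysis (MCDA) rating tool for **prioritizing
real-world-evidence (RWE) questions** that arise from cancer-drug funding
decisions. When a drug is funded on immature or non-comparative evidence,
payers are left with uncertainties — about long-term survival, the right
comparator, value for money — that post-market RWE studies could resolve.
There are always more candidate questions than analytic capacity, so this
package scores each proposed question on a structured rubric and ranks the
portfolio, for HTA analysts, payer committees, and methodologists who run
that prioritization.

## The model

Each proposal is rated on seven criteria in two groups, each on a 3-point
scale (3 = high performance):

| group | criterion | weight (%) |
|---|---|---|
| A — importance | drug's perceived incremental benefit | 17.65 |
| A — importance | magnitude of uncertainty | 10.6 |
| A — importance | relevance of uncertainty | 18.8 |
| B — feasibility | comparator | 11.8 |
| B — feasibility | cases | 14.1 |
| B — feasibility | data | 17.65 |
| B — feasibility | expertise and methodology | 9.4 |

The aggregate is the weighted sum `V = Σᵢ wᵢ rᵢ` with weights in percent
(summing to 100) and ratings rᵢ ∈ {1, 2, 3}, so totals live on a 100–300
scale. Quantitatively measurable criteria are rated by rule engines:

- **Benefit** uses a graded clinical-benefit rubric on the hazard ratio (HR)
  and gain in median survival: e.g. for diseases with baseline median OS
  > 1 year, HR < 0.70 with a gain ≥ 5 months is substantial benefit (3),
  HR < 0.70 with a gain of 3–5 months is moderate (2), anything else is
  minimal (1); a PFS-only benefit (HR < 0.65, gain > 1.5 months) caps at 2.
- **Uncertainty** is the relative width of the survival confidence interval
  or of the assessed ICER range, whichever is larger: < 10 % → 1,
  10–25 % → 2, > 25 % → 3.
- **Feasibility** criteria are checklist rubrics, including the
  reasonable-time rule: accrual plus follow-up must finish within half the
  remaining patent life.

Qualitative criteria (relevance of uncertainty) take expert-asserted
ratings. The package also elicits weights from most/least-important
stakeholder surveys (equal start, vote-driven adjustment), manages
multi-rater panel sessions (per-criterion discordance flags, recorded —
never averaged — consensus), and checks rank stability under Dirichlet
perturbation of the weights.

## Worked example

`python examples/score_one_proposal.py` builds a profile with a strong OS
benefit (HR 0.62, +5.5 months on a 14-month baseline), a wide ICER range
(60 % variation), and good feasibility, then prints:

```
proposal: example-os-benefit
  benefit                    rating 3  (rule_derived), contributes 52.95
  magnitude_of_uncertainty   rating 3  (rule_derived), contributes 31.80
  relevance_of_uncertainty   rating 3  (expert_asserted), contributes 56.40
  comparator                 rating 3  (rule_derived), contributes 35.40
  cases                      rating 3  (rule_derived), contributes 42.30
  data                       rating 2  (rule_derived), contributes 35.30
  expertise_and_methodology  rating 3  (rule_derived), contributes 28.20
total: 282.35 on the 100-300 scale (importance 141.15 + feasibility 141.20)
```

Each contribution is weight × rating; the only criterion below top marks is
data (one missing covariate → moderate concern, 17.65 × 2 = 35.30). A total
of 282.35 near the 300 ceiling marks a question that is both important and
feasible — a strong candidate for an RWE study. The other scripts under
`examples/` show portfolio ranking with rank-stability, survey-based weight
elicitation, a simulated five-rater panel, and the structural evolution of
the criterion set (remove + merge operations).

## Command line

The same pipeline is available from the shell:

```bash
rwemcda fixtures -n 6 --seed 11 --rater-noise 0 --out-dir work/
rwemcda rate work/profiles.yaml --out work/ratings.csv
rwemcda score work/ratings.csv --out work/scores.csv
rwemcda rank work/ratings.csv --out work/ranks.csv --report work/report.txt
rwemcda panel work/panel.csv
rwemcda sensitivity work/ratings.csv --n-draws 1000 --seed 11
rwemcda elicit survey.csv --out weights.yaml
```

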