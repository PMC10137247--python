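"""Rate and score a single RWE-question proposal from its evidence.

Builds an evidence profile for a hypothetical post-market question — a drug
with a clear OS benefit on a long-survival indication, a wide assessed ICER
range, and good feasibility — runs every rule engine, and prints the
weighted aggregate on the 100-300 scale.
"""

from rwemcda import (
    EconomicEvidence,
    Endpoint,
    EvidenceProfile,
    FeasibilityChecklist,
    SurvivalEvidence,
    aggregate,
    default_criterion_set,
    rate_all,
)

profile = EvidenceProfile(
    proposal_id="example-os-benefit",
    survival=(
        SurvivalEvidence(
            endpoint=Endpoint.OVERALL_SURVIVAL,
            hazard_ratio=0.62,            # strictly below the 0.70 bar
            median_gain_months=5.5,       # above the 5-month top threshold
            baseline_median_months=14.0,  # long-survival form applies
        ),
    ),
    economic=EconomicEvidence(
        icer_base=150_000, icer_lower=120_000, icer_upper=210_000
    ),  # (210k - 120k) / 150k = 60% variation -> substantial uncertainty
    feasibility=FeasibilityChecklist(
        n_standard_of_care_options=1,
        patient_volume="high",
        required_sample_size=200,
        annual_accruable_patients=100.0,
        followup_needed_years=1.5,
        remaining_patent_years=9.0,      # 2 + 1.5 = 3.5 < 4.5 -> timely
        n_missing_covariates=1,          # moderate data concern
    ),
    expert_ratings={"relevance_of_uncertainty": 3},
)

cset = default_criterion_set()
rv = rate_all(profile, cset)
score = aggregate(rv, cset)

print(f"proposal: {profile.proposal_id}")
for cid in cset.ids():
    print(f"  {cid:<26} rating {rv.ratings[cid]}  ({rv.provenance[cid].value}),"
          f" contributes {score.per_criterion_contribution[cid]:.2f}")
print(f"total: {score.total:.2f} on the 100-300 scale "
      f"(importance {score.group_a_subtotal:.2f} + "
      f"feasibility {score.group_b_subtotal:.2f})")
print("Higher totals mark RWE questions that are both important and feasible;"
      " the split shows which side drives the score.")
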