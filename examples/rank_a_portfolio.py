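"""Rank a synthetic portfolio and check how stable the ranking is.

Generates six proposals with known ground-truth ratings, scores them under
the shipped weights, prints the priority order, then perturbs the weights
with a Dirichlet centred on the defaults to see which ranks survive the
acknowledged imprecision of consensus-derived weights.
"""

from rwemcda import (
    FixtureSpec,
    aggregate,
    default_criterion_set,
    generate_fixtures,
    rank_portfolio,
    rank_stability,
    rate_all,
)

cset = default_criterion_set()
bundle = generate_fixtures(FixtureSpec(n_proposals=6, seed=11, rater_noise=0.0))
vectors = [rate_all(p, cset) for p in bundle.profiles]
table = rank_portfolio([aggregate(rv, cset) for rv in vectors])

print("rank  proposal  total   tied")
for row in table.rows:
    print(f"{row.rank:>4}  {row.proposal_id}   {row.total:6.1f}  {row.tied}")

retention = rank_stability(vectors, cset, concentration=100, n_draws=1000, seed=11)
print("\nrank-retention probability under weight perturbation:")
for row in table.rows:
    print(f"  {row.proposal_id}: {retention[row.proposal_id]:.2f}")
print("Values near 1 mean the proposal's priority does not hinge on the exact"
      " weights; low values flag rankings that deliberation should revisit.")
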