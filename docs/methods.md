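# Methods

## The additive value model

A proposal's value is `V = Σᵢ wᵢ rᵢ`, with percent weights wᵢ summing to
100 and ratings rᵢ on a 3-point scale, giving totals in [100, 300]. The
model assumes preferential independence between criteria (no interaction
terms) and treats the 3-point scale as equal-interval — both standard
working assumptions for additive MCDA used as a deliberation aid rather
than a decision rule. Scores are reported raw; a normalized display
(divide by 300) is available but the raw scale keeps per-criterion
contributions readable against the weight table. No funding threshold on
the total is defined: the score guides deliberation, it does not replace
it.

The final seven-criterion set ships with its published weights verbatim
(17.65, 10.6, 18.8, 11.8, 14.1, 17.65, 9.4). The nine- and ten-criterion
predecessor sets carry equal splits (100/9, 100/10), since no weights were
ever published for them and the elicitation procedure itself starts from an
equal split; the ten-criterion draft is reconstructed by name only and its
descriptions are approximate.

## Rule engines and boundary conventions

The published rubric leaves a few edges open; the conventions adopted are:

- **Strict hazard-ratio thresholds.** "HR < 0.65" and "HR < 0.70" are
  honored strictly: an HR exactly at the threshold falls to the lower
  rating.
- **Overlap and gap in the OS gain bands.** On the short-survival form the
  printed moderate band (2.5–2.9 months) and substantial band
  (2.5–3.0 months) overlap; we assign [2.5, 3.0) → 2 and ≥ 3.0 → 3. On the
  long-survival form the printed bands (3–4.9 and > 5) leave [4.9, 5.0)
  unassigned; we use [3.0, 5.0) → 2 and ≥ 5.0 → 3. Both choices make the
  scale a partition with the graded intent preserved.
- **One year = 12.0 months**, and a baseline median of exactly 12 months
  uses the short-survival form, because the long form is printed strictly
  ("> 1 year").
- **PFS caps at 2** (HR < 0.65 and gain strictly > 1.5 months), and benefit
  shown only in an alternative outcome (response rate, quality of life) is
  fixed at 1; an expert override can raise it if a panel disagrees.
- **Multiple survival items combine by maximum**, mirroring the rubric's
  disjunctive clause structure.
- **Uncertainty variation** is defined as full interval width divided by
  the point estimate (CI width / survival estimate; ICER range width / base
  case) — the simplest scale-free reading of "percent variation". When both
  sources exist the maximum governs: a question is as uncertain as its most
  uncertain quantity. The middle band is closed at both ends
  (0.10 ≤ v ≤ 0.25 → 2), the outer bands open.
- **Comparator is worst-governs**: the minimum of the standard-of-care
  subscore (1 if > 2 options, an evolving standard, or none at all; 2 if
  exactly two; 3 if one stable standard) and the patient-volume subscore
  (low/moderate/high → 1/2/3). The zero-options case is not covered by the
  printed rubric; it is scored 1 because no identifiable standard of care
  means no comparator cohort.
- **Reasonable time**: accrual years = required sample / annual accrual;
  a study is timely iff accrual + follow-up < 0.5 × remaining patent years
  (strict). The cases rating is 3 when the whole study is timely, 2 when
  accrual alone is, 1 otherwise. "Patency" is read as patent/market
  exclusivity, supplied in years.

Structural edits on criterion sets conserve the 100 total: removal rescales
survivors by `100/(100 − w_removed)` (proportional renormalization),
merging pools the pair's weights additively and leaves all other weights
bit-identical. The published final weights are never derived by these
operations — they are constants.

## Weight elicitation

The survey procedure is: three most-important and three least-important
votes per respondent, one response per organization (smallest respondent id
kept), equal starting weights, vote-driven adjustment, optional manual
deltas with renormalization. The published workflow describes the
adjustment only qualitatively ("increase, decrease, or leave unchanged"),
so the adjustment rule here is the simplest monotone one consistent with
it: with net votes `netᵢ = mostᵢ − leastᵢ`,

    adjustedᵢ = base × (1 + α · netᵢ / max(1, maxⱼ|netⱼ|)),

renormalized to 100. α ∈ (0, 1] (default 0.5) sets the strength of the
survey's pull away from the equal start. At the extreme α = 1 the most
down-voted criterion's adjusted weight would be exactly zero; a tiny
positive floor (base × 10⁻¹²) is applied before renormalization so derived
weights are always strictly positive, without affecting monotonicity
(only exact zeros — criteria sharing the same extreme net — are floored).
This rule does not claim to reproduce the shipped final weights: the
facilitator's actual adjustment magnitudes were never published.

## Panel sessions

Raters score independently; per criterion the spread (max − min) of
ratings is exhaustive on a 3-point scale and maps to
{0: none, 1: discuss, 2: severe}. Consensus is *recorded*, never computed:
the workflow resolves discordance by discussion, so the tool refuses to
average across raters, and a consensus rating that matches no individual
rating requires a discussion note before it is accepted. Sessions are
immutable once consensus is recorded; re-opening after new evidence is out
of scope. Agreement is summarized as the exact-unanimity proportion per
criterion across sessions; chance-corrected coefficients (kappa family) are
deliberately not provided at this panel size.

## Rank stability

Consensus-derived weights are imprecise, so `rank_stability` redraws weight
vectors from `Dirichlet(c · w/100)` — mean equal to the nominal weights,
coefficient of variation shrinking as the concentration c grows — re-ranks
per draw, and reports each proposal's probability of retaining its nominal
rank. Defaults: c = 100 (roughly ±30 % relative jitter on a mid-sized
weight), 1000 draws, seeded and reproducible. `c = ∞` disables the
perturbation. Ties (totals within 10⁻⁹) share the smaller rank and are
flagged; the display order within a tie (higher importance subtotal, then
proposal id) is a stable convention only — flagged ties go back to humans.

## Synthetic data

The generator emulates the piloted setting: a handful of proposals each
rated by a five-person multidisciplinary panel. For each proposal it draws
an intended rating per criterion (uniform over {1, 2, 3} unless a
`rating_mix` is given) and constructs evidence that the rule engines
provably map back to it — OS evidence on the long-survival form with HR and
gain drawn strictly inside the target band (e.g. HR ∈ [0.40, 0.69],
gain ∈ [5.1, 8.0] for rating 3), an ICER range with relative width drawn
inside the target uncertainty band around a 100 000 $/QALY base, checklist
entries hitting each feasibility band under a 10-year patent horizon, and
an expert rating for relevance. Simulated raters echo the intended rating,
flipped ±1 with probability `rater_noise` and clipped to [1, 3]. Everything
is deterministic given the seed.

What this does not emulate: correlated criteria (real proposals with high
benefit tend to have specific uncertainty profiles), short-survival-form
benefit evidence, rater bias that is systematic rather than symmetric
noise, and evidence that is itself uncertain (the generator's ground truth
is exact). Passing round-trip tests therefore show the engines invert the
rubric correctly and the pipeline is self-consistent — not that the rubric
is valid for real proposals, which is a question for pilot panels.

## Numerical choices

Weights are stored at full precision and validated to sum to 100 within
10⁻⁹; rounding to two decimals is presentation-only. Rating/weight
conservation after remove/merge is exact up to floating-point
associativity (tested at 10⁻⁹). Boundary scans in the acceptance script
bracket a rating transition on a fine grid and bisect to ~10⁻¹², so the
reported thresholds are the engines' actual switch points, not grid
artifacts. Problem sizes used by the test suite (40 000-point
classifier grid, 500-proposal round trip, 1000 randomized surveys and
dominance pairs) keep the full run in a few seconds while covering every
band of every rubric.

## Known limitations

- The benefit rubric covers only the survival excerpts of the graded
  clinical-benefit scale; curative-intent forms and quality-of-life or
  toxicity adjustments are out of scope, as is estimating HRs or ICERs
  from patient-level data.
- Weight elicitation implements the equal-start-and-adjust procedure, not
  formal swing weighting, AHP, or discrete-choice methods.
- Aggregation is strictly additive; outranking and multiplicative MCDA
  models are non-goals.
- Persistence is flat files (YAML/JSON/CSV); there is no service layer or
  collaborative real-time collection.
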