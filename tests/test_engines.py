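"""Rating engines: rubric thresholds, boundary conventions, monotonicity."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rwemcda import (
    EconomicEvidence,
    Endpoint,
    EvidenceProfile,
    McdaError,
    Provenance,
    SurvivalEvidence,
    default_criterion_set,
    rate_all,
    rate_benefit,
    rate_cases,
    rate_comparator,
    rate_data,
    rate_expertise_methodology,
    rate_uncertainty,
    reasonable_time_years,
    uncertainty_variation,
)


def os_evidence(baseline, hr, gain, **kw):
    return SurvivalEvidence(
        endpoint=Endpoint.OVERALL_SURVIVAL,
        hazard_ratio=hr,
        median_gain_months=gain,
        baseline_median_months=baseline,
        **kw,
    )


def pfs_evidence(hr, gain):
    return SurvivalEvidence(
        endpoint=Endpoint.PROGRESSION_FREE_SURVIVAL,
        hazard_ratio=hr,
        median_gain_months=gain,
        baseline_median_months=6.0,
    )


def profile_with(make_checklist, **kw):
    return EvidenceProfile(
        proposal_id="p", feasibility=make_checklist(), **kw
    )


class TestBenefit:
    @pytest.mark.parametrize(
        "baseline,hr,gain,expected",
        [
            # long-survival form: HR < 0.70 with gain >= 5 is substantial
            (14.0, 0.68, 5.5, 3),
            (14.0, 0.68, 4.0, 2),
            (14.0, 0.72, 8.0, 1),
            # short-survival form: HR < 0.65 with gain >= 3 is substantial
            (8.0, 0.80, 1.0, 1),
            (8.0, 0.60, 2.7, 2),
            (8.0, 0.60, 3.5, 3),
            # printed strict inequality: HR exactly at threshold drops down
            (8.0, 0.65, 4.0, 1),
            (14.0, 0.70, 6.0, 1),
            # exactly one year of baseline survival uses the short form
            (12.0, 0.68, 5.5, 1),
            (12.0, 0.60, 2.5, 2),
        ],
    )
    def test_overall_survival_rubric(
        self, make_checklist, baseline, hr, gain, expected
    ):
        p = profile_with(
            make_checklist, survival=(os_evidence(baseline, hr, gain),)
        )
        assert rate_benefit(p).rating == expected

    @pytest.mark.parametrize(
        "hr,gain,expected",
        [
            (0.55, 2.0, 2),
            (0.55, 1.5, 1),  # strict: gain must exceed 1.5 months
            (0.70, 3.0, 1),
            (0.55, 9.0, 2),  # PFS evidence never reaches the top rating
        ],
    )
    def test_pfs_rubric_caps_at_moderate(self, make_checklist, hr, gain, expected):
        p = profile_with(make_checklist, survival=(pfs_evidence(hr, gain),))
        assert rate_benefit(p).rating == expected

    def test_alternative_outcome_only_is_minimal(self, make_checklist):
        p = profile_with(make_checklist, alternative_outcome_benefit_only=True)
        result = rate_benefit(p)
        assert result.rating == 1
        assert "alternative" in result.rationale

    def test_best_clause_governs_across_items(self, make_checklist):
        p = profile_with(
            make_checklist,
            survival=(pfs_evidence(0.5, 3.0), os_evidence(14.0, 0.6, 6.0)),
        )
        assert rate_benefit(p).rating == 3

    def test_expert_fallback_and_unratable(self, make_checklist):
        p = profile_with(make_checklist, expert_ratings={"benefit": 2})
        assert rate_benefit(p).rating == 2
        bare = p.model_copy(update={"expert_ratings": {}})
        with pytest.raises(McdaError, match="benefit unratable"):
            rate_benefit(bare)

    @given(
        hr=st.floats(min_value=0.05, max_value=1.2),
        gain=st.floats(min_value=0.0, max_value=10.0),
        baseline=st.sampled_from([6.0, 24.0]),
        d_hr=st.floats(min_value=0.0, max_value=0.5),
        d_gain=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_monotone_in_hr_and_gain(self, hr, gain, baseline, d_hr, d_gain):
        """Lower hazard ratio or larger gain never lowers the rating."""

        def rating(h, g):
            ev = os_evidence(baseline, h, g)
            return rate_benefit(
                EvidenceProfile.model_construct(
                    proposal_id="p", survival=(ev,),
                    alternative_outcome_benefit_only=False,
                    expert_ratings={},
                )
            ).rating

        base = rating(hr, gain)
        assert rating(max(hr - d_hr, 1e-6), gain) >= base
        assert rating(hr, gain + d_gain) >= base


class TestUncertainty:
    def test_survival_ci_variation(self, make_checklist):
        ev = os_evidence(
            14.0, 0.6, 5.0, point_estimate_months=10.0, ci_lower=8.0, ci_upper=12.0
        )
        p = profile_with(make_checklist, survival=(ev,))
        assert uncertainty_variation(p) == pytest.approx(0.4)

    def test_degenerate_interval_is_zero(self, make_checklist):
        ev = os_evidence(
            14.0, 0.6, 5.0, point_estimate_months=10.0, ci_lower=10.0, ci_upper=10.0
        )
        assert uncertainty_variation(
            profile_with(make_checklist, survival=(ev,))
        ) == 0.0

    def test_icer_variation_and_max_governs(self, make_checklist):
        econ = EconomicEvidence(
            icer_base=100_000, icer_lower=95_000, icer_upper=105_000
        )
        p = profile_with(
            make_checklist,
            survival=(
                os_evidence(14.0, 0.6, 5.0, point_estimate_months=10.0,
                            ci_lower=8.0, ci_upper=12.0),
            ),
            economic=econ,
        )
        assert uncertainty_variation(p) == pytest.approx(0.4)  # CI wider
        econ_only = profile_with(
            make_checklist, survival=(os_evidence(14.0, 0.6, 5.0),),
            economic=econ,
        )
        assert uncertainty_variation(econ_only) == pytest.approx(0.1)

    def test_no_quantitative_source(self, make_checklist):
        p = profile_with(
            make_checklist, survival=(os_evidence(14.0, 0.6, 5.0),)
        )
        with pytest.raises(McdaError, match="no quantitative uncertainty"):
            uncertainty_variation(p)

    @given(
        point=st.floats(min_value=0.5, max_value=50.0),
        halfwidth=st.floats(min_value=0.0, max_value=10.0),
        c=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, make_checklist, point, halfwidth, c):
        """Rescaling the point estimate and CI by c > 0 changes nothing."""

        def variation(scale):
            ev = os_evidence(
                14.0, 0.6, 5.0,
                point_estimate_months=point * scale,
                ci_lower=(point - halfwidth) * scale,
                ci_upper=(point + halfwidth) * scale,
            )
            return uncertainty_variation(
                profile_with(self_make_checklist, survival=(ev,))
            )

        self_make_checklist = make_checklist
        assert variation(c) == pytest.approx(variation(1.0), rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "variation,expected",
        [(0.0, 1), (0.05, 1), (0.0999, 1), (0.10, 2), (0.20, 2),
         (0.25, 2), (0.2501, 3), (0.30, 3), (2.0, 3)],
    )
    def test_bands(self, variation, expected):
        assert rate_uncertainty(variation) == expected

    def test_quantitative_beats_expert(self):
        assert rate_uncertainty(0.05, expert_rating=3) == 1
        assert rate_uncertainty(None, expert_rating=3) == 3
        with pytest.raises(McdaError, match="uncertainty unratable"):
            rate_uncertainty(None, None)

    @given(
        a=st.floats(min_value=0.0, max_value=1.0),
        b=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_in_variation(self, a, b):
        lo, hi = sorted((a, b))
        assert rate_uncertainty(lo) <= rate_uncertainty(hi)


class TestComparator:
    @pytest.mark.parametrize(
        "n_soc,evolving,volume,expected",
        [
            (1, False, "high", 3),
            (3, False, "high", 1),
            (1, False, "low", 1),     # worst dimension governs
            (2, False, "high", 2),
            (2, False, "moderate", 2),
            (1, True, "high", 1),     # evolving standard of care
            (0, False, "high", 1),    # no identifiable standard of care
        ],
    )
    def test_worst_governs(self, make_checklist, n_soc, evolving, volume, expected):
        fc = make_checklist(
            n_standard_of_care_options=n_soc,
            soc_evolving=evolving,
            patient_volume=volume,
        )
        assert rate_comparator(fc) == expected


class TestReasonableTimeAndCases:
    def test_half_patent_life_rule(self, make_checklist):
        fc = make_checklist(
            required_sample_size=100, annual_accruable_patients=50.0,
            followup_needed_years=1.0, remaining_patent_years=10.0,
        )
        assert reasonable_time_years(fc) == (2.0, 3.0, True)
        slow = make_checklist(
            required_sample_size=100, annual_accruable_patients=10.0,
            followup_needed_years=0.0, remaining_patent_years=10.0,
        )
        assert reasonable_time_years(slow) == (10.0, 10.0, False)

    def test_instantaneous_accrual_is_always_reasonable(self, make_checklist):
        fc = make_checklist(
            required_sample_size=100, annual_accruable_patients=1e9,
            followup_needed_years=0.0, remaining_patent_years=0.1,
        )
        assert reasonable_time_years(fc).reasonable

    @pytest.mark.parametrize(
        "n,rate,followup,expected",
        [
            (50, 50.0, 1.0, 3),   # 1 + 1 = 2 < 5
            (200, 50.0, 3.0, 2),  # accrual 4 < 5 but total 7 >= 5
            (300, 50.0, 0.0, 1),  # accrual 6 >= 5
        ],
    )
    def test_cases_bands(self, make_checklist, n, rate, followup, expected):
        fc = make_checklist(
            required_sample_size=n, annual_accruable_patients=rate,
            followup_needed_years=followup, remaining_patent_years=10.0,
        )
        assert rate_cases(fc) == expected


class TestDataAndExpertise:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            ({}, 3),
            ({"n_missing_covariates": 3}, 1),
            ({"n_missing_covariates": 2}, 2),
            ({"n_missing_covariates": 1}, 2),
            ({"missing_eligibility_characteristics": True}, 1),
            ({"can_identify_primary_treatment_line": False}, 1),
            ({"can_identify_prior_subsequent_treatment_line": False}, 2),
        ],
    )
    def test_data_checklist(self, make_checklist, kw, expected):
        assert rate_data(make_checklist(**kw)) == expected

    @pytest.mark.parametrize(
        "expertise,methods,expected",
        [(True, True, 3), (True, False, 2), (False, True, 2), (False, False, 1)],
    )
    def test_expertise_methodology(self, make_checklist, expertise, methods, expected):
        fc = make_checklist(
            expertise_available=expertise, methods_available=methods
        )
        assert rate_expertise_methodology(fc) == expected


class TestRateAll:
    def test_full_profile_total_and_provenance(self, make_checklist):
        cset = default_criterion_set()
        p = EvidenceProfile(
            proposal_id="p",
            survival=(os_evidence(14.0, 0.6, 6.0),),
            economic=EconomicEvidence(
                icer_base=100_000, icer_lower=80_000, icer_upper=120_000
            ),
            feasibility=make_checklist(),
            expert_ratings={"relevance_of_uncertainty": 3},
        )
        rv = rate_all(p, cset)
        assert set(rv.ratings) == set(cset.ids())
        assert all(r in (1, 2, 3) for r in rv.ratings.values())
        assert rv.provenance["benefit"] is Provenance.RULE_DERIVED
        assert rv.provenance["relevance_of_uncertainty"] is Provenance.EXPERT_ASSERTED
        assert rv.ratings["benefit"] == 3
        assert rv.ratings["magnitude_of_uncertainty"] == 3  # 40% variation

    def test_all_expert_profile(self, make_checklist):
        cset = default_criterion_set()
        p = EvidenceProfile(
            proposal_id="p",
            feasibility=make_checklist(),
            expert_ratings={
                "benefit": 2,
                "magnitude_of_uncertainty": 1,
                "relevance_of_uncertainty": 3,
            },
        )
        rv = rate_all(p, cset)
        # no quantitative benefit/uncertainty inputs -> expert-asserted
        assert rv.provenance["benefit"] is Provenance.EXPERT_ASSERTED
        assert rv.provenance["magnitude_of_uncertainty"] is Provenance.EXPERT_ASSERTED
        # checklist criteria remain rule-derived
        assert rv.provenance["data"] is Provenance.RULE_DERIVED

    def test_override_flag_required_to_beat_rules(self, make_checklist):
        cset = default_criterion_set()
        base = dict(
            proposal_id="p",
            survival=(os_evidence(14.0, 0.6, 6.0),),
            feasibility=make_checklist(),
            expert_ratings={
                "relevance_of_uncertainty": 3,
                "magnitude_of_uncertainty": 2,
                "benefit": 1,
            },
        )
        assert rate_all(EvidenceProfile(**base), cset).ratings["benefit"] == 3
        overridden = EvidenceProfile(**base, expert_overrides=("benefit",))
        rv = rate_all(overridden, cset)
        assert rv.ratings["benefit"] == 1
        assert rv.provenance["benefit"] is Provenance.EXPERT_ASSERTED

    def test_missing_qualitative_rating_is_incomplete(self, make_checklist):
        cset = default_criterion_set()
        p = EvidenceProfile(
            proposal_id="p",
            survival=(os_evidence(14.0, 0.6, 6.0),),
            economic=EconomicEvidence(
                icer_base=1.0, icer_lower=1.0, icer_upper=1.0
            ),
            feasibility=make_checklist(),
        )
        with pytest.raises(McdaError, match="incomplete rating"):
            rate_all(p, cset)
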