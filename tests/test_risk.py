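"""Risk composition: BMD gradient, prior-fracture RR, treatment RR, offset."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteomark.risk import (
    TreatmentStratum,
    bmd_rr,
    cycle_fracture_prob,
    prior_fx_rr,
    rate_to_cycle_prob,
    residual_rr,
    treatment_rr,
)


class TestBmdRR:
    def test_at_population_mean_rr_is_one(self, params):
        rrs = params.relative_risks
        mean_t = params.mean_pop_tscore(72)
        assert bmd_rr("hip", 72, mean_t, rrs) == pytest.approx(1.0)

    def test_one_sd_below_mean_equals_gradient(self, params):
        rrs = params.relative_risks
        mean_t = params.mean_pop_tscore(72)
        assert bmd_rr("hip", 72, mean_t - 1.0, rrs) == pytest.approx(2.60)

    def test_two_sd_below_mean_squares_gradient(self, params):
        # closed-form power law, cross-checked on the log scale
        rrs = params.relative_risks
        mean_t = params.mean_pop_tscore(72)
        val = bmd_rr("vertebral", 72, mean_t - 2.0, rrs)
        assert val == pytest.approx(1.80**2)
        assert math.log(val) == pytest.approx(2.0 * math.log(1.80))

    def test_age_specific_hip_gradient_switch(self, params):
        rrs = params.relative_risks
        mean_t = params.mean_pop_tscore(66)
        assert bmd_rr("hip", 66, mean_t - 1.0, rrs, hip_gradient="age_specific") == (
            pytest.approx(2.89)
        )


class TestPriorFxRR:
    def test_unadjusted_equals_original(self, params):
        rrs = params.relative_risks
        for site, orig in (("vertebral", 4.40), ("wrist", 1.40), ("other", 1.90)):
            assert prior_fx_rr(site, 72, rrs, adjusted=False) == orig
            assert prior_fx_rr(site, 72, rrs, adjusted=True) == pytest.approx(0.9 * orig)


class TestTreatmentRR:
    @pytest.mark.parametrize(
        "drug, site, months, expected",
        [
            ("denosumab", "hip", 30, 0.28),      # 24-36 month interval
            ("denosumab", "hip", 6, 0.55),
            ("denosumab", "vertebral", 24, 0.29),
            ("alendronate", "vertebral", 60, 0.51),  # 36-month value carried forward
            ("alendronate", "hip", 12, 0.86),
        ],
    )
    def test_interval_step_function(self, params, drug, site, months, expected):
        assert treatment_rr(params.efficacy[drug], site, months) == expected

    def test_zero_months_on_is_neutral(self, params):
        assert treatment_rr(params.efficacy["denosumab"], "hip", 0) == 1.0


class TestResidualRR:
    def test_linear_midpoint(self, params):
        # 24 months on at RR 0.29, 24-month offset, halfway through
        prof = params.efficacy["denosumab"]
        r0 = treatment_rr(prof, "vertebral", 24)
        val = residual_rr(prof, "vertebral", 24, 12, max_offset_years=2.0)
        assert val == pytest.approx(r0 + (1 - r0) * 0.5)

    def test_full_offset_returns_to_baseline(self, params):
        prof = params.efficacy["denosumab"]
        assert residual_rr(prof, "hip", 36, 12, max_offset_years=1.0) == 1.0
        assert residual_rr(prof, "hip", 36, 240, max_offset_years=2.0) == 1.0

    def test_zero_offset_loses_efficacy_immediately(self, params):
        prof = params.efficacy["denosumab"]
        assert residual_rr(prof, "hip", 36, 0, max_offset_years=0.0) == 1.0

    def test_continuous_at_discontinuation_instant(self, params):
        prof = params.efficacy["alendronate"]
        for months_on in (6, 18, 36, 60):
            r0 = treatment_rr(prof, "hip", months_on)
            assert residual_rr(prof, "hip", months_on, 0, 2.0) == pytest.approx(r0)

    def test_early_discontinuation_shortens_offset(self, params):
        # 6 months on treatment: efficacy fully gone after 6 months off,
        # even though the drug's maximum offset is 2 years
        prof = params.efficacy["alendronate"]
        assert residual_rr(prof, "hip", 6, 6, max_offset_years=2.0) == 1.0
        assert residual_rr(prof, "hip", 24, 6, max_offset_years=2.0) < 1.0


class TestCycleProb:
    def test_zero_rate_gives_zero(self, params):
        p = params.copy()
        p.incidence.rates["hip"] = {a: 0.0 for a in p.incidence.rates["hip"]}
        stratum = TreatmentStratum("never_treated")
        assert cycle_fracture_prob("hip", 72, stratum, False, p) == 0.0

    def test_exponential_conversion_closed_form(self):
        assert rate_to_cycle_prob(0.02) == pytest.approx(1 - math.exp(-0.01))
        assert rate_to_cycle_prob(0.02) == pytest.approx(0.00995, abs=1e-5)

    def test_treatment_rr_halves_composed_rate(self, params):
        on = TreatmentStratum("on_treatment", months_on=12)
        off = TreatmentStratum("never_treated")
        p_on = cycle_fracture_prob("vertebral", 72, on, False, params,
                                   strategy_drug="denosumab", max_offset_years=1.0)
        p_off = cycle_fracture_prob("vertebral", 72, off, False, params)
        rr = params.efficacy["denosumab"].rr["vertebral"][12]
        assert math.log(1 - p_on) == pytest.approx(rr * math.log(1 - p_off))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(rate=st.floats(0.0, 0.3))
    def test_conversion_agrees_with_daily_bernoulli_oracle(self, rate):
        # brute-force: 182.5 daily Bernoulli trials at rate/365 per day
        p_daily = 1.0 - (1.0 - rate / 365.0) ** 182.5
        assert rate_to_cycle_prob(rate) == pytest.approx(p_daily, abs=1e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        rr_a=st.floats(0.05, 1.5),
        rr_b=st.floats(0.05, 1.5),
        months=st.integers(1, 120),
    )
    def test_lower_treatment_rr_never_raises_fracture_prob(self, params, rr_a, rr_b, months):
        lo, hi = sorted((rr_a, rr_b))
        p = params.copy()
        stratum = TreatmentStratum("on_treatment", months_on=months)
        probs = []
        for rr in (lo, hi):
            for m in (12, 24, 36):
                p.efficacy["denosumab"].rr["hip"][m] = rr
            probs.append(
                cycle_fracture_prob("hip", 72, stratum, True, p,
                                    strategy_drug="denosumab", max_offset_years=1.0)
            )
        assert probs[0] <= probs[1]
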