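"""Cost and QALY accrual."""

import pytest

import osteomark as om
from osteomark.economics import (
    cycle_drug_and_monitoring_cost,
    discount_factor,
    downstream_disutility,
    ltc_cost_accrual,
)


class TestDiscounting:
    def test_cycle_zero_is_undiscounted(self):
        assert discount_factor(0.03, 0) == 1.0

    def test_zero_rate_never_discounts(self):
        assert discount_factor(0.0, 40) == 1.0

    def test_one_year_at_3pct(self):
        assert discount_factor(0.03, 2) == pytest.approx(1 / 1.03)

    def test_discounted_totals_bounded_by_undiscounted(self, params):
        base = om.evaluate(om.denosumab(), params)
        undisc = om.evaluate(
            om.denosumab(), om.apply_override(params, "config.discount_rate_annual", 0.0)
        )
        assert base.total_cost < undisc.total_cost
        assert base.qalys < undisc.qalys
        assert base.life_years < undisc.life_years


class TestDrugAndMonitoring:
    def test_no_treatment_costs_nothing(self, params):
        drug, mgmt = cycle_drug_and_monitoring_cost(om.no_treatment(), 0.0, params)
        assert drug == 0.0 and mgmt == 0.0

    def test_denosumab_fully_persistent_cycle(self, params):
        drug, mgmt = cycle_drug_and_monitoring_cost(om.denosumab(), 1.0, params)
        assert drug == pytest.approx(0.5 * 2899)
        assert mgmt == pytest.approx(0.5 * (2 * 14.31 + 90.87 + 0.5 * 38.95))
        assert drug + mgmt == pytest.approx(1518.98, abs=0.01)

    def test_scales_with_persistent_fraction(self, params):
        full = sum(cycle_drug_and_monitoring_cost(om.alendronate(), 1.0, params))
        half = sum(cycle_drug_and_monitoring_cost(om.alendronate(), 0.5, params))
        assert half == pytest.approx(full / 2)
        assert sum(cycle_drug_and_monitoring_cost(om.alendronate(), 0.0, params)) == 0.0


class TestLTC:
    def test_zero_admission_probability(self, params):
        p = om.apply_override(params, "costs.ltc_admission_prob_after_hip", 0.0)
        assert ltc_cost_accrual(0.5, p) == 0.0

    def test_expected_lump_sum(self, params):
        assert ltc_cost_accrual(0.01, params) == pytest.approx(
            0.01 * 0.2 * 180 * 216
        )
        assert ltc_cost_accrual(0.01, params) == pytest.approx(77.76)

    def test_only_hip_fractures_incur_ltc(self, params):
        """With hip incidence zeroed the long-term-care term vanishes even
        though other fractures still occur."""
        p_nohip = params.copy()
        p_nohip.incidence.rates["hip"] = {a: 0.0 for a in p_nohip.incidence.rates["hip"]}
        p_free = om.apply_override(p_nohip, "costs.ltc_admission_prob_after_hip", 0.0)
        a = om.evaluate(om.no_treatment(), p_nohip)
        b = om.evaluate(om.no_treatment(), p_free)
        assert a.total_cost == pytest.approx(b.total_cost)


class TestQALYs:
    def test_well_cohort_accrues_baseline_utility(self, no_fracture_params):
        p = om.apply_override(no_fracture_params, "config.horizon_years", 0.5)
        p = om.apply_override(p, "mortality.q_female.72.0", 0.0)
        oc = om.evaluate(om.no_treatment(), p)
        assert oc.qalys == pytest.approx(0.771 * 0.5)
        assert oc.life_years == pytest.approx(0.5)

    def test_qalys_never_exceed_life_years(self, params):
        for s in om.base_case_strategies():
            oc = om.evaluate(s, params)
            assert oc.qalys <= oc.life_years

    def test_downstream_disutility_three_step(self, params):
        # wrist fracture while in a state worth 0.66: one-year decrement
        assert downstream_disutility(0.66, "wrist", 1.0, params) == pytest.approx(0.1122)
        p = params.copy()
        p.utilities.multiplier_year1["wrist"] = 1.0
        assert downstream_disutility(0.66, "wrist", 1.0, p) == 0.0
        assert downstream_disutility(0.66, "wrist", 0.0, params) == 0.0


class TestCostComposition:
    def test_zeroing_non_drug_costs_leaves_drug_cost_exactly(self, params):
        p = params.copy()
        for site in p.costs.fracture_year1:
            p.costs.fracture_year1[site] = {"50-64": 0.0, "65+": 0.0}
        for site in p.costs.fracture_year2plus:
            p.costs.fracture_year2plus[site] = {"50-64": 0.0, "65+": 0.0}
        p.costs.ltc_admission_prob_after_hip = 0.0
        strategy = om.denosumab()
        strategy.nurse_visits_per_year = 0.0
        strategy.physician_visits_per_year = 0.0
        strategy.dxa_scans_per_year = 0.0
        oc = om.evaluate(strategy, p)
        assert oc.total_cost == pytest.approx(oc.cost_by_category["drug"])
        assert oc.cost_by_category["management"] == 0.0

    def test_hip_cost_uses_age_band_year1_value(self, params):
        """A unit hip-fracture mass at 65+ accrues the year-1 cost across the
        two-cycle acute window."""
        from osteomark.economics import state_cost_matrix

        c = state_cost_matrix(params, 72.0, 16)
        from osteomark.engine import HIP_FX, POST_HIP

        assert c[HIP_FX, 0] + c[POST_HIP, 0] == pytest.approx(51760.0)
        assert c[POST_HIP, 5] == pytest.approx(7896.0 / 2)
        c_young = state_cost_matrix(params, 60.0, 16)
        assert c_young[HIP_FX, 0] == pytest.approx(67115.0 / 2)
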