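"""Cohort engine: mortality, transitions, mass conservation, path oracle."""

import numpy as np
import pytest

import osteomark as om
from osteomark.engine import (
    HIP_FX,
    POST_HIP,
    WELL,
    death_prob,
    downstream_fracture_events,
    n_tunnel_compartments,
    prior_vf_weight,
    run_trace,
    step,
)
from osteomark.states import HealthState, N_ALIVE_STATES, N_VF_FLAGS, VF_NONE


class TestDeathProb:
    def test_baseline_closed_form(self, params):
        p = om.apply_override(params, "mortality.q_female.72.0", 0.04)
        q = death_prob(72, HealthState.WELL, 0, 1.0, p)
        assert q == pytest.approx(1 - 0.96**0.5)
        assert q == pytest.approx(0.0202, abs=1e-4)

    def test_rr_one_gives_baseline(self, params):
        q_well = death_prob(72, HealthState.WELL, 0, 1.0, params)
        p = params.copy()
        for site in p.mortality.rr_post_fracture:
            p.mortality.rr_post_fracture[site] = {50.0: 1.0}
        assert death_prob(72, HealthState.HIP_FX, 0, 1.0, p) == pytest.approx(q_well)

    def test_zero_attribution_removes_all_excess(self, params):
        p = om.apply_override(params, "config.excess_mortality_attribution", 0.0)
        q_well = death_prob(80, HealthState.WELL, 0, 1.0, p)
        for state in (HealthState.HIP_FX, HealthState.VERT_FX, HealthState.POST_HIP):
            assert death_prob(80, state, 0, 1.0, p) == pytest.approx(q_well)

    def test_excess_expires_after_window(self, params):
        q_well = death_prob(80, HealthState.WELL, 0, 1.0, params)
        q_in = death_prob(80, HealthState.POST_HIP, 10, 1.0, params)
        q_out = death_prob(80, HealthState.POST_HIP, 16, 1.0, params)
        assert q_in > q_well
        assert q_out == pytest.approx(q_well)


class TestPriorVfWeight:
    def test_quotient(self):
        assert prior_vf_weight(0.1, 1 - 0.236) == pytest.approx(0.1309, abs=1e-4)

    def test_zero_incremental_gives_zero(self):
        assert prior_vf_weight(0.0, 0.764) == 0.0

    def test_equal_proportions_give_unit_weight(self):
        assert prior_vf_weight(0.5, 0.5) == 1.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            prior_vf_weight(0.1, 0.0)


def _empty_arrays(n_strata=1, n_t=16):
    occ = np.zeros((n_strata, N_VF_FLAGS, N_ALIVE_STATES, n_t))
    q = np.zeros((N_VF_FLAGS, N_ALIVE_STATES, n_t))
    p = np.zeros((n_strata, N_VF_FLAGS, N_ALIVE_STATES, 4))
    return occ, q, p


class TestStep:
    def test_no_events_only_advances_clocks(self):
        occ, q, p = _empty_arrays()
        occ[0, VF_NONE, WELL, 0] = 0.6
        occ[0, VF_NONE, POST_HIP, 3] = 0.4
        new, events, deaths = step(occ, q, p)
        assert deaths == 0 and events.sum() == 0
        assert new[0, VF_NONE, WELL, 0] == 0.6
        assert new[0, VF_NONE, POST_HIP, 4] == 0.4

    def test_hip_refracture_two_outcome_bookkeeping(self):
        occ, q, p = _empty_arrays()
        occ[0, VF_NONE, HIP_FX, 0] = 1.0
        q[:] = 0.1
        p[0, :, HIP_FX, 0] = 0.3
        new, events, deaths = step(occ, q, p)
        assert deaths == pytest.approx(0.1)
        assert new[0, VF_NONE, HIP_FX, 0] == pytest.approx(0.9 * 0.3)
        assert new[0, VF_NONE, POST_HIP, 0] == pytest.approx(0.9 * 0.7)
        assert events[0] == pytest.approx(0.9 * 0.3)

    def test_matches_exhaustive_path_enumeration(self):
        """Three cycles of a hip-only reduction against a brute-force
        enumeration of all death/fracture outcome paths."""
        q_c, p_hip, n_cycles = 0.02, 0.05, 3

        # independent oracle: enumerate every per-cycle outcome sequence
        def enumerate_paths(state, prob, cycle, dist):
            if cycle == n_cycles:
                dist[state] = dist.get(state, 0.0) + prob
                return
            dist["dead"] = dist.get("dead", 0.0) + prob * q_c  # death first
            surv = prob * (1 - q_c)
            enumerate_paths("hip0", surv * p_hip, cycle + 1, dist)
            if state == "well":
                enumerate_paths("well", surv * (1 - p_hip), cycle + 1, dist)
            else:  # hip states: re-fracture resets, otherwise post-hip ages
                nxt = "post0" if state == "hip0" else f"post{int(state[4:]) + 1}"
                enumerate_paths(nxt, surv * (1 - p_hip), cycle + 1, dist)

        dist = {}
        enumerate_paths("well", 1.0, 0, dist)

        occ, q, p = _empty_arrays()
        occ[0, VF_NONE, WELL, 0] = 1.0
        q[:] = q_c
        p[0, :, :, 0] = p_hip
        deaths_cum = 0.0
        for _ in range(n_cycles):
            occ, events, deaths = step(occ, q, p)
            deaths_cum += deaths
        assert occ[0, VF_NONE, WELL, 0] == pytest.approx(dist.get("well", 0))
        assert occ[0, VF_NONE, HIP_FX, 0] == pytest.approx(dist.get("hip0", 0))
        assert occ[0, VF_NONE, POST_HIP, 0] == pytest.approx(dist.get("post0", 0))
        assert occ[0, VF_NONE, POST_HIP, 1] == pytest.approx(dist.get("post1", 0))
        assert deaths_cum == pytest.approx(dist.get("dead", 0))


class TestDownstream:
    def test_no_higher_state_occupancy_no_events(self):
        occ, _, p = _empty_arrays()
        occ[0, VF_NONE, WELL, 0] = 1.0
        p[:] = 0.5
        assert downstream_fracture_events(occ, p).sum() == 0.0

    def test_post_hip_mass_times_wrist_prob(self):
        occ, _, p = _empty_arrays()
        occ[0, VF_NONE, POST_HIP, 5] = 0.5
        p[0, :, POST_HIP, 2] = 0.02
        d = downstream_fracture_events(occ, p)
        assert d[1, 2] == pytest.approx(0.01)  # hip_y2 group, wrist site
        assert d.sum() == pytest.approx(0.01)

    def test_bounded_by_occupancy_times_prob_sum(self, params):
        rng = np.random.default_rng(0)
        for _ in range(20):
            occ, _, p = _empty_arrays()
            occ[0] = rng.random((N_VF_FLAGS, N_ALIVE_STATES, 16)) * 0.01
            p[0] = rng.random((N_VF_FLAGS, N_ALIVE_STATES, 4)) * 0.2
            d = downstream_fracture_events(occ, p)
            hi_mass = occ[0, :, [HIP_FX, POST_HIP, 2, 6], :].sum()
            assert d.sum() <= hi_mass * p.max() * 3 + 1e-12


class TestRunTrace:
    def test_zero_horizon_returns_initial_occupancy_only(self, params):
        p = om.apply_override(params, "config.horizon_years", 0.0)
        trace = run_trace(om.no_treatment(), p)
        assert trace.n_cycles == 0
        assert trace.initial_occ.sum() == pytest.approx(1.0)

    def test_mass_conserved_every_cycle(self, params):
        for strategy in om.base_case_strategies():
            trace = run_trace(strategy, params)
            for rec in trace.records:
                assert rec.alive + rec.deaths_cum == pytest.approx(1.0, abs=1e-10)

    def test_neutral_treatment_equals_no_treatment(self, params):
        p = params.copy()
        for site in p.efficacy["denosumab"].rr:
            p.efficacy["denosumab"].rr[site] = {12: 1.0, 24: 1.0, 36: 1.0}
        neutral = om.denosumab()
        neutral.annual_drug_cost = 0.0
        neutral.nurse_visits_per_year = 0.0
        neutral.physician_visits_per_year = 0.0
        neutral.dxa_scans_per_year = 0.0
        a = om.evaluate(neutral, p)
        b = om.evaluate(om.no_treatment(), p)
        assert a.total_cost == pytest.approx(b.total_cost, abs=1e-9)
        assert a.qalys == pytest.approx(b.qalys, abs=1e-12)
        assert a.events["any"] == pytest.approx(b.events["any"], abs=1e-12)

    def test_survival_matches_life_table_product_without_fractures(
        self, no_fracture_params
    ):
        trace = run_trace(om.no_treatment(), no_fracture_params)
        surv = 1.0
        cfg = no_fracture_params.config
        for rec in trace.records:
            assert rec.alive == pytest.approx(surv, abs=1e-12)
            q_annual = no_fracture_params.q_annual(rec.age)
            surv *= (1 - q_annual) ** cfg.cycle_length

    def test_untreated_fracture_counts_dominate_treated(self, params):
        treated = run_trace(om.denosumab(), params).cumulative_events()
        untreated = run_trace(om.no_treatment(), params).cumulative_events()
        for site in ("hip", "vertebral", "wrist", "other", "any"):
            assert untreated[site] >= treated[site]

    def test_tunnel_depth_follows_mortality_window(self, params):
        assert n_tunnel_compartments(params) == 16
        p = om.apply_override(params, "config.excess_mortality_years", 3.0)
        assert n_tunnel_compartments(p) == 6
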