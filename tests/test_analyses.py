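"""Analyses: ICER classification, scenarios, OWSA plumbing, PSA machinery."""

import numpy as np
import pytest

import osteomark as om
from osteomark.analyses import (
    OWSAVariant,
    icer,
    owsa,
    psa,
    sample_parameters,
    scenario_grid,
)
from osteomark.economics import StrategyOutcome


def _outcome(cost, qaly, name="x"):
    return StrategyOutcome(name, cost, {}, {}, qaly, qaly)


class TestICER:
    def test_simple_ratio(self):
        res = icer(_outcome(1000.0, 0.01), _outcome(0.0, 0.0))
        assert res.icer == pytest.approx(100_000)
        assert res.classification == "icer"

    def test_dominant_when_cheaper_and_better(self):
        res = icer(_outcome(900.0, 1.01), _outcome(1000.0, 1.0))
        assert res.classification == "dominant"
        assert res.icer is None

    def test_dominated_when_costlier_and_worse(self):
        res = icer(_outcome(1100.0, 0.99), _outcome(1000.0, 1.0))
        assert res.classification == "dominated"

    def test_indifferent_at_zero_deltas(self):
        res = icer(_outcome(1000.0, 1.0), _outcome(1000.0, 1.0))
        assert res.classification == "indifferent"

    def test_equal_qalys_classified_by_cost_not_divided(self):
        res = icer(_outcome(1100.0, 1.0), _outcome(1000.0, 1.0))
        assert res.icer is None and res.classification == "dominated"


class TestEvaluate:
    def test_deterministic(self, params):
        a = om.evaluate(om.denosumab(), params)
        b = om.evaluate(om.denosumab(), params)
        assert a.total_cost == b.total_cost
        assert a.qalys == b.qalys

    def test_net_benefit_ranking_consistent_with_icer(self, params):
        den = om.evaluate(om.denosumab(), params)
        alen = om.evaluate(om.alendronate(), params)
        res = icer(den, alen)
        assert res.classification == "icer" and res.icer > 0
        for lam in (10_000.0, 300_000.0):
            nmb = lam * res.delta_qaly - res.delta_cost
            assert (nmb >= 0) == (lam >= res.icer)


class TestScenarioGrid:
    def test_base_combination_reproduces_base_case(self, params):
        den = om.evaluate(om.denosumab(), params)
        alen = om.evaluate(om.alendronate(), params)
        base = icer(den, alen)
        grid = scenario_grid(params, on_durations=(5.0,), holiday_durations=(2.0,),
                             include_5v5=False)
        assert grid.iloc[0]["icer"] == pytest.approx(base.icer)

    def test_grid_includes_5v5_special_case(self, params):
        grid = scenario_grid(params, on_durations=(), holiday_durations=())
        assert len(grid) == 1
        assert grid.iloc[0]["note"] == "both arms capped at 5 years"
        assert grid.iloc[0]["icer"] > 0


class TestOWSA:
    def test_identity_variant_reproduces_base(self, params):
        df = owsa([OWSAVariant("base"), OWSAVariant("same", {})], params)
        assert df.loc["base", "icer_vs_alendronate_value"] == (
            df.loc["same", "icer_vs_alendronate_value"]
        )

    def test_unknown_variable_raises(self, params):
        with pytest.raises(om.SchemaError):
            owsa([OWSAVariant("bad", {"not.a.path": 1})], params)

    def test_discount_variant_changes_only_discounting(self, params):
        df = owsa(
            [OWSAVariant("base"), OWSAVariant("d0", {"config.discount_rate_annual": 0.0})],
            params,
        )
        assert (df.loc["d0", "delta_qaly_vs_alendronate"]
                > df.loc["base", "delta_qaly_vs_alendronate"])


class TestPSA:
    def test_seed_reproducible(self, params):
        a = psa(params, n=3, seed=11)
        b = psa(params, n=3, seed=11)
        assert a.draws.equals(b.draws)
        assert np.allclose(a.ceac.values, b.ceac.values)

    def test_zero_variance_single_draw_equals_deterministic(self, params):
        det = om.evaluate(om.denosumab(), params)
        r = psa(params, n=1, seed=1, se_fraction=0.0)
        row = r.draws[r.draws.strategy == det.strategy].iloc[0]
        assert row.cost == pytest.approx(det.total_cost, abs=1e-9)
        assert row.qaly == pytest.approx(det.qalys, abs=1e-12)

    def test_sampled_parameters_respect_invariants(self, params):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = sample_parameters(params, rng)
            p.validate()
            for curve in p.persistence.values():
                vals = [curve.observed[m] for m in sorted(curve.observed)]
                assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_sampler_moment_matching(self):
        from osteomark.analyses import _beta, _lognormal

        rng = np.random.default_rng(0)
        ln = np.array([_lognormal(rng, 0.5, 0.05) for _ in range(4000)])
        assert ln.mean() == pytest.approx(0.5, abs=0.01)
        assert ln.std() == pytest.approx(0.05, abs=0.01)
        be = np.array([_beta(rng, 0.8, 0.08) for _ in range(4000)])
        assert be.mean() == pytest.approx(0.8, abs=0.01)
        assert ((be > 0) & (be < 1)).all()
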