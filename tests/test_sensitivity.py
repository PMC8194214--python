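"""Deterministic sweeps, threshold analysis, and first-/second-order Monte Carlo."""

import numpy as np
import pandas as pd
import pytest

from appendix_cea import (
    DistributionSpec,
    ParameterError,
    PSASamples,
    ceac,
    draw_parameters,
    generate_toy_tree,
    incremental_nmb_distribution,
    microsimulate,
    named_rng,
    one_way,
    population_simulation,
    psa_run,
    rollback,
    threshold_analysis,
    tornado,
)
from appendix_cea.engine import EngineError
from appendix_cea.sensitivity import get_parameter, set_parameter


# --------------------------------------------------------------------------
# parameter paths and draws
# --------------------------------------------------------------------------

class TestParameterPaths:
    def test_scalar_and_nested_targets_round_trip(self, params):
        p = params.copy()
        set_parameter(p, "p_oa_ssi", 0.2)
        assert get_parameter(p, "p_oa_ssi") == 0.2
        set_parameter(p, "utilities.ssi", 0.5)
        assert get_parameter(p, "utilities.ssi") == 0.5
        set_parameter(p, "cost_items.ssi.cephalexin_500mg.quantity", 10)
        assert get_parameter(p, "cost_items.ssi.cephalexin_500mg.quantity") == 10

    def test_nom_success_target_rescales_schedule(self, params):
        p = params.copy()
        set_parameter(p, "p_nom_success", 0.85)
        assert p.validate() == []
        assert p.cumulative_failure() == pytest.approx(0.15, abs=1e-9)

    def test_event_scale_target_multiplies_every_tariff(self, params):
        p = params.copy()
        base = p.event_cost_usd("nom_initial")
        set_parameter(p, "scale.cost_items.nom_initial", 0.5)
        assert p.event_cost_usd("nom_initial") == pytest.approx(0.5 * base, rel=1e-12)
        assert get_parameter(params, "scale.cost_items.nom_initial") == 1.0

    def test_unknown_target_rejected(self, params):
        with pytest.raises(ParameterError):
            set_parameter(params.copy(), "no_such_field", 1.0)
        with pytest.raises(ParameterError):
            get_parameter(params, "cost_items.ssi.nothing.quantity")


class TestDraws:
    def test_all_point_specs_return_base_exactly(self, params):
        specs = [
            DistributionSpec("point", {"value": params.p_oa_ssi}, "p_oa_ssi"),
            DistributionSpec("point", {"value": params.wtp}, "wtp"),
        ]
        drawn = draw_parameters(specs, params, named_rng(0, "psa"))
        assert drawn.to_dict() == params.to_dict()

    def test_dirichlet_draw_lands_on_simplex(self, params, specs):
        d = next(s for s in specs if s.kind == "dirichlet")
        rng = named_rng(1, "psa")
        for _ in range(50):
            drawn = draw_parameters([d], params, rng)
            branch = [drawn.p_oa_ssi, drawn.p_oa_abscess, drawn.p_oa_ileus]
            assert all(0 <= b <= 1 for b in branch)
            assert sum(branch) <= 1.0 + 1e-12  # residual no-complication mass

    def test_spec_with_unknown_target_rejected(self, params):
        spec = DistributionSpec("beta", {"alpha": 2, "beta": 2}, "not_a_field")
        with pytest.raises(ParameterError):
            draw_parameters([spec], params, named_rng(0, "psa"))

    @pytest.mark.parametrize(
        "kind, p, mean, var",
        [
            ("beta", {"alpha": 20.0, "beta": 80.0}, 0.2, 0.2 * 0.8 / 101.0),
            ("poisson", {"mean": 3.0}, 3.0, 3.0),
            ("uniform", {"lower": 2.0, "upper": 6.0}, 4.0, 16.0 / 12.0),
        ],
    )
    def test_moment_recovery_within_three_se(self, params, kind, p, mean, var):
        n = 10_000
        target = "p_oa_ssi" if kind == "beta" else "cost_items.ssi.cephalexin_500mg.quantity"
        spec = DistributionSpec(kind, p, target)
        rng = named_rng(11, "psa")
        draws = np.array([get_parameter(draw_parameters([spec], params, rng), target) for _ in range(n)])
        se = np.sqrt(var / n)
        assert abs(draws.mean() - mean) < 3 * se

    def test_dirichlet_moment_recovery(self, params, specs):
        d = next(s for s in specs if s.kind == "dirichlet")
        conc = np.asarray(d.parameters["concentration"])
        expected = conc[1] / conc.sum()  # marginal mean of the SSI branch
        rng = named_rng(13, "psa")
        n = 10_000
        draws = np.array([draw_parameters([d], params, rng).p_oa_ssi for _ in range(n)])
        var = expected * (1 - expected) / (conc.sum() + 1)
        assert abs(draws.mean() - expected) < 3 * np.sqrt(var / n)


# --------------------------------------------------------------------------
# deterministic sensitivity analysis
# --------------------------------------------------------------------------

class TestOneWay:
    def test_parameter_unused_by_strategy_has_zero_span(self, tree, params):
        entry = one_way("scale.cost_items.nom_initial", 0.5, 1.5, tree, params, strategy="LA")
        assert entry.span == pytest.approx(0.0, abs=1e-9)

    def test_linear_cost_parameter_moves_nmb_one_for_one(self, tree, params):
        # the LA package enters the LA strategy cost with weight 1 at year 0
        lo, hi = 400_000.0, 900_000.0
        entry = one_way("package_cost_la", lo, hi, tree, params, strategy="LA")
        expected = (hi - lo) * params.inflation_factor / params.exchange_rate
        assert entry.outcome_low - entry.outcome_high == pytest.approx(expected, rel=1e-9)
        assert entry.span == pytest.approx(expected, rel=1e-9)

    def test_tornado_sorted_by_descending_span(self, tree, params):
        entries = tornado(
            {
                "package_cost_la": (600_000.0, 1_000_000.0),
                "p_recur_complicated": (0.05, 0.2),
                "scale.cost_items.nom_initial": (0.8, 1.2),
            },
            tree,
            params,
            strategy="LA",
        )
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)

    def test_unknown_parameter_rejected(self, tree, params):
        with pytest.raises(ParameterError):
            one_way("nope", 0, 1, tree, params, strategy="LA")


class TestThreshold:
    def test_linear_crossing_matches_algebra(self, tree, params):
        """Sweep the LA package tariff until LA and OA reach NMB parity."""
        base = rollback(tree, params)
        d_nmb = (params.wtp * base["LA"].qalys - base["LA"].cost) - (
            params.wtp * base["OA"].qalys - base["OA"].cost
        )
        # NMB difference moves by -inflation/fx per COP of package tariff
        slope = params.inflation_factor / params.exchange_rate
        expected = params.package_cost_la + d_nmb / slope
        result = threshold_analysis(
            "package_cost_la", tree, params, "LA", "OA", 500_000.0, 1_500_000.0
        )
        assert result.crossed
        assert result.value == pytest.approx(expected, rel=1e-6)

    def test_parity_at_baseline_reports_zero_change(self, tree, params):
        p = params.copy()
        result = threshold_analysis(
            "package_cost_la", tree, p, "LA", "OA", 500_000.0, 1_500_000.0
        )
        p2 = p.copy()
        set_parameter(p2, "package_cost_la", result.value)
        confirm = threshold_analysis(
            "package_cost_la", tree, p2, "LA", "OA", result.value * 0.999, result.value * 1.001
        )
        assert confirm.crossed
        assert abs(confirm.percent_change) < 0.2

    def test_inert_parameter_declares_no_threshold(self, tree, params):
        result = threshold_analysis(
            "utilities.complicated_aa", tree, params, "LA", "OA", 0.5, 0.9
        )
        assert not result.crossed
        assert result.value is None


# --------------------------------------------------------------------------
# first-order microsimulation
# --------------------------------------------------------------------------

class TestMicrosimulation:
    def test_degenerate_tree_reproduces_rollback_every_trial(self):
        toy = generate_toy_tree(1, seed=4)
        res = rollback(toy.tree, toy.params)
        sim = microsimulate(toy.tree, toy.params, 20, named_rng(0, "microsim"))
        for strategy, group in sim.groupby("strategy"):
            assert np.allclose(group["cost"], res[strategy].cost)
            assert np.allclose(group["qalys"], res[strategy].qalys)

    def test_same_seed_gives_identical_samples(self, tree, params, specs):
        a = microsimulate(tree, params, 200, named_rng(5, "microsim"), specs=specs)
        b = microsimulate(tree, params, 200, named_rng(5, "microsim"), specs=specs)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_converges_to_expectation_within_three_se(self):
        toy = generate_toy_tree(2, seed=9, n_strategies=1)
        res = rollback(toy.tree, toy.params)
        sim = microsimulate(toy.tree, toy.params, 50_000, named_rng(3, "microsim"))
        costs = sim.loc[sim["strategy"] == "S1", "cost"]
        se = costs.std(ddof=1) / np.sqrt(len(costs))
        assert abs(costs.mean() - res["S1"].cost) < 3 * max(se, 1e-9)

    def test_utilities_only_mode_fixes_branch_outcome(self, tree, params, specs):
        sim = microsimulate(
            tree, params, 50, named_rng(2, "microsim"), specs=specs, utilities_only=True
        )
        for strategy, group in sim.groupby("strategy"):
            assert group["cost"].nunique() == 1  # expectation-weighted costs
            assert group["qalys"].nunique() > 1  # random utilities still vary

    def test_requires_at_least_one_trial(self, tree, params):
        with pytest.raises(EngineError):
            microsimulate(tree, params, 0, named_rng(0, "microsim"))


# --------------------------------------------------------------------------
# second-order PSA
# --------------------------------------------------------------------------

class TestPSA:
    def test_degenerate_specs_equal_deterministic_rollback_exactly(self, tree, params):
        specs = [DistributionSpec("point", {"value": params.p_oa_ssi}, "p_oa_ssi")]
        samples = psa_run(tree, params, specs, 5, named_rng(0, "psa"))
        res = rollback(tree, params)
        for _, row in samples.data.iterrows():
            assert row["cost"] == res[row["strategy"]].cost
            assert row["qalys"] == res[row["strategy"]].qalys
        summary = samples.summary()
        # identical samples; SD only differs from 0 by float round-off in the variance
        assert (summary["sd"].abs() < 1e-9).all()

    def test_summary_schema_mirrors_cost_and_qaly_blocks(self, psa_samples):
        summary = psa_samples.summary()
        assert set(summary.columns) == {"outcome", "strategy", "mean", "sd", "min", "median", "max"}
        assert len(summary) == 2 * 3  # cost/qalys x OA/LA/NOM

    def test_same_seed_bitwise_identical(self, tree, params, specs):
        a = psa_run(tree, params, specs, 50, named_rng(42, "psa"))
        b = psa_run(tree, params, specs, 50, named_rng(42, "psa"))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_strategies_share_each_iteration_draw(self, psa_samples):
        digests = psa_samples.data.groupby("iteration")["digest"].nunique()
        assert (digests == 1).all()

    def test_requires_at_least_one_iteration(self, tree, params, specs):
        with pytest.raises(EngineError):
            psa_run(tree, params, specs, 0, named_rng(0, "psa"))


class TestCEAC:
    def test_probabilities_sum_to_one_on_every_lambda(self, psa_samples):
        for point in ceac(psa_samples, np.linspace(0, 20001, 11)):
            assert sum(point.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(np.isfinite(v) for v in point.probabilities.values())

    def test_lambda_zero_rewards_minimal_cost(self, psa_samples):
        point = ceac(psa_samples, [0.0])[0]
        costs = psa_samples.matrix("cost")
        winners = costs.idxmin(axis=1).value_counts(normalize=True)
        for strategy, prob in point.probabilities.items():
            assert prob == pytest.approx(winners.get(strategy, 0.0), abs=1e-12)

    def test_single_iteration_yields_indicator(self, tree, params, specs):
        samples = psa_run(tree, params, specs, 1, named_rng(3, "psa"))
        point = ceac(samples, [6667.0])[0]
        assert sorted(point.probabilities.values()) == [0.0, 0.0, 1.0]

    def test_empty_grid_rejected(self, psa_samples):
        with pytest.raises(EngineError):
            ceac(psa_samples, [])


class TestIncrementalNMB:
    def test_self_comparison_degenerates_to_zero(self, psa_samples):
        out = incremental_nmb_distribution(psa_samples, "LA", "LA", 6667.0)
        assert out["mean"] == 0.0
        assert out["p_positive"] == 0.0

    def test_delta_nmb_identity_scales_with_lambda(self):
        # constructed samples with known ΔE > 0: ΔNMB(λ) = ΔE·λ − ΔC exactly
        rows = []
        for it, (dc, de) in enumerate([(50.0, 0.01), (-20.0, 0.02), (10.0, 0.005)]):
            rows.append({"iteration": it, "strategy": "A", "cost": 100 + dc, "qalys": 1 + de, "digest": "x"})
            rows.append({"iteration": it, "strategy": "B", "cost": 100.0, "qalys": 1.0, "digest": "x"})
        samples = PSASamples(pd.DataFrame(rows), redraws=0)
        lo = incremental_nmb_distribution(samples, "A", "B", 6667.0)
        hi = incremental_nmb_distribution(samples, "A", "B", 2 * 6667.0)
        des = np.array([0.01, 0.02, 0.005])
        dcs = np.array([50.0, -20.0, 10.0])
        assert lo["mean"] == pytest.approx((des * 6667 - dcs).mean(), rel=1e-12)
        assert hi["mean"] - lo["mean"] == pytest.approx((des * 6667).mean(), rel=1e-12)

    def test_unknown_strategy_rejected(self, psa_samples):
        with pytest.raises(EngineError):
            incremental_nmb_distribution(psa_samples, "LA", "XX", 6667.0)


class TestPopulationSimulation:
    def test_over_expenditure_is_mean_total_difference(self, tree, params, specs):
        pop = population_simulation(tree, params, specs, 500, named_rng(1, "population"), n_iterations=20)
        expected = pop.totals["OA"].mean() - pop.totals["LA"].mean()
        assert pop.over_expenditure("OA", "LA") == pytest.approx(expected, rel=1e-12)

    def test_single_patient_is_one_microsimulation_trial(self, tree, params):
        pop = population_simulation(tree, params, [], 1, named_rng(2, "population"), n_iterations=30)
        # one patient: each iteration total is one sampled path cost
        compiled_costs = set()
        from appendix_cea.engine import compile_tree

        for strategy, cs in compile_tree(tree, params).items():
            compiled_costs.update(round(c, 9) for c in cs.path_costs(params))
        for value in pop.totals.to_numpy().ravel():
            assert round(float(value), 9) in compiled_costs

    def test_totals_scale_with_population_size(self, tree, params, specs):
        small = population_simulation(tree, params, specs, 100, named_rng(3, "population"), n_iterations=40)
        large = population_simulation(tree, params, specs, 10_000, named_rng(3, "population"), n_iterations=40)
        ratio = large.totals["LA"].mean() / small.totals["LA"].mean()
        assert ratio == pytest.approx(100.0, rel=0.1)

    def test_requires_positive_sizes(self, tree, params, specs):
        with pytest.raises(EngineError):
            population_simulation(tree, params, specs, 0, named_rng(0, "population"))
        with pytest.raises(EngineError):
            population_simulation(tree, params, specs, 10, named_rng(0, "population"), n_iterations=0)


def test_named_streams_are_distinct():
    a = named_rng(7, "psa").uniform(size=5)
    b = named_rng(7, "microsim").uniform(size=5)
    c = named_rng(7, "population").uniform(size=5)
    assert not np.allclose(a, b)
    assert not np.allclose(a, c)
    with pytest.raises(EngineError):
        named_rng(7, "nope")
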