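"""ICER/dominance, NMB, bootstrap resampling, percentile CIs and CEAC."""

import numpy as np
import pandas as pd
import pytest

from trialcea.econ_eval import (
    ArmSummary,
    EvaluationConfig,
    bootstrap_arms,
    ceac,
    evaluate,
    incremental,
    nmb,
    percentile_ci,
)

from conftest import make_analysis_frame


def _pair(dc, de, ref_cost=1000.0, ref_eff=0.10):
    ref = ArmSummary("UC", ref_cost, ref_eff, 100)
    treat = ArmSummary("MT", ref_cost + dc, ref_eff + de, 100)
    return treat, ref


class TestIncremental:
    def test_northeast_tradeoff_ratio(self):
        res = incremental(*_pair(255.0, 0.05))
        assert res.ratio == pytest.approx(5100.0)
        assert res.classification == "tradeoff_NE"

    def test_dominated_quadrant(self):
        res = incremental(*_pair(806.0, -0.02))
        assert res.classification == "dominated"
        assert res.ratio == pytest.approx(-40_300.0)

    def test_dominant_quadrant(self):
        res = incremental(*_pair(-100.0, 0.01))
        assert res.classification == "dominant"

    def test_identical_summaries(self):
        s = ArmSummary("UC", 500.0, 0.1, 50)
        res = incremental(s, s)
        assert res.delta_cost == 0 and res.delta_effect == 0
        assert res.ratio is None
        assert res.classification == "equivalent"

    def test_equal_effects_classified_by_cost_sign(self):
        assert incremental(*_pair(10.0, 0.0)).classification == "dominated"
        assert incremental(*_pair(-10.0, 0.0)).classification == "dominant"

    def test_sign_convention_ratio_equal_labels_flip(self):
        """(dC,dE) and (-dC,-dE) give the same ratio; the label flips."""
        a = incremental(*_pair(255.0, 0.05))
        b = incremental(*_pair(-255.0, -0.05))
        assert a.ratio == pytest.approx(b.ratio)
        assert a.classification == "tradeoff_NE"
        assert b.classification == "tradeoff_SW"
        c = incremental(*_pair(-806.0, 0.02))
        d = incremental(*_pair(806.0, -0.02))
        assert {c.classification, d.classification} == {"dominant", "dominated"}


class TestNmb:
    def test_worked_example(self):
        assert nmb(0.05, 255.0, 18_000.0) == pytest.approx(645.0)

    def test_zero_wtp_is_minus_cost(self):
        assert nmb(0.3, 120.0, 0.0) == pytest.approx(-120.0)

    def test_null_differences(self):
        for w in (0.0, 500.0, 1e5):
            assert nmb(0.0, 0.0, w) == 0.0

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(0.1, 10.0, -1.0)


class TestBootstrapArms:
    def test_singleton_arms_reproduce_observed(self):
        df = pd.DataFrame({"arm": ["A", "B"], "cost": [10.0, 20.0],
                           "effect": [0.0, 1.0]})
        reps = bootstrap_arms(df, 1, seed=0)
        assert reps.costs.tolist() == [[10.0, 20.0]]
        assert reps.effects["effect"].tolist() == [[0.0, 1.0]]

    def test_constant_dataset_gives_constant_replicates(self):
        df = pd.DataFrame({"arm": ["A"] * 30 + ["B"] * 30,
                           "cost": 7.0, "effect": 0.5})
        reps = bootstrap_arms(df, 50, seed=1)
        assert np.all(reps.costs == 7.0)
        assert np.all(reps.effects["effect"] == 0.5)

    def test_percentile_ci_brackets_analytic_mean(self):
        df = pd.DataFrame({"arm": "A", "cost": np.arange(1.0, 101.0),
                           "effect": 0.0})
        reps = bootstrap_arms(df, 5000, seed=2)
        lo, hi = percentile_ci(reps.costs[:, 0], 0.95)
        assert lo < 50.5 < hi
        assert hi - lo < 25  # sanity: SE of the mean ~2.9

    def test_deterministic_given_seed(self, analysis_frame):
        a = bootstrap_arms(analysis_frame, 100, seed=3,
                           cost_col="health_cost",
                           effect_cols=("abstinent", "qaly"))
        b = bootstrap_arms(analysis_frame, 100, seed=3,
                           cost_col="health_cost",
                           effect_cols=("abstinent", "qaly"))
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.effects["qaly"], b.effects["qaly"])

    def test_empty_arm_rejected(self):
        df = pd.DataFrame({"arm": ["A"], "cost": [1.0], "effect": [0.0]})
        df = df[df["arm"] == "B"]
        with pytest.raises(ValueError):
            bootstrap_arms(df, 10, seed=0)

    def test_nan_rows_excluded_per_outcome(self):
        df = pd.DataFrame({"arm": "A", "cost": [5.0, np.nan, 5.0],
                           "effect": [1.0, 1.0, np.nan]})
        reps = bootstrap_arms(df, 20, seed=4)
        assert np.all(reps.costs == 5.0)
        assert np.all(reps.effects["effect"] == 1.0)


class TestPercentileCi:
    def test_degenerate_distribution(self):
        assert percentile_ci([3.0] * 10) == (3.0, 3.0)

    def test_linear_interpolation_definition(self):
        lo, hi = percentile_ci(np.arange(1.0, 1001.0), 0.95)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_symmetric_about_median_for_symmetric_sample(self):
        x = np.concatenate([np.arange(-500, 0), np.arange(1, 501)])
        lo, hi = percentile_ci(x, 0.9)
        med = np.median(x)
        assert (med - lo) == pytest.approx(hi - med)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            percentile_ci([1.0])


def _reps_from(costs, effects):
    from trialcea.econ_eval import BootstrapReplicates
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    return BootstrapReplicates(
        arms=tuple(f"arm{i}" for i in range(costs.shape[1])),
        costs=costs, effects={"effect": effects},
    )


class TestCeac:
    def test_probabilities_sum_to_one_everywhere(self):
        rng = np.random.default_rng(6)
        reps = _reps_from(rng.normal(1000, 200, (400, 3)),
                          rng.random((400, 3)))
        curve = ceac(reps, np.arange(0, 50_001, 500))
        total = curve.probabilities.sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_wtp_zero_equals_lowest_cost_probability(self):
        rng = np.random.default_rng(7)
        costs = rng.normal(100, 30, (500, 3))
        reps = _reps_from(costs, rng.random((500, 3)))
        curve = ceac(reps, [0.0])
        lowest = (costs.argmin(axis=1)[:, None] == np.arange(3)).mean(axis=0)
        assert curve.probabilities.iloc[0].to_numpy() == pytest.approx(lowest)

    def test_everywhere_dominant_arm_has_probability_one(self):
        costs = np.column_stack([np.full(100, 50.0), np.full(100, 80.0)])
        eff = np.column_stack([np.full(100, 0.9), np.full(100, 0.1)])
        curve = ceac(_reps_from(costs, eff), np.arange(0, 20_001, 1000))
        assert np.all(curve.probabilities["arm0"].to_numpy() == 1.0)
        assert np.all(curve.probabilities["arm1"].to_numpy() == 0.0)

    def test_exact_ties_split_equally(self):
        costs = np.full((10, 2), 30.0)
        eff = np.full((10, 2), 0.4)
        curve = ceac(_reps_from(costs, eff), [0.0, 18_000.0])
        assert np.allclose(curve.probabilities.to_numpy(), 0.5)

    def test_symmetric_identical_arms_near_half(self):
        rng = np.random.default_rng(8)
        half = rng.normal(1000, 100, (2000, 1))
        costs = np.hstack([half, rng.normal(1000, 100, (2000, 1))])
        eff = np.hstack([rng.normal(0.5, 0.05, (2000, 1)),
                         rng.normal(0.5, 0.05, (2000, 1))])
        curve = ceac(_reps_from(costs, eff), [18_000.0])
        assert curve.probabilities.iloc[0, 0] == pytest.approx(0.5, abs=0.05)

    def test_empty_grid_rejected(self):
        reps = _reps_from(np.zeros((5, 2)), np.zeros((5, 2)))
        with pytest.raises(ValueError):
            ceac(reps, [])

    def test_ranking_invariant_to_common_cost_shift(self):
        rng = np.random.default_rng(9)
        costs = rng.normal(500, 50, (300, 3))
        eff = rng.random((300, 3))
        grid = [0.0, 9_000.0, 40_000.0]
        a = ceac(_reps_from(costs, eff), grid)
        b = ceac(_reps_from(costs + 123.45, eff), grid)
        pd.testing.assert_frame_equal(a.probabilities, b.probabilities)


class TestEvaluate:
    def test_bundle_deterministic_given_seed(self, analysis_frame):
        cfg = EvaluationConfig(seed=5, reps_cost=200, reps_ceac=150)
        a = evaluate(analysis_frame, cfg)
        b = evaluate(analysis_frame, cfg)
        for key in ("arm_summaries", "incrementals", "cost_ci", "ceac",
                    "cuac", "probabilities_at_wtp"):
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_sensitivity_scenario_shifts_costs_exactly(self, analysis_frame):
        cfg = EvaluationConfig(seed=5, reps_cost=50, reps_ceac=50)
        bundle = evaluate(analysis_frame, cfg)
        prim = bundle["arm_summaries"].set_index(["arm", "outcome"])
        sens = bundle["sensitivity"]["arm_summaries"].set_index(["arm", "outcome"])
        diff = (sens["mean_cost"] - prim["mean_cost"]).groupby("arm").first()
        assert diff["MTC"] == pytest.approx(84.19)
        assert diff["MT"] == pytest.approx(74.54)
        assert diff["UC"] == pytest.approx(0.0)

    def test_equal_effects_ceac_determined_by_costs(self):
        rng = np.random.default_rng(10)
        df = make_analysis_frame(rng, n_per_arm=40,
                                 cost_means=(2000.0, 1200.0, 800.0),
                                 abst_probs=(0.0, 0.0, 0.0))
        df["qaly"] = 0.8
        cfg = EvaluationConfig(seed=1, reps_cost=50, reps_ceac=400)
        bundle = evaluate(df, cfg)
        cuac = bundle["cuac"]
        # identical QALYs everywhere: the cheapest arm (UC, even with zero
        # intervention cost) wins at every willingness to pay
        assert (cuac["UC"] > 0.9).all()

    def test_incrementals_cover_both_scales_and_reference(self, analysis_frame):
        cfg = EvaluationConfig(seed=2, reps_cost=50, reps_ceac=50)
        bundle = evaluate(analysis_frame, cfg)
        inc = bundle["incrementals"]
        assert set(inc["outcome"]) == {"abstinent", "qaly"}
        assert set(inc["comparison"]) == {"MTC vs UC", "MT vs UC", "MTC vs MT"}
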