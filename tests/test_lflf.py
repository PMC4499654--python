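"""Tests of the linguistic fuzzy-logic forecaster and SMAPE classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgdx.ftransform import FTComponents, inverse_ftransform, uniform_partition
from ecgdx.lflf import (
    Context,
    EvaluativeExpression,
    FuzzyRule,
    LflfConfig,
    RuleSignature,
    SmapeClassification,
    classify_by_smape,
    component_differences,
    deduce,
    fit_forecaster,
    fit_seasonal,
    forecast,
    generate_rules,
    linguistic_eval,
    select_best_predictor,
    smape,
    verdict_from_smape,
)


class TestComponentDifferences:
    def test_constant_components(self):
        cs = component_differences(np.full(6, 2.0))
        assert np.all(cs.dX == 0) and np.all(cs.d2X == 0)

    def test_linear_components(self):
        cs = component_differences([1.0, 2.0, 3.0, 4.0])
        assert np.array_equal(cs.dX, [1.0, 1.0, 1.0])
        assert np.array_equal(cs.d2X, [0.0, 0.0])

    def test_matches_loop_recomputation(self, rng):
        X = rng.normal(size=12)
        cs = component_differences(X)
        for i in range(1, 12):
            assert cs.dX[i - 1] == pytest.approx(X[i] - X[i - 1])
        for i in range(2, 12):
            assert cs.d2X[i - 2] == pytest.approx((X[i] - X[i - 1]) - (X[i - 1] - X[i - 2]))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            component_differences([1.0, 2.0])


class TestLinguisticEval:
    def test_context_minimum_is_sharpest_small(self):
        expr, degree = linguistic_eval(3.0, Context(3.0, 9.0))
        assert expr.atomic == "sm" and expr.hedge == "ex"
        assert degree == 1.0

    def test_midpoint_is_plain_medium(self):
        expr, degree = linguistic_eval(6.0, Context(3.0, 9.0))
        assert expr.atomic == "me" and expr.hedge == ""
        assert degree == 1.0

    def test_maximum_is_sharpest_big(self):
        expr, _ = linguistic_eval(9.0, Context(3.0, 9.0))
        assert expr.atomic == "bi" and expr.hedge == "ex"

    def test_sweep_moves_monotonically_small_medium_big(self):
        ctx = Context(0.0, 1.0)
        order = {"sm": 0, "me": 1, "bi": 2}
        seen = [order[linguistic_eval(v, ctx)[0].atomic] for v in np.linspace(0, 1, 100)]
        assert seen == sorted(seen)
        assert set(seen) == {0, 1, 2}

    def test_signed_context_zero_maps_to_zero_expression(self):
        expr, degree = linguistic_eval(0.0, Context(-2.0, 2.0, signed=True))
        assert expr.atomic == "ze" and degree == 1.0

    def test_signed_context_negative_value(self):
        expr, _ = linguistic_eval(-1.0, Context(-2.0, 2.0, signed=True))
        assert expr.sign == -1

    def test_degenerate_context_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            linguistic_eval(1.0, Context(2.0, 2.0))


class TestExpressions:
    @pytest.mark.parametrize("text", ["ml sm", "qr sm", "-me", "ve bi", "ze", "-ro sm"])
    def test_render_parse_round_trip(self, text):
        assert EvaluativeExpression.parse(text).render() == text

    def test_rule_renders_to_readable_sentence_and_parses_back(self):
        rule = FuzzyRule(
            antecedents=(
                ("S(t)", EvaluativeExpression.parse("ml sm")),
                ("dS(t)", EvaluativeExpression.parse("qr sm")),
            ),
            consequent=("dS(t+1)", EvaluativeExpression.parse("-me")),
        )
        text = rule.render()
        assert text == "IF S(t) is ml sm AND dS(t) is qr sm THEN dS(t+1) is -me"
        parsed = FuzzyRule.parse(text)
        assert parsed.antecedents == rule.antecedents
        assert parsed.consequent == rule.consequent


class TestGenerateRules:
    SIG = RuleSignature.parse("S(t)&dS(t) -> dS(t+1)")

    def test_constant_components_collapse_to_one_zero_rule(self):
        desc = generate_rules(np.full(20, 3.0), self.SIG)
        assert len(desc.rules) == 1
        assert desc.rules[0].consequent[1].render() == "ze"

    def test_rule_count_bounded_by_time_indices(self, rng):
        X = rng.normal(size=25)
        desc = generate_rules(X, self.SIG)
        assert len(desc.rules) <= len(self.SIG.index_range(25))

    def test_signature_fixes_antecedent_count(self, rng):
        X = rng.normal(size=25)
        desc = generate_rules(X, self.SIG)
        assert all(len(r.antecedents) == 2 for r in desc.rules)

    def test_deterministic_rule_base(self, rng):
        X = rng.normal(size=30)
        d1 = generate_rules(X, self.SIG)
        d2 = generate_rules(X, self.SIG)
        assert d1.render() == d2.render()

    def test_insufficient_components_raise(self):
        with pytest.raises(ValueError):
            generate_rules(np.array([1.0, 2.0]), self.SIG)


class TestDeduce:
    def test_anchored_rule_returns_its_consequent_centroid(self):
        X = np.linspace(0.0, 1.0, 10)  # strictly rising components
        sig = RuleSignature.parse("dS(t) -> dS(t+1)")
        desc = generate_rules(X, sig)
        # all differences are identical -> single rule; deduction at the same
        # difference must return the consequent centroid in context units
        assert len(desc.rules) == 1
        out = deduce(desc, {"dS(t)": X[1] - X[0]})
        expr = desc.rules[0].consequent[1]
        assert out == pytest.approx(desc.contexts["dS(t+1)"].denormalize(expr.centroid()))

    def test_closer_rule_wins(self):
        sig = RuleSignature.parse("S(t) -> S(t+1)")
        ctx = Context(0.0, 1.0)
        rule_low = FuzzyRule(
            antecedents=(("S(t)", EvaluativeExpression.parse("ex sm")),),
            consequent=("S(t+1)", EvaluativeExpression.parse("ex sm")),
        )
        rule_high = FuzzyRule(
            antecedents=(("S(t)", EvaluativeExpression.parse("ex bi")),),
            consequent=("S(t+1)", EvaluativeExpression.parse("ex bi")),
        )
        from ecgdx.lflf import LinguisticDescription

        desc = LinguisticDescription(
            rules=[rule_low, rule_high],
            signature=sig,
            contexts={"S(t)": ctx, "S(t+1)": ctx},
        )
        low = deduce(desc, {"S(t)": 0.0})
        high = deduce(desc, {"S(t)": 1.0})
        assert low < 0.5 < high

    def test_empty_description_raises(self):
        from ecgdx.lflf import LinguisticDescription

        desc = LinguisticDescription(
            rules=[], signature=RuleSignature.parse("S(t) -> S(t+1)"), contexts={}
        )
        with pytest.raises(ValueError, match="empty"):
            deduce(desc, {"S(t)": 0.5})


class TestSeasonalAR:
    def test_recovers_ar1_coefficient(self):
        rng = np.random.default_rng(5)
        x = np.zeros(500)
        for t in range(1, 500):
            x[t] = 0.8 * x[t - 1] + rng.normal(0, 0.1)
        model = fit_seasonal(x, order=1)
        assert model.coef[0] == pytest.approx(0.8, abs=0.1)

    def test_zero_residual_gives_zero_model(self):
        model = fit_seasonal(np.zeros(50))
        assert np.allclose(model.coef, 0.0)
        assert np.allclose(model.forecast(np.zeros(50), 5), 0.0)

    def test_order_larger_than_data_raises(self):
        with pytest.raises(ValueError):
            fit_seasonal(np.zeros(4), order=10)

    def test_order_selection_finds_low_order_process(self):
        rng = np.random.default_rng(6)
        x = np.zeros(400)
        for t in range(1, 400):
            x[t] = 0.9 * x[t - 1] + rng.normal(0, 0.05)
        model = fit_seasonal(x)
        assert 1 <= model.order <= 5


class TestForecast:
    def test_constant_series_forecasts_its_own_value(self):
        model = fit_forecaster(np.full(100, 5.0), "S(t)&dS(t) -> dS(t+1)")
        fc = forecast(model, 15)
        assert np.allclose(fc.values, 5.0, atol=1e-9)

    def test_composition_identity(self, rng):
        series = np.sin(np.arange(120) / 6.0) + rng.normal(0, 0.05, 120)
        model = fit_forecaster(series, "S(t)&dS(t) -> dS(t+1)")
        fc = forecast(model, 10)
        assert np.allclose(fc.values, fc.trend + fc.seasonal, atol=1e-12)

    def test_beats_flat_mean_on_trended_sinusoid(self):
        t = np.arange(1.0, 221.0)
        series = 0.05 * t + np.sin(2 * np.pi * t / 20.0)
        train, val = series[:200], series[200:]
        model = select_best_predictor(train, val)
        flat = np.full(len(val), train.mean())
        assert model.smape_validation < smape(val, flat)

    def test_bad_horizon_raises(self):
        model = fit_forecaster(np.full(50, 1.0), "S(t) -> S(t+1)")
        with pytest.raises(ValueError):
            forecast(model, 0)


class TestSmape:
    def test_identical_vectors(self):
        assert smape([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_single_point_arithmetic(self):
        assert smape([1.0], [3.0]) == pytest.approx(100.0)

    def test_all_zero_pairs_contribute_nothing(self):
        assert smape([0.0, 1.0], [0.0, 1.0]) == 0.0

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, a, seed):
        f = np.random.default_rng(seed).uniform(-50, 50, len(a))
        assert smape(a, f) == pytest.approx(smape(f, np.asarray(a)))

    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-10, 10, 12)
        f = rng.uniform(-10, 10, 12)
        assert smape(c * a, c * f) == pytest.approx(smape(a, f), rel=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            smape([1.0], [1.0, 2.0])


class TestSelectBestPredictor:
    def test_singleton_menu_wins_trivially(self):
        t = np.arange(1.0, 121.0)
        series = np.sin(2 * np.pi * t / 15.0)
        model = select_best_predictor(series[:100], series[100:], ["dS(t) -> dS(t+1)"])
        assert model.signature.render() == "dS(t) -> dS(t+1)"

    def test_reported_smape_matches_independent_reevaluation(self):
        t = np.arange(1.0, 161.0)
        series = 0.02 * t + np.cos(2 * np.pi * t / 25.0)
        train, val = series[:140], series[140:]
        model = select_best_predictor(train, val)
        fc = forecast(model, len(val))
        assert model.smape_validation == pytest.approx(smape(val, fc.values))

    def test_empty_menu_raises(self):
        with pytest.raises(ValueError):
            select_best_predictor(np.zeros(50), np.zeros(5), [])


def _planted_series(seed: int, n: int = 80, spacing: int = 7, noise: float = 0.02):
    """Series whose component dynamics follow dX_{i+1} = dX_i - 0.3(X_i - 5)."""
    rng = np.random.default_rng(seed)
    X = [5.0, 5.0 + rng.uniform(0.5, 1.0)]
    for _ in range(n - 2):
        dx = X[-1] - X[-2]
        X.append(X[-1] + dx - 0.3 * (X[-1] - 5.0))
    X = np.array(X)
    T = (n - 1) * spacing + 1
    part = uniform_partition(1, T, n)
    t = np.arange(1, T + 1, dtype=float)
    series = inverse_ftransform(FTComponents(X, part, t), t)
    return series + rng.normal(0, noise, T)


class TestSignatureRecovery:
    def test_planted_signature_attains_minimal_validation_smape(self):
        hits = 0
        for seed in range(10):
            series = _planted_series(seed)
            train, val = series[:-42], series[-42:]
            model = select_best_predictor(train, val)
            hits += model.signature.render() == "S(t)&dS(t) -> dS(t+1)"
        assert hits >= 7


class TestClassifyBySmape:
    @pytest.mark.parametrize(
        "sh,ss,verdict",
        [
            (1.33555, 3.40168, "healthy"),
            (1.72265, 1.31922, "sick"),
            (2.0, 2.0, "sick"),  # ties fall to the sick branch
        ],
    )
    def test_decision_rule(self, sh, ss, verdict):
        assert verdict_from_smape(sh, ss) == verdict

    def test_returns_both_smapes_and_consistent_verdict(self):
        rng = np.random.default_rng(0)
        healthy = np.sin(np.arange(400) / 8.0) + rng.normal(0, 0.05, 400) + 2.0
        sick = 0.4 * np.sin(np.arange(400) / 8.0) + rng.normal(0, 0.05, 400) + 2.0
        tested = 0.4 * np.sin(np.arange(80) / 8.0) + rng.normal(0, 0.05, 80) + 2.0
        result = classify_by_smape(healthy, sick, tested)
        assert isinstance(result, SmapeClassification)
        assert result.verdict == verdict_from_smape(result.smape_healthy, result.smape_sick)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            classify_by_smape([], [1.0, 2.0], [1.0])
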