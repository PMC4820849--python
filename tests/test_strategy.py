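"""Strategy transforms and binomial / Poisson-binomial reliability maths."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from conflictplan import (
    StrategySpec,
    apply_strategy,
    count_abandoned,
    enforce_reliability,
    greedy_solve,
    meeting_probability,
    meeting_probability_hetero,
    required_units,
)

from conftest import toy_features, toy_units


def enumerate_meeting_probability(p, amounts, target):
    """Independent oracle: sum over all 2^n survive/lose outcomes."""
    total = 0.0
    n = len(p)
    for outcome in itertools.product([0, 1], repeat=n):
        prob = 1.0
        amt = 0.0
        for survive, pi, ai in zip(outcome, p, amounts):
            prob *= (1 - pi) if survive else pi
            amt += ai if survive else 0.0
        if amt >= target - 1e-12:
            total += prob
    return total


class TestMeetingProbability:
    def test_worked_example_six_units_quarter_risk(self):
        """Six units at 25% loss risk protect a 3-unit target with p=0.962."""
        assert meeting_probability(6, 3, 0.25) == pytest.approx(0.962, abs=5e-4)

    def test_impossible_and_lossless_limits(self):
        assert meeting_probability(2, 3, 0.1) == 0.0
        assert meeting_probability(5, 5, 0.0) == 1.0
        assert meeting_probability(5, 0, 1.0) == 1.0

    def test_four_choose_two_enumeration(self):
        # all 2^4 equally likely outcomes at p=0.5: 11/16 keep >= 2 survivors
        assert meeting_probability(4, 2, 0.5) == pytest.approx(11 / 16)
        assert enumerate_meeting_probability(
            [0.5] * 4, [1] * 4, 2
        ) == pytest.approx(11 / 16)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            meeting_probability(-1, 0, 0.5)
        with pytest.raises(ValueError):
            meeting_probability(3, -2, 0.5)

    @given(
        n=hs.integers(0, 30), k=hs.integers(0, 30),
        p=hs.floats(0, 1), dp=hs.floats(0, 0.5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_all_arguments(self, n, k, p, dp):
        base = meeting_probability(n, k, p)
        assert meeting_probability(n + 1, k, p) >= base - 1e-12
        assert meeting_probability(n, k + 1, p) <= base + 1e-12
        assert meeting_probability(n, k, min(1.0, p + dp)) <= base + 1e-12


class TestMeetingProbabilityHetero:
    def test_reduces_to_binomial_under_equal_risks(self):
        for n, k, p in [(6, 3, 0.25), (4, 2, 0.5), (8, 5, 0.1)]:
            assert meeting_probability_hetero(
                [p] * n, [1.0] * n, k
            ) == pytest.approx(meeting_probability(n, k, p), abs=1e-12)

    def test_zero_risk_always_meets_attainable_target(self):
        assert meeting_probability_hetero([0, 0, 0], [1, 2, 3], 6) == 1.0

    def test_unattainable_target_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert meeting_probability_hetero([0.1], [1.0], 2.0) == 0.0

    def test_exact_enumeration_matches_independent_oracle(self):
        p = [0.1, 0.2, 0.3, 0.1, 0.5, 0.05]
        a = [1.0] * 6
        exact = meeting_probability_hetero(p, a, 4)
        assert exact == pytest.approx(enumerate_meeting_probability(p, a, 4),
                                      abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration_within_3_se(self):
        rng = np.random.default_rng(0)
        p = [0.1, 0.2, 0.3, 0.1, 0.5, 0.05]
        a = [1.0] * 6
        exact = meeting_probability_hetero(p, a, 4)
        mc, se = meeting_probability_hetero(
            p, a, 4, exact_limit=2, n_reps=100_000, rng=rng, return_se=True
        )
        assert abs(mc - exact) <= 3 * se

    @given(
        p=hs.lists(hs.floats(0, 0.9), min_size=2, max_size=8),
        frac=hs.floats(0.1, 0.9),
    )
    @settings(derandomize=True, max_examples=100)
    def test_probability_bounds_and_monotone_target(self, p, frac):
        a = [1.0] * len(p)
        t1 = frac * len(p)
        v1 = meeting_probability_hetero(p, a, t1)
        v2 = meeting_probability_hetero(p, a, min(t1 + 0.5, len(p)))
        assert 0 <= v2 <= v1 + 1e-9
        assert v1 <= 1 + 1e-12


class TestRequiredUnits:
    def test_worked_example_needs_six_units(self):
        """Five units give 89.65% < 95%; six give 96.24%."""
        assert required_units(3, 0.25, 0.95) == 6
        assert meeting_probability(5, 3, 0.25) == pytest.approx(0.8965, abs=5e-4)

    def test_no_losses_needs_exactly_the_requirement(self):
        assert required_units(3, 0.0, 0.99) == 3

    def test_closed_form_two_units(self):
        # P(at least 1 of n survives) = 1 - 0.5^n; need n=2 for rho=0.75
        assert required_units(1, 0.5, 0.75) == 2

    def test_certain_loss_rejected(self):
        with pytest.raises(ValueError):
            required_units(2, 1.0, 0.9)

    @given(p=hs.floats(0, 0.8), rho=hs.floats(0.5, 0.99))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_loss_and_reliability(self, p, rho):
        base = required_units(3, p, rho)
        assert required_units(3, min(p + 0.1, 0.95), rho) >= base
        assert required_units(3, p, min(rho + 0.009, 0.995)) >= base


class TestApplyStrategy:
    def setup_method(self):
        self.units = toy_units([1.0, 2.0, 3.0, 4.0])
        self.features = toy_features({"A": [10, 10, 0, 0], "B": [0, 0, 5, 5]})
        self.risks = {0: 0.4, 1: 0.0, 2: 0.5, 3: 0.2}

    def test_ignorant_is_identity(self):
        prob = apply_strategy(self.units, self.risks, self.features,
                              StrategySpec("ignorant", target_fraction=0.5))
        assert list(prob.unit_ids) == [0, 1, 2, 3]
        np.testing.assert_allclose(prob.amounts, prob.raw_amounts)
        np.testing.assert_allclose(prob.targets, [10.0, 5.0])

    def test_avoiding_excludes_above_threshold(self):
        prob = apply_strategy(self.units, self.risks, self.features,
                              StrategySpec("avoiding", threshold=0.35))
        assert all(p <= 0.35 for p in prob.risk)
        assert set(prob.unit_ids) == {1, 3}

    def test_accounting_discounts_amounts(self):
        units = toy_units([1.0, 1.0])
        features = toy_features({"A": [10, 10]})
        prob = apply_strategy(units, {0: 0.4, 1: 0.0}, features,
                              StrategySpec("accounting"))
        np.testing.assert_allclose(prob.amounts[0], [6.0, 10.0])

    def test_sensitive_excludes_then_discounts(self):
        prob = apply_strategy(self.units, self.risks, self.features,
                              StrategySpec("sensitive", threshold=0.35))
        assert set(prob.unit_ids) == {1, 3}
        # unit 3 (p=0.2) discounted to 5*0.8
        np.testing.assert_allclose(prob.amounts[1], [0.0, 4.0])

    def test_locked_in_units_survive_exclusion(self):
        units = toy_units([1.0, 1.0], status=["locked_in", "available"])
        prob = apply_strategy(units, {0: 0.9, 1: 0.1},
                              toy_features({"A": [5, 5]}),
                              StrategySpec("avoiding", threshold=0.3))
        assert 0 in prob.unit_ids
        assert prob.locked_in[list(prob.unit_ids).index(0)]

    def test_infeasible_target_capped_and_flagged(self):
        units = toy_units([1.0])
        prob = apply_strategy(units, {0: 0.9}, toy_features({"A": [10]}),
                              StrategySpec("accounting", target_fraction=0.5))
        assert prob.capped[0]
        assert prob.targets[0] == pytest.approx(1.0)  # 10 * (1 - 0.9)

    @pytest.mark.parametrize("theta", [0.0, 0.25, 0.35, 0.5, 1.0])
    def test_exclusion_correct_at_every_threshold(self, theta):
        prob = apply_strategy(self.units, self.risks, self.features,
                              StrategySpec("avoiding", threshold=theta))
        assert all(self.risks[u] <= theta for u in prob.unit_ids)

    def test_abandoned_counts_match_enumeration_and_decrease_in_theta(self):
        counts = []
        for theta in [0.0, 0.25, 0.35, 0.5, 1.0]:
            prob = apply_strategy(self.units, self.risks, self.features,
                                  StrategySpec("avoiding", threshold=theta))
            # enumeration oracle
            avail = set(prob.unit_ids)
            expected = 0
            for fid, grp in self.features.groupby("feature_id"):
                if grp.loc[grp["unit_id"].isin(avail), "amount_km2"].sum() == 0:
                    expected += 1
            assert count_abandoned(self.features, prob) == expected
            counts.append(expected)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_lowering_threshold_never_adds_units(self):
        prev = None
        for theta in [1.0, 0.5, 0.35, 0.25, 0.0]:
            prob = apply_strategy(self.units, self.risks, self.features,
                                  StrategySpec("avoiding", threshold=theta))
            current = set(prob.unit_ids)
            if prev is not None:
                assert current <= prev
            prev = current


class TestEnforceReliability:
    def test_zero_risk_exits_without_inflation(self):
        units = toy_units([1.0, 1.0, 1.0])
        features = toy_features({"A": [1, 1, 1]})
        spec = StrategySpec("accounting", target_fraction=0.5)
        prob = apply_strategy(units, {0: 0.0, 1: 0.0, 2: 0.0}, features, spec)
        before = prob.targets.copy()
        out, report = enforce_reliability(
            prob, features, {0: 0.0, 1: 0.0, 2: 0.0}, spec,
            solver=lambda p: greedy_solve(p, 0))
        np.testing.assert_allclose(out.targets, before)
        assert report["met"].all()

    def test_quarter_risk_feature_gets_six_units(self):
        """Ten unit-amount cells at p=0.25, 3 required, rho=0.95: the final
        solution must hold at least six cells of the feature."""
        units = toy_units([1.0] * 10)
        features = toy_features({"A": [1] * 10})
        risks = {u: 0.25 for u in range(10)}
        spec = StrategySpec("accounting", reliability=0.95, target_fraction=0.3)
        prob = apply_strategy(units, risks, features, spec)
        out, report = enforce_reliability(
            prob, features, risks, spec, solver=lambda p: greedy_solve(p, 0))
        sol = greedy_solve(out, 0)
        assert len(sol.selected) >= 6
        assert report["met"].all()

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_posthoc_monte_carlo_reaches_reliability(self, p):
        rng = np.random.default_rng(17)
        units = toy_units([1.0] * 12)
        features = toy_features({"A": [1] * 12})
        risks = {u: p for u in range(12)}
        spec = StrategySpec("accounting", reliability=0.9, target_fraction=0.25)
        prob = apply_strategy(units, risks, features, spec)
        out, _ = enforce_reliability(
            prob, features, risks, spec, solver=lambda pr: greedy_solve(pr, 0))
        sol = greedy_solve(out, 0)
        n_sel = len(sol.selected)
        reps = 10_000
        survived = (rng.random((reps, n_sel)) >= p).sum(axis=1)
        freq = float((survived >= 3).mean())  # 0.25 * 12 = 3 cells required
        se = np.sqrt(freq * (1 - freq) / reps)
        assert freq >= 0.9 - 3 * se
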