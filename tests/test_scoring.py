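"""Weighted-sum aggregation, contributions, scenarios and ranking."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from orphanmcda import (
    DrugProfile,
    InputError,
    ScoreResult,
    WeightScenario,
    aggregate_score,
    builtin_scenarios,
    contribution_matrix,
    default_framework,
    rank_drugs,
)

from ._oracles import weighted_sum

CRITERIA = default_framework().criterion_ids


def profile(drug_id="d1", default=2, **overrides):
    scores = {cid: default for cid in CRITERIA}
    scores.update(overrides)
    return DrugProfile(drug_id=drug_id, scores=scores)


# Strategies: full nine-criterion profiles and normalised scenarios.
# Nonzero weights are bounded away from zero so that a one-point score bump
# on a weighted criterion is representable after normalisation.
score_maps = st.fixed_dictionaries({cid: st.sampled_from([1, 2, 3]) for cid in CRITERIA})
raw_weight_maps = st.fixed_dictionaries(
    {
        cid: st.one_of(st.just(0.0), st.floats(min_value=0.01, max_value=10.0))
        for cid in CRITERIA
    }
).filter(lambda w: sum(w.values()) > 1e-6)


class TestBuiltinScenarios:
    def test_three_scenarios_with_expected_names(self, scenarios):
        assert [s.name for s in scenarios] == [
            "Scenario 1 (Base Case)",
            "Scenario 2",
            "Scenario 3",
        ]

    def test_base_case_is_exact_ninths(self, scenarios):
        assert all(w == 1 / 9 for w in scenarios[0].weights.values())

    def test_scenario2_weights(self, scenarios):
        w = scenarios[1].weights
        assert w["disease_severity"] == pytest.approx(0.30)
        assert w["treatment_impact"] == pytest.approx(0.30)
        assert w["available_alternatives"] == pytest.approx(0.20)
        assert w["rarity"] == pytest.approx(0.14)
        assert w["follow_up_measures"] == pytest.approx(0.06)
        assert scenarios[1].excluded == {
            "research_level",
            "effectiveness_uncertainty",
            "manufacturing_complexity",
            "unique_indication",
        }

    def test_scenario3_exclusions(self, scenarios):
        assert scenarios[2].excluded == {"manufacturing_complexity", "unique_indication"}

    def test_each_scenario_sums_to_one(self, scenarios):
        for s in scenarios:
            assert math.fsum(s.weights.values()) == pytest.approx(1.0, abs=1e-9)


class TestWeightScenario:
    def test_percent_input_normalised(self):
        s = WeightScenario("pct", {cid: 100.0 / 9.0 for cid in CRITERIA})
        assert math.fsum(s.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(InputError):
            WeightScenario("bad", {"rarity": -0.1, "disease_severity": 1.1})

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            WeightScenario("bad", {cid: 0.0 for cid in CRITERIA})


class TestAggregateScore:
    def test_constant_scores_are_weight_invariant(self, scenarios):
        for sc in scenarios:
            assert aggregate_score(profile(default=2), sc).weighted_score == pytest.approx(2.0)

    def test_minimum_profile_equal_weights(self, scenarios):
        r = aggregate_score(profile(default=1), scenarios[0])
        assert r.weighted_score == pytest.approx(1.0)
        assert r.raw_sum == 9
        assert r.percent_of_max == pytest.approx(100.0 / 3.0)

    def test_hand_computed_scenario2_value(self, scenarios):
        """All criteria at 3 except disease severity at 1: dropping a
        30%-weighted criterion by two points costs 0.6 points."""
        r = aggregate_score(profile(default=3, disease_severity=1), scenarios[1])
        assert r.weighted_score == pytest.approx(2.40, abs=1e-12)

    def test_contributions_sum_to_weighted_score(self, scenarios):
        r = aggregate_score(profile(default=3, rarity=1), scenarios[2])
        assert math.fsum(r.contributions.values()) == pytest.approx(r.weighted_score, abs=1e-9)

    def test_criterion_mismatch_raises(self, scenarios):
        scores = {cid: 2 for cid in CRITERIA if cid != "rarity"}
        with pytest.raises(InputError, match="mismatch"):
            aggregate_score(DrugProfile("d1", scores=scores), scenarios[0])

    @given(scores=score_maps, raw=raw_weight_maps)
    def test_matches_brute_force_oracle(self, scores, raw):
        scenario = WeightScenario("h", raw)
        result = aggregate_score(DrugProfile("d", scores=scores), scenario)
        assert result.weighted_score == pytest.approx(
            weighted_sum(scores, scenario.weights), abs=1e-9
        )

    @given(scores=score_maps, raw=raw_weight_maps)
    def test_bounds_for_fully_scored_profiles(self, scores, raw):
        r = aggregate_score(DrugProfile("d", scores=scores), WeightScenario("h", raw))
        assert 1.0 - 1e-9 <= r.weighted_score <= 3.0 + 1e-9
        assert 9 <= r.raw_sum <= 27

    @given(scores=score_maps, raw=raw_weight_maps, data=st.data())
    def test_monotone_in_positively_weighted_criterion(self, scores, raw, data):
        scenario = WeightScenario("h", raw)
        positive = [cid for cid in CRITERIA if scenario.weights[cid] > 0 and scores[cid] < 3]
        if not positive:
            return
        cid = data.draw(st.sampled_from(positive))
        bumped = dict(scores, **{cid: scores[cid] + 1})
        low = aggregate_score(DrugProfile("d", scores=scores), scenario).weighted_score
        high = aggregate_score(DrugProfile("d", scores=bumped), scenario).weighted_score
        assert high > low

    @given(scores=score_maps, raw=raw_weight_maps, data=st.data())
    def test_zero_weight_criterion_has_no_effect(self, scores, raw, data):
        zeroed_cid = data.draw(st.sampled_from(sorted(CRITERIA)))
        raw = dict(raw, **{zeroed_cid: 0.0})
        if sum(raw.values()) <= 1e-6:
            return
        scenario = WeightScenario("h", raw)
        base = aggregate_score(DrugProfile("d", scores=scores), scenario).weighted_score
        for other in (1, 2, 3):
            varied = dict(scores, **{zeroed_cid: other})
            assert aggregate_score(
                DrugProfile("d", scores=varied), scenario
            ).weighted_score == pytest.approx(base, abs=1e-12)

    @given(scores=score_maps, raw=raw_weight_maps)
    def test_permutation_equivariance(self, scores, raw):
        """Relabelling criteria consistently in profile and scenario leaves
        the aggregate unchanged."""
        scenario = WeightScenario("h", raw)
        mapping = dict(zip(CRITERIA, reversed(CRITERIA)))
        p_scores = {mapping[cid]: s for cid, s in scores.items()}
        p_weights = {mapping[cid]: w for cid, w in scenario.weights.items()}
        a = aggregate_score(DrugProfile("d", scores=scores), scenario).weighted_score
        b = aggregate_score(
            DrugProfile("d", scores=p_scores), WeightScenario("h2", p_weights)
        ).weighted_score
        assert a == pytest.approx(b, abs=1e-9)


class TestContributionMatrix:
    def test_uniform_profile_equal_weights_cells(self, scenarios):
        m = contribution_matrix([profile(default=1)], scenarios[0])
        assert (m.to_numpy() == pytest.approx(1 / 9)) and m.shape == (1, 9)

    def test_row_sums_match_aggregate(self, scenarios, example_profiles):
        m = contribution_matrix(example_profiles, scenarios[1])
        for p in example_profiles:
            expected = aggregate_score(p, scenarios[1]).weighted_score
            assert m.loc[p.drug_id].sum() == pytest.approx(expected, abs=1e-9)

    def test_identical_profiles_give_identical_rows(self, scenarios):
        a, b = profile("a", default=3, rarity=1), profile("b", default=3, rarity=1)
        m = contribution_matrix([a, b], scenarios[2])
        assert (m.loc["a"] == m.loc["b"]).all()

    def test_columns_follow_framework_order(self, scenarios):
        m = contribution_matrix([profile()], scenarios[0])
        assert list(m.columns) == list(CRITERIA)


class TestRankDrugs:
    @staticmethod
    def result(drug_id, score, scenario="s"):
        return ScoreResult(drug_id, scenario, score, 0, 0.0, {})

    def test_competition_ranking_with_tie(self):
        ranking = rank_drugs(
            [self.result("A", 2.4), self.result("C", 1.8), self.result("B", 2.4)]
        )
        assert ranking.entries == ((1, "A", 2.4), (1, "B", 2.4), (3, "C", 1.8))
        assert ranking.tie_groups == (frozenset({"A", "B"}),)

    def test_single_drug(self):
        assert rank_drugs([self.result("X", 2.0)]).entries == ((1, "X", 2.0),)

    def test_strictly_decreasing_scores_rank_one_to_n(self):
        results = [self.result(f"d{i}", 3.0 - 0.1 * i) for i in range(5)]
        ranking = rank_drugs(results)
        assert [r for r, _, _ in ranking.entries] == [1, 2, 3, 4, 5]
        assert ranking.tie_groups == ()

    def test_duplicate_drug_id_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            rank_drugs([self.result("A", 2.0), self.result("A", 1.0)])

    def test_mixed_scenarios_rejected(self):
        with pytest.raises(InputError, match="scenario"):
            rank_drugs([self.result("A", 2.0, "s1"), self.result("B", 1.0, "s2")])
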