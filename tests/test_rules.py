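"""Rule induction, statistics, filtering, classification, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from roughdelphi.roughset import approximate
from roughdelphi.rules import (
    DecisionRule,
    RuleSet,
    classify,
    cross_validate,
    filter_rules,
    induce_rules,
    rule_stats,
)
from roughdelphi.table import DecisionTable

from conftest import random_table
from oracles import minimal_certain_rules


def _ruleset(*specs) -> RuleSet:
    return RuleSet(
        rules=tuple(
            DecisionRule(
                conditions=tuple(conds),
                decision=dec,
                support=sup,
                coverage=cov,
                certainty=1.0,
            )
            for conds, dec, sup, cov in specs
        )
    )


class TestInduceRules:
    def test_hand_table_minimal_rules(self, four_object_table):
        rules = induce_rules(four_object_table)
        as_set = {
            (r.conditions, r.decision, r.support, r.coverage) for r in rules
        }
        assert as_set == {
            ((("a", 1),), 1, 2, 1.0),
            ((("a", 2),), 2, 2, 1.0),
        }

    def test_single_object_table(self):
        table = DecisionTable(
            pd.DataFrame({"a": [3], "b": [1], "d": [2]}), decision="d"
        )
        (rule,) = induce_rules(table).rules
        assert len(rule.conditions) == 1
        assert rule.support == 1
        assert rule.coverage == 1.0

    def test_planted_conjunction_recovered(self, study_table):
        """The dominant planted satisfaction pathway appears verbatim."""
        rules = induce_rules(study_table)
        wanted = {("cost_control", 5), ("safety", 5)}
        assert any(
            set(r.conditions) == wanted and r.decision == 3 for r in rules
        )

    def test_all_rules_certain_and_minimal(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            table = random_table(rng, max_objects=25, max_attrs=4)
            for rule in induce_rules(table):
                assert rule.certainty == 1.0
                # condition-minimal: dropping any literal breaks certainty
                for i in range(len(rule.conditions)):
                    rest = rule.conditions[:i] + rule.conditions[i + 1 :]
                    if not rest:
                        sub_support, _, sub_cert = rule_stats(
                            rest, rule.decision, table
                        )
                        assert sub_cert < 1.0
                    else:
                        _, _, sub_cert = rule_stats(rest, rule.decision, table)
                        assert sub_cert < 1.0

    def test_completeness_covers_lower_approximation(self):
        rng = np.random.default_rng(32)
        for _ in range(15):
            table = random_table(rng, max_objects=25, max_attrs=4)
            rules = induce_rules(table)
            for value in table.decision_values():
                lower = set(
                    approximate(
                        table,
                        table.condition_attributes,
                        table.decision_class(value),
                    ).lower
                )
                covered = set()
                for rule in rules:
                    if rule.decision != value:
                        continue
                    for obj in table.objects:
                        if all(
                            table.value(obj, a) == v for a, v in rule.conditions
                        ):
                            covered.add(obj)
                assert covered == lower

    def test_short_rules_are_oracle_minimal(self):
        """Induced rules of <= 3 literals appear in the brute-force
        enumeration of condition-minimal certain conjunctions."""
        rng = np.random.default_rng(33)
        for _ in range(10):
            table = random_table(rng, max_objects=20, max_attrs=4, max_values=3)
            oracle = minimal_certain_rules(table, max_len=3)
            for rule in induce_rules(table):
                if len(rule.conditions) > 3:
                    continue
                conj = tuple(sorted(rule.conditions))
                assert conj in oracle[rule.decision]


class TestRuleStats:
    def test_hand_table(self, four_object_table):
        assert rule_stats((("a", 1),), 1, four_object_table) == (2, 1.0, 1.0)

    def test_empty_condition_vacuous_premise(self, four_object_table):
        support, coverage, certainty = rule_stats((), 1, four_object_table)
        assert support == 2
        assert coverage == 1.0
        assert certainty == 0.5

    def test_large_class_ratio(self):
        # 49 matches of a 108-member class: the coverage prints as 45.37%
        frame = pd.DataFrame(
            {
                "a": [1] * 49 + [2] * 59 + [3] * 10,
                "d": [3] * 108 + [1] * 10,
            }
        )
        table = DecisionTable(frame, decision="d")
        support, coverage, _ = rule_stats((("a", 1),), 3, table)
        assert support == 49
        assert coverage == pytest.approx(49 / 108)
        assert f"{coverage:.2%}" == "45.37%"

    def test_absent_class_undefined_coverage(self, four_object_table):
        with pytest.raises(ZeroDivisionError):
            rule_stats((("a", 1),), 99, four_object_table)

    def test_coverage_identity_integer_arithmetic(self, study_table):
        for rule in induce_rules(study_table):
            class_size = len(study_table.decision_class(rule.decision))
            assert rule.coverage * class_size == pytest.approx(rule.support)


class TestFilterRules:
    def test_zero_threshold_identity(self, four_object_table):
        rules = induce_rules(four_object_table)
        assert filter_rules(rules, 0.0).rules == rules.rules

    def test_full_threshold_whole_class_only(self):
        rules = _ruleset(
            ([("a", 1)], 1, 5, 1.0),
            ([("a", 2)], 1, 2, 0.4),
        )
        kept = filter_rules(rules, 1.0)
        assert [r.coverage for r in kept] == [1.0]

    def test_boundary_coverage_kept(self):
        rules = _ruleset(([("a", 1)], 1, 1, 0.10))
        assert len(filter_rules(rules, 0.10)) == 1

    def test_class_restriction_and_stable_order(self):
        rules = _ruleset(
            ([("a", 1)], 1, 3, 0.5),
            ([("a", 2)], 2, 3, 0.5),
            ([("a", 3)], 3, 3, 0.5),
        )
        kept = filter_rules(rules, 0.1, keep_classes=[1, 3])
        assert [r.decision for r in kept] == [1, 3]

    def test_monotone_in_threshold(self):
        rules = _ruleset(
            *[([("a", v)], 1, v, v / 10) for v in range(1, 6)]
        )
        sizes = [len(filter_rules(rules, t / 10)) for t in range(0, 7)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_rules(_ruleset(), 1.01)


class TestClassify:
    def test_single_matching_rule(self):
        rules = _ruleset(([("a", 1)], 1, 3, 0.5), ([("a", 2)], 2, 3, 0.5))
        assert classify({"a": 1}, rules) == 1

    def test_support_weighted_vote(self):
        rules = _ruleset(
            ([("a", 1)], 1, 5, 0.5),
            ([("b", 2)], 2, 2, 0.5),
        )
        assert classify({"a": 1, "b": 2}, rules) == 1

    def test_partial_match_fallback(self):
        rules = _ruleset(([("a", 1), ("b", 1)], 1, 3, 0.5))
        assert classify({"a": 9, "b": 9}, rules) == 1

    def test_partial_match_prefers_larger_fraction(self):
        rules = _ruleset(
            ([("a", 1), ("b", 1)], 1, 9, 0.5),
            ([("c", 1), ("d", 1), ("e", 1)], 2, 1, 0.5),
        )
        # 2/3 of the second rule's literals hold, only 1/2 of the first's
        row = {"a": 1, "b": 9, "c": 1, "d": 1, "e": 9}
        assert classify(row, rules) == 2

    def test_empty_ruleset_rejected(self):
        with pytest.raises(ValueError):
            classify({"a": 1}, RuleSet(rules=()))


class TestCrossValidate:
    def test_constant_decision_perfect(self):
        table = DecisionTable(
            pd.DataFrame({"a": [1, 2, 3, 4], "d": [1, 1, 1, 1]}), decision="d"
        )
        result = cross_validate(table, n_folds=2, seed=5)
        assert result.mean_accuracy == 1.0

    def test_perfectly_determined_table(self, four_object_table):
        # stratification puts one a=1 and one a=2 row in each training split
        result = cross_validate(four_object_table, n_folds=2, seed=0)
        assert result.mean_accuracy == 1.0
        assert result.n_folds == 2

    def test_mean_is_average_of_folds(self, study_table):
        result = cross_validate(study_table, n_folds=5, seed=2)
        assert result.mean_accuracy == pytest.approx(
            np.mean(result.per_fold_accuracy)
        )
        assert all(0.0 <= a <= 1.0 for a in result.per_fold_accuracy)

    def test_deterministic_under_seed(self, four_object_table):
        r1 = cross_validate(four_object_table, n_folds=2, seed=7)
        r2 = cross_validate(four_object_table, n_folds=2, seed=7)
        assert r1 == r2

    def test_singleton_class_merges_folds(self):
        frame = pd.DataFrame(
            {"a": [1, 1, 2, 2, 3, 3, 9], "d": [1, 1, 1, 1, 2, 2, 3]}
        )
        table = DecisionTable(frame, decision="d")
        with pytest.warns(UserWarning, match="merging"):
            result = cross_validate(table, n_folds=4, seed=0)
        assert result.n_folds < 4

    def test_validation_errors(self, four_object_table):
        with pytest.raises(ValueError):
            cross_validate(four_object_table, n_folds=1)
        with pytest.raises(ValueError):
            cross_validate(four_object_table, n_folds=9)

    def test_object_order_invariance(self, four_object_table):
        """Classification does not depend on the order of table rows."""
        rules = induce_rules(four_object_table)
        frame = four_object_table.frame.iloc[::-1].reset_index(drop=True)
        shuffled = DecisionTable(frame, decision="d")
        rules_shuffled = induce_rules(shuffled)
        for row in ({"a": 1, "b": 2}, {"a": 2, "b": 1}):
            assert classify(row, rules) == classify(row, rules_shuffled)
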