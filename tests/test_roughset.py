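"""Rough-set algebra: partitions, approximations, gamma, reducts, core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roughdelphi.roughset import (
    approximate,
    dependency,
    find_reducts,
    partition,
    quality_of_classification,
)
from roughdelphi.table import DecisionTable, read_isf, write_isf

from conftest import random_table
from oracles import naive_approximation, naive_gamma, pairwise_partition


class TestPartition:
    def test_hand_enumeration(self, four_object_table):
        p = partition(four_object_table, ["a"])
        assert p.blocks == (("o1", "o2"), ("o3", "o4"))

    def test_empty_attrs_single_block(self, four_object_table):
        p = partition(four_object_table, [])
        assert p.blocks == (("o1", "o2", "o3", "o4"),)

    def test_all_attrs_distinct_rows_singletons(self, four_object_table):
        p = partition(four_object_table, ["a", "b"])
        assert all(len(b) == 1 for b in p.blocks)

    def test_unknown_attribute_rejected(self, four_object_table):
        with pytest.raises(KeyError):
            partition(four_object_table, ["zzz"])

    def test_refinement_property(self):
        """Blocks under a superset of attributes refine the coarser blocks."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            table = random_table(rng, max_objects=30)
            attrs = list(table.condition_attributes)
            coarse = partition(table, attrs[:1])
            fine = partition(table, attrs)
            coarse_blocks = [set(b) for b in coarse.blocks]
            for block in fine.blocks:
                assert any(set(block) <= cb for cb in coarse_blocks)


class TestApproximate:
    def test_hand_enumeration(self, four_object_table):
        result = approximate(four_object_table, ["a"], ["o1", "o2", "o3"])
        assert result.lower == ("o1", "o2")
        assert result.upper == ("o1", "o2", "o3", "o4")
        assert result.boundary == ("o3", "o4")
        assert result.accuracy == 0.5

    def test_definable_set_is_exact(self, four_object_table):
        result = approximate(four_object_table, ["a"], ["o1", "o2"])
        assert result.lower == result.upper == ("o1", "o2")
        assert result.accuracy == 1.0

    def test_empty_target_convention(self, four_object_table):
        result = approximate(four_object_table, ["a"], [])
        assert result.lower == result.upper == ()
        assert result.accuracy == 1.0

    def test_unknown_object_rejected(self, four_object_table):
        with pytest.raises(KeyError):
            approximate(four_object_table, ["a"], ["nope"])

    def test_monotonicity_and_duality(self):
        """More attributes widen the lower and shrink the upper
        approximation; upper(X) is the complement of lower(complement)."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            table = random_table(rng, max_objects=30)
            attrs = list(table.condition_attributes)
            objs = list(table.objects)
            target = [o for o in objs if rng.random() < 0.4]
            small = approximate(table, attrs[:1], target)
            large = approximate(table, attrs, target)
            assert set(small.lower) <= set(large.lower)
            assert set(large.upper) <= set(small.upper)
            complement = [o for o in objs if o not in set(target)]
            dual = approximate(table, attrs[:1], complement)
            assert set(small.upper) == set(objs) - set(dual.lower)


class TestDependency:
    def test_hand_table(self, four_object_table):
        assert dependency(four_object_table, ["a"]).gamma == 1.0
        assert dependency(four_object_table, ["b"]).gamma == 0.0

    def test_full_conditions_on_consistent_table(self, consistent_table):
        assert quality_of_classification(consistent_table) == 1.0

    def test_empty_attrs_zero_with_multiple_classes(self, four_object_table):
        assert dependency(four_object_table, []).gamma == 0.0

    def test_per_class_sizes_sum_to_gamma(self, four_object_table):
        report = dependency(four_object_table, ["a"])
        assert sum(report.per_class_lower_sizes.values()) == 4

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_gamma_monotone_in_attributes(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, max_objects=25, max_attrs=4)
        attrs = list(table.condition_attributes)
        gammas = [
            dependency(table, attrs[:k]).gamma for k in range(len(attrs) + 1)
        ]
        assert all(g1 <= g2 + 1e-12 for g1, g2 in zip(gammas, gammas[1:]))


class TestReducts:
    def test_noise_attribute_dropped(self, four_object_table):
        result = find_reducts(four_object_table)
        assert result.reducts == (("a",),)
        assert result.core == ("a",)

    def test_duplicate_columns_empty_core(self):
        table = DecisionTable(
            pd.DataFrame({"a": [1, 2], "b": [1, 2], "d": [1, 2]}), decision="d"
        )
        result = find_reducts(table)
        assert set(result.reducts) == {("a",), ("b",)}
        assert result.core == ()

    def test_single_condition(self):
        table = DecisionTable(
            pd.DataFrame({"a": [1, 2], "d": [1, 2]}), decision="d"
        )
        result = find_reducts(table)
        assert result.reducts == (("a",),)
        assert result.core == ("a",)

    def test_reduct_minimality(self, study_table):
        """Every reported reduct preserves gamma and loses it when any
        single attribute is removed."""
        result = find_reducts(study_table)
        gamma_full = quality_of_classification(study_table)
        for reduct in result.reducts[:5]:
            assert dependency(study_table, reduct).gamma == gamma_full
            for attr in reduct:
                rest = tuple(a for a in reduct if a != attr)
                assert dependency(study_table, rest).gamma < gamma_full

    def test_core_membership_equivalence(self):
        """a is in the core iff removing it from C lowers gamma."""
        rng = np.random.default_rng(13)
        for _ in range(15):
            table = random_table(rng, max_objects=25, max_attrs=5)
            conditions = table.condition_attributes
            gamma_full = dependency(table, conditions).gamma
            core = set(find_reducts(table).core)
            for attr in conditions:
                rest = tuple(a for a in conditions if a != attr)
                drops = dependency(table, rest).gamma < gamma_full
                assert (attr in core) == drops

    def test_heuristic_gate(self):
        rng = np.random.default_rng(3)
        data = {f"c{i}": rng.integers(1, 3, 40) for i in range(21)}
        data["d"] = rng.integers(1, 3, 40)
        table = DecisionTable(pd.DataFrame(data), decision="d")
        with pytest.raises(ValueError, match="heuristic"):
            find_reducts(table)
        result = find_reducts(table, allow_heuristic=True)
        assert not result.exhaustive
        assert dependency(table, result.reducts[0]).gamma == result.gamma


class TestOracleAgreement:
    def test_partition_matches_pairwise_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            table = random_table(rng, max_objects=30)
            attrs = list(table.condition_attributes)
            ours = {frozenset(b) for b in partition(table, attrs).blocks}
            oracle = {frozenset(b) for b in pairwise_partition(table, attrs)}
            assert ours == oracle

    def test_approximation_and_gamma_match_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            table = random_table(rng, max_objects=25)
            attrs = list(table.condition_attributes)[:2]
            target = [o for o in table.objects if rng.random() < 0.5]
            ours = approximate(table, attrs, target)
            lo, up = naive_approximation(table, attrs, target)
            assert set(ours.lower) == lo
            assert set(ours.upper) == up
            assert dependency(table, attrs).gamma == naive_gamma(table, attrs)


class TestTableIO:
    def test_missing_cells_rejected(self):
        frame = pd.DataFrame({"a": [1, None], "d": [1, 2]})
        with pytest.raises(ValueError, match="missing"):
            DecisionTable(frame, decision="d")

    def test_isf_round_trip(self, tmp_path, four_object_table):
        path = tmp_path / "table.isf"
        write_isf(four_object_table, path)
        again = read_isf(path)
        assert again.condition_attributes == four_object_table.condition_attributes
        assert again.decision_attribute == four_object_table.decision_attribute
        assert (
            again.frame.to_numpy().tolist()
            == four_object_table.frame.to_numpy().tolist()
        )

    def test_csv_default_decision_is_last_column(self, tmp_path, four_object_table):
        path = tmp_path / "table.csv"
        four_object_table.to_csv(path)
        again = DecisionTable.from_csv(path)
        assert again.decision_attribute == "d"
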