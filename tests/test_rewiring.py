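import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betrewire import rewiring
from betrewire.errors import ConfigurationError, ContractError
from betrewire.rewiring import DECREASED, INCREASED, SUSTAINED


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["bait", "prey", "timepoint", "replicate", "spectral_count", "fdr"]
    )


class TestSumReplicates:
    def test_two_replicates_of_218_sum_to_436(self, interaction_fixture):
        _, df = interaction_fixture
        assert rewiring.sum_replicates(df, "BRD3", "TCOF1", 60) == 436

    def test_absent_key_is_zero(self, interaction_fixture):
        _, df = interaction_fixture
        assert rewiring.sum_replicates(df, "BRD4", "TCOF1", 60) == 0

    def test_three_replicates(self):
        df = make_table([("B", "P", 0, f"r{i}", c, 0.0) for i, c in enumerate([3, 4, 5])])
        assert rewiring.sum_replicates(df, "B", "P", 0) == 12


class TestLfc:
    @pytest.mark.parametrize(
        "ref,treated,expected",
        [
            (10, 10, 0.0),
            (40, 9, math.log2(10 / 41)),   # ~ -2.036
            (0, 436, math.log2(437 / 1)),  # ~ +8.77, the TCOF1 gain
        ],
    )
    def test_worked_values(self, ref, treated, expected):
        assert rewiring.lfc(ref, treated, 1.0) == pytest.approx(expected)

    def test_negative_input_is_contract_error(self):
        with pytest.raises(ContractError):
            rewiring.lfc(-1, 5)
        with pytest.raises(ContractError):
            rewiring.lfc(5, 5, pseudocount=0)

    @given(a=st.integers(0, 10_000), b=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric(self, a, b):
        assert rewiring.lfc(a, b) == pytest.approx(-rewiring.lfc(b, a))


class TestClassify:
    @pytest.mark.parametrize(
        "ref,treated,category,below",
        [
            (0, 436, INCREASED, False),
            (8, 0, DECREASED, True),
            (10, 10, SUSTAINED, False),
        ],
    )
    def test_worked_calls(self, ref, treated, category, below):
        assert rewiring.classify(ref, treated) == (category, below)

    @given(ref=st.integers(0, 500), treated=st.integers(0, 500))
    @settings(max_examples=300, deadline=None)
    def test_category_matches_lfc_rule(self, ref, treated):
        category, below = rewiring.classify(ref, treated)
        value = rewiring.lfc(ref, treated)
        expected = DECREASED if value <= -2 else INCREASED if value >= 2 else SUSTAINED
        assert category == expected
        assert below == (ref > 0 and treated == 0)
        if below:
            assert category == DECREASED

    def test_monotone_in_treated_count(self):
        order = {DECREASED: 0, SUSTAINED: 1, INCREASED: 2}
        ranks = [order[rewiring.classify(50, t)[0]] for t in range(0, 600)]
        assert ranks == sorted(ranks)


class TestClassifyTable:
    def test_single_sustained_pair(self):
        df = make_table(
            [("B", "P", 0, "r1", 10, 0.001), ("B", "P", 60, "r1", 12, 0.001)]
        )
        summary = rewiring.rewiring_summary(df, 0, 60)
        assert summary.totals == {DECREASED: 0, SUSTAINED: 1, INCREASED: 0}

    def test_conservation_invariant(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(60):
            rows.append(("B1", f"P{i}", 0, "r1", int(rng.integers(0, 80)), 0.001))
            rows.append(("B1", f"P{i}", 60, "r1", int(rng.integers(0, 80)), 0.001))
        summary = rewiring.rewiring_summary(make_table(rows), 0, 60)
        assert sum(summary.totals.values()) == summary.n_pairs
        assert summary.per_bait.sum(axis=1).sum() == summary.n_pairs
        assert not summary.calls.duplicated(subset=["bait", "prey"]).any()

    def test_timepoint_swap_swaps_decreased_and_increased(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(80):
            rows.append(("B1", f"P{i}", 0, "r1", int(rng.integers(0, 100)), 0.001))
            rows.append(("B1", f"P{i}", 60, "r1", int(rng.integers(0, 100)), 0.001))
        table = make_table(rows)
        fwd = rewiring.rewiring_summary(table, 0, 60)
        rev = rewiring.rewiring_summary(table, 60, 0)
        assert fwd.totals[DECREASED] == rev.totals[INCREASED]
        assert fwd.totals[INCREASED] == rev.totals[DECREASED]
        assert fwd.totals[SUSTAINED] == rev.totals[SUSTAINED]

    def test_missing_timepoint_is_configuration_error(self):
        df = make_table([("B", "P", 0, "r1", 10, 0.001)])
        with pytest.raises(ConfigurationError):
            rewiring.rewiring_summary(df, 0, 60)

    def test_fdr_cut_defines_the_universe(self):
        df = make_table(
            [("B", "P", 0, "r1", 10, 0.5), ("B", "P", 60, "r1", 10, 0.5),
             ("B", "Q", 0, "r1", 10, 0.001), ("B", "Q", 60, "r1", 10, 0.001)]
        )
        summary = rewiring.rewiring_summary(df, 0, 60, fdr_cut=0.01)
        assert summary.n_pairs == 1
        assert rewiring.rewiring_summary(df, 0, 60, fdr_cut=None).n_pairs == 2


class TestBelowDetection:
    def test_definition(self):
        df = make_table(
            [("B", "A", 0, "r1", 10, 0.001), ("B", "A", 60, "r1", 0, 0.001),
             ("B", "B2", 0, "r1", 10, 0.001), ("B", "B2", 60, "r1", 3, 0.001),
             ("B", "C", 0, "r1", 0, 0.001), ("B", "C", 60, "r1", 0, 0.001)]
        )
        assert rewiring.below_detection_set(df, "B", 0, 60) == {"A"}

    def test_unknown_bait_warns_and_returns_empty(self):
        df = make_table([("B", "A", 0, "r1", 10, 0.001), ("B", "A", 60, "r1", 0, 0.001)])
        with pytest.warns(UserWarning, match="unknown bait"):
            assert rewiring.below_detection_set(df, "NOPE", 0, 60) == set()


class TestBaitOverlap:
    def test_planted_four_bait_overlap_structure_recovered(self):
        from betrewire import synthetic

        table, truth = synthetic.simulate_interactions(
            n_baits=4, n_preys=80, presence_prob=0.5, seed=27)
        truth_df = pd.DataFrame(truth.data["interactions"])
        seen = truth_df[truth_df["present"] & truth_df["fdr_pass"]
                        & (truth_df["ref_count"] > 0)]
        expected = seen.groupby("prey")["bait"].apply(set).to_dict()
        overlap = rewiring.bait_overlap(table, timepoint=0)
        assert overlap.prey_to_baits == expected
        assert overlap.shared_by_all == {p for p, b in expected.items() if len(b) == 4}
        assert overlap.single_bait == {p for p, b in expected.items() if len(b) == 1}

    def test_two_bait_example(self):
        df = make_table(
            [("b1", "X", 0, "r1", 5, 0.001), ("b2", "X", 0, "r1", 5, 0.001),
             ("b1", "Y", 0, "r1", 5, 0.001)]
        )
        overlap = rewiring.bait_overlap(df, timepoint=0)
        assert overlap.shared_by_all == {"X"}
        assert overlap.single_bait == {"Y"}
        assert overlap.n_baits == 2


class TestGroupRollup:
    def test_single_group_single_bait_fraction_one(self):
        df = make_table([("b1", "P", 0, "r1", 7, 0.001)])
        rollup = rewiring.group_rollup(df, {"P": "G"})
        assert rollup.fractions.loc["G", "b1"] == 1.0

    def test_30_10_split_gives_75_25(self):
        df = make_table(
            [("b1", "P", 0, "r1", 30, 0.001), ("b2", "P", 0, "r1", 10, 0.001)]
        )
        rollup = rewiring.group_rollup(df, {"P": "G"})
        assert rollup.fractions.loc["G", "b1"] == pytest.approx(0.75)
        assert rollup.fractions.loc["G", "b2"] == pytest.approx(0.25)

    def test_fractions_sum_to_one_and_unmapped_counted(self):
        rng = np.random.default_rng(11)
        rows = []
        group_map = {}
        for i in range(30):
            prey = f"P{i}"
            if i < 24:
                group_map[prey] = f"G{i % 4}"
            for bait in ("b1", "b2", "b3"):
                rows.append((bait, prey, 0, "r1", int(rng.integers(1, 50)), 0.001))
        rollup = rewiring.group_rollup(make_table(rows), group_map)
        assert np.allclose(rollup.fractions.sum(axis=1), 1.0)
        assert rollup.n_unmapped_preys == 6

    def test_empty_map_is_configuration_error(self):
        df = make_table([("b1", "P", 0, "r1", 7, 0.001)])
        with pytest.raises(ConfigurationError):
            rewiring.group_rollup(df, {})
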