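import math

import numpy as np
import pytest
from scipy import stats

import randseq as rs
from randseq import NA


@pytest.fixture
def seq(seq_factory):
    return seq_factory


class TestDigramCounts:
    def test_lag1_no_wrap(self, seq):
        table = rs.digram_counts(seq([1, 2, 1, 2, 1]), lag=1, wrap=False)
        assert table.counts.entries == {(1, 2): 2, (2, 1): 2}
        assert table.counts.total == 4

    def test_lag1_wrap_adds_cyclic_pair(self, seq):
        table = rs.digram_counts(seq([1, 2, 1, 2, 1]), lag=1, wrap=True)
        assert table.counts[(1, 1)] == 1
        assert table.counts.total == 5

    def test_lag2(self, seq):
        table = rs.digram_counts(seq([1, 2, 3, 4, 5]), lag=2, wrap=False)
        assert table.counts.entries == {(1, 3): 1, (2, 4): 1, (3, 5): 1}
        assert table.counts.total == 3

    def test_row_totals_are_marginals(self, seq):
        table = rs.digram_counts(seq([1, 2, 1, 2, 3]), lag=1)
        assert table.row_totals.entries == {1: 2, 2: 2}

    def test_short_sequence_errors(self, seq):
        with pytest.raises(rs.SequenceError):
            rs.digram_counts(seq([1, 2]), lag=2)


class TestRedundancy:
    def test_constant_is_maximal(self, seq):
        s = seq([5] * 10)
        assert rs.redundancy(s) == 1.0
        assert rs.redundancy(s, "classical") == 100.0

    def test_equal_usage_is_zero(self, seq):
        s = seq([d for d in range(1, 10) for _ in range(2)])
        assert rs.redundancy(s) == pytest.approx(0.0, abs=1e-12)

    def test_counts_3_1_binary_against_entropy_oracle(self):
        # independent oracle: R = 1 - H(p)/log2(a) via scipy's entropy
        s = rs.make_sequence([1, 1, 1, 2], min_scale=1, max_scale=2)
        expected = 1.0 - stats.entropy([3 / 4, 1 / 4], base=2) / math.log2(2)
        assert rs.redundancy(s) == pytest.approx(expected, abs=1e-12)


class TestRngIndex:
    def test_perfect_alternation_is_one(self, seq):
        assert rs.rng_index(seq([1, 2, 1, 2, 1])) == pytest.approx(1.0)

    def test_all_distinct_digrams_is_zero(self, seq):
        # digrams (1,2),(2,1),(1,3) all distinct; row totals {1:2, 2:1}
        assert rs.rng_index(seq([1, 2, 1, 3])) == pytest.approx(0.0)

    def test_hand_enumerated_half(self, seq):
        # digrams (1,2)x2,(2,1),(2,3): numerator 2; row totals {1:2, 2:2}: denominator 4
        assert rs.rng_index(seq([1, 2, 1, 2, 3])) == pytest.approx(0.5)

    def test_degenerate_denominator_marks_not_computable(self, seq):
        assert rs.rng_index(seq([1, 2, 3])) is NA

    def test_classical_wraps(self, seq):
        s = seq([1, 2, 1, 2, 1])
        # wrap adds the (1,1) pair: numerator 4, denominator 3log3 + 2
        expected = 4.0 / (3 * math.log2(3) + 2.0)
        assert rs.rng_index(s, "classical") == pytest.approx(expected)


class TestRng2Index:
    def test_hand_enumeration(self, seq):
        # lag-2 pairs (1,1),(2,2),(1,1): numerator 2, denominator 2
        assert rs.rng2_index(seq([1, 2, 1, 2, 1])) == pytest.approx(1.0)

    def test_all_distinct_is_zero(self, seq):
        # lag-2 pairs (1,1),(2,3),(1,2),(3,4) all distinct, repeated first member
        assert rs.rng2_index(seq([1, 2, 1, 3, 2, 4])) == pytest.approx(0.0)

    def test_modes_agree_exactly(self, seq):
        s = seq([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5])
        assert rs.rng2_index(s, "classical") == rs.rng2_index(s, "default")


class TestNsq:
    def test_single_digram_binary(self):
        s = rs.make_sequence([1, 2], min_scale=1, max_scale=2)
        assert rs.nsq(s) == pytest.approx(1.0)

    def test_binary_with_all_four_pairs_is_zero(self, coin):
        s = rs.generate_iid(coin, 100, seed=1)
        assert len(set(zip(s.tokens, s.tokens[1:]))) == 4
        assert rs.nsq(s) == 0.0

    def test_fixture_with_37_distinct_pairs(self):
        s = rs.construct_fixture("digram_count", n=50, a=9, d=37)
        assert rs.nsq(s, "classical") == pytest.approx(55.000)
        assert rs.nsq(s, "default") == pytest.approx(0.550)


class TestCoupon:
    def test_minimal_completion(self):
        s = rs.make_sequence([1, 2, 3], min_scale=1, max_scale=3)
        assert rs.coupon(s) == pytest.approx(3.0)

    def test_hand_simulated_scan(self):
        s = rs.make_sequence([1, 1, 2, 3, 3, 2, 1], min_scale=1, max_scale=3)
        assert rs.coupon(s) == pytest.approx(3.5)

    def test_unused_alternative_not_computable(self, seq):
        s = seq([d for d in [1, 2, 3, 4, 5, 6, 8, 9] * 3])  # 7 never used
        assert rs.coupon(s) is NA


class TestFod:
    def test_signed_differences(self, seq):
        assert rs.fod_table(seq([1, 3, 2])).entries == {2: 1, -1: 1}

    def test_constant(self, seq):
        assert rs.fod_table(seq([5] * 5)).entries == {0: 4}

    def test_ordinal_coding_for_named_alternatives(self):
        s = rs.make_sequence(
            ["head", "tail", "head"], alternatives=["head", "tail"]
        )
        assert rs.fod_table(s).entries == {1: 1, -1: 1}


class TestAdjacency:
    def test_ascending_only(self, seq):
        adj = rs.adjacency(seq([1, 2, 3, 5]))
        assert adj.ascending == pytest.approx(2 / 4)
        assert adj.descending == 0.0
        assert adj.combined == pytest.approx(2 / 4)

    def test_descending(self, seq):
        adj = rs.adjacency(seq([9, 8, 1]))
        assert adj.descending == pytest.approx(1 / 3)

    def test_combined_is_sum(self, seq):
        adj = rs.adjacency(seq([1, 2, 1, 5, 6, 9, 8]))
        assert adj.combined == pytest.approx(adj.ascending + adj.descending)


class TestTurningPoints:
    def test_monotone_is_zero(self, seq):
        assert rs.turning_points(seq([1, 2, 3, 4, 5])) == 0

    def test_peak_and_trough(self, seq):
        assert rs.turning_points(seq([1, 3, 2, 4])) == 2

    def test_plateau_collapsed(self, seq):
        assert rs.turning_points(seq([1, 3, 3, 2])) == 1


class TestTpi:
    def test_fifty_with_33_turning_points(self):
        s = rs.construct_fixture("turning_points", n=50, tp=33)
        assert rs.tpi(s, "classical") == pytest.approx(103.125)
        assert rs.tpi(s, "default") == pytest.approx(0.03125)

    def test_monotone_default_is_minus_one(self, seq):
        assert rs.tpi(seq([1, 2, 3, 4])) == pytest.approx(-1.0)

    def test_ratio_from_turning_point_example(self, seq):
        assert rs.tpi(seq([1, 3, 2, 4])) == pytest.approx(0.5)

    def test_too_short_errors(self, seq):
        with pytest.raises(rs.SequenceError):
            rs.tpi(seq([1, 2]))


class TestPhaseLengths:
    def test_hand_scan(self, seq):
        asc, desc = rs.phase_lengths(seq([1, 3, 2, 4, 1]))
        assert asc.entries == {1: 1}
        assert desc.entries == {1: 1}

    def test_strict_alternation_all_ones(self, seq):
        asc, desc = rs.phase_lengths(seq([1, 9, 1, 9, 1, 9, 1]))
        lengths = asc.expand() + desc.expand()
        assert lengths and set(lengths) == {1}

    def test_monotone_empty(self, seq):
        asc, desc = rs.phase_lengths(seq([1, 2, 3, 4]))
        assert asc.total == 0 and desc.total == 0


class TestRuns:
    def test_equal_phase_lengths_zero_variance(self, seq):
        assert rs.runs(seq([1, 9, 1, 9, 1, 9, 1])) == pytest.approx(0.0)

    def test_hand_example(self, seq):
        assert rs.runs(seq([1, 3, 2, 4, 1])) == pytest.approx(0.0)

    def test_classical_mode_not_computable(self, seq):
        assert rs.runs(seq([1, 3, 2, 4, 1]), "classical") is NA

    def test_too_few_phases_not_computable(self, seq):
        assert rs.runs(seq([1, 2, 3])) is NA

    def test_population_variance(self, seq):
        # pooled phase lengths {1, 2}: population variance 0.25
        s = seq([1, 5, 2, 3, 4, 1])
        asc, desc = rs.phase_lengths(s)
        pooled = asc.expand() + desc.expand()
        assert rs.runs(s) == pytest.approx(float(np.var(pooled)))


class TestRepetitionDistances:
    def test_simple(self, seq):
        assert rs.repetition_distances(seq([1, 2, 1])).entries == {2: 1}

    def test_immediate(self, seq):
        assert rs.repetition_distances(seq([1, 1])).entries == {1: 1}

    def test_most_recent_occurrence(self, seq):
        assert rs.repetition_distances(seq([1, 2, 1, 2, 1])).entries == {2: 3}

    def test_no_repeats_empty(self, seq):
        assert rs.repetition_distances(seq([1, 2, 3])).entries == {}


class TestRepetitionGap:
    def test_point_mass(self, seq):
        gap = rs.repetition_gap(seq([1, 2, 1, 2, 1]))
        assert gap == rs.RepetitionGap(2.0, 2.0, 2.0)

    def test_modal_tie_resolves_to_smallest(self, seq):
        gap = rs.repetition_gap(seq([1, 1, 2, 3, 1]))  # distances {1:1, 3:1}
        assert gap.mean == pytest.approx(2.0)
        assert gap.median == pytest.approx(2.0)
        assert gap.mode == 1.0

    def test_no_repeats_not_computable(self, seq):
        assert rs.repetition_gap(seq([1, 2, 3])) is NA


class TestPhiIndices:
    def test_period_three_sequence_signs(self, seq):
        # every repeat is at distance exactly 3
        s = seq([1, 2, 3] * 10)
        phi = rs.phi_indices(s, reps=400, seed=11)
        assert phi[3] > 0
        assert phi[2] < 0

    def test_lag_beyond_length_not_computable(self):
        s = rs.make_sequence([1, 2, 1], min_scale=1, max_scale=2)
        phi = rs.phi_indices(s, lags=(2, 5), reps=100, seed=0)
        assert phi[5] is NA

    def test_deterministic_in_seed(self, seq):
        s = seq([3, 1, 4, 1, 5, 9, 2, 6, 5, 3])
        a = rs.phi_indices(s, reps=200, seed=3)
        b = rs.phi_indices(s, reps=200, seed=3)
        assert a == b


class TestResponseFrequencies:
    def test_includes_zeros(self):
        s = rs.make_sequence([1, 1, 2], min_scale=1, max_scale=3)
        assert rs.response_frequencies(s).entries == {1: 2, 2: 1, 3: 0}

    def test_constant(self, seq):
        table = rs.response_frequencies(seq([4] * 7))
        assert table[4] == 7
        assert table.total == 7

    def test_total_is_n(self, seq):
        s = seq([1, 2, 2, 9])
        assert rs.response_frequencies(s).total == s.n


class TestAllRng:
    def test_all_thirteen_measure_groups_present(self, seq):
        result = rs.all_rng(seq([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8]), phi_reps=50)
        groups = [m for m in rs.MEASURES if m != "rf"]
        assert len(groups) == 13
        for name in groups:
            assert name in result
        assert "rf" in result  # response frequencies ride along by default

    def test_single_enabled_measure(self, seq):
        result = rs.all_rng(seq([1, 2, 3]), enabled=("coupon",))
        assert list(result.keys()) == ["coupon"]

    def test_unused_alternative_only_disables_coupon(self, seq):
        s = seq([1, 2, 3, 4, 5, 6, 8, 9] * 3)  # 7 missing
        result = rs.all_rng(s, phi_reps=50)
        assert result["coupon"] is NA
        assert result["redundancy"] is not NA
        assert result["tpi"] is not NA

    def test_unknown_measure_rejected(self, seq):
        with pytest.raises(ValueError, match="unknown measures"):
            rs.all_rng(seq([1, 2, 3]), enabled=("bogus",))

    def test_empty_enabled_rejected(self, seq):
        with pytest.raises(ValueError):
            rs.all_rng(seq([1, 2, 3]), enabled=())
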