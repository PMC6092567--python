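"""Unit and property tests for the shared statistical primitives."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppx.stats_core import (
    ContingencyTable2x2,
    bh_adjust,
    fisher_exact_2x2,
    kendall_tau,
    n_arrangements,
    permutation_pvalue,
    power_simulation,
)


def fisher_two_sided_oracle(a, b, c, d):
    """Brute-force minimum-likelihood Fisher p via factorial rationals."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    f = math.factorial

    def pmf(i):
        j = row1 - i
        return Fraction(
            f(col1) * f(n - col1) * f(row1) * f(n - row1),
            f(i) * f(col1 - i) * f(j) * f(n - col1 - j) * f(n),
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = pmf(a)
    return float(sum(pmf(i) for i in range(lo, hi + 1) if pmf(i) <= p_obs))


class TestFisherExact:
    def test_symmetric_table_is_null(self):
        res = fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert res.odds_ratio == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_opposite_direction_regulation_table(self):
        # 15 of 17 genes counter-regulated in preterm vs 9 of 17 in term disease
        res = fisher_exact_2x2(ContingencyTable2x2(15, 2, 9, 8))
        assert round(res.p_value, 3) == 0.057
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(15, 2, 9, 8), abs=1e-12)

    def test_zero_cell_gives_infinite_odds_ratio(self):
        res = fisher_exact_2x2(ContingencyTable2x2(5, 0, 3, 7))
        assert res.odds_ratio == math.inf
        assert 0 < res.p_value <= 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_one_sided_alternatives_sum_beyond_one(self):
        t = ContingencyTable2x2(8, 2, 3, 9)
        g = fisher_exact_2x2(t, "greater").p_value
        l = fisher_exact_2x2(t, "less").p_value
        # the observed table is counted in both tails
        assert g + l >= 1.0

    @given(st.lists(st.integers(0, 25), min_size=4, max_size=4).filter(lambda t: sum(t) > 0))
    def test_matches_bruteforce_oracle(self, counts):
        res = fisher_exact_2x2(ContingencyTable2x2(*counts))
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(*counts), abs=1e-12)

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4).filter(lambda t: sum(t) > 0))
    def test_transpose_invariance(self, counts):
        a, b, c, d = counts
        r1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        r2 = fisher_exact_2x2(ContingencyTable2x2(a, c, b, d))
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        if math.isfinite(r1.odds_ratio) and math.isfinite(r2.odds_ratio):
            assert r1.odds_ratio == pytest.approx(r2.odds_ratio)

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
            if a + b + c + d == 0:
                continue
            mine = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            ref = fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, abs=1e-9)


def bh_oracle(p):
    """Step-up definition: q_i = min_{j: p_j >= p_i} p_j * m / rank(p_j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(size=100)
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_dominates_input_and_preserves_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        # sorted by p, the adjusted values are monotone non-decreasing
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_idempotent_on_constant_vectors(self):
        # constant vectors are fixed points of the step-up map
        q = np.array([0.2, 0.2, 0.2, 0.2])
        assert bh_adjust(q) == pytest.approx(q)


class TestKendallTau:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 4.0 / 6.0),
        ],
    )
    def test_pair_count_examples(self, x, y, expected):
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            kendall_tau([1, 1, 1], [1, 2, 3])


def mean_diff(values, labels):
    labels = np.asarray(labels)
    groups = np.unique(labels)
    return values[labels == groups[0]].mean() - values[labels == groups[1]].mean()


class TestPermutationPvalue:
    def test_exhaustive_enumeration_small_design(self):
        values = np.array([10.0, 10.0, 0.0, 0.0])
        labels = np.array(["A", "A", "B", "B"])
        res = permutation_pvalue(values, labels, mean_diff, tail="greater")
        assert res.exhaustive and res.n_permutations == 6
        assert res.p_value == pytest.approx(1 / 6)
        assert sorted(res.null_statistics) == pytest.approx([-10, 0, 0, 0, 0, 10])

    def test_unique_maximum_gives_one_over_arrangements(self):
        rng = np.random.default_rng(0)
        values = np.array([9.0, 8.0, 7.5, 0.1, 0.2, 0.0])
        labels = np.array(["A"] * 3 + ["B"] * 3)
        res = permutation_pvalue(values, labels, mean_diff, tail="greater")
        assert res.exhaustive
        assert res.p_value == pytest.approx(1 / n_arrangements(labels))

    def test_exhaustive_is_seed_independent(self):
        values = np.arange(8.0)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        p1 = permutation_pvalue(values, labels, mean_diff, seed=1).p_value
        p2 = permutation_pvalue(values, labels, mean_diff, seed=999).p_value
        assert p1 == p2

    def test_sampled_p_is_smoothed_and_positive(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=20)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        res = permutation_pvalue(
            values, labels, mean_diff, max_exhaustive=100, n_random=200, seed=2
        )
        assert not res.exhaustive and res.n_permutations == 200
        assert res.p_value >= 1 / 201

    def test_degenerate_single_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.arange(4.0), np.array(["A"] * 4), mean_diff)

    def test_type_one_error_calibration(self):
        """Under a true null the rejection rate at alpha=0.05 stays inside the
        binomial 99% band over 500 repeats."""
        rng = np.random.default_rng(12)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        alpha = 0.05
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            values = rng.normal(size=10)
            res = permutation_pvalue(values, labels, mean_diff, tail="two_sided")
            rejections += res.p_value <= alpha
        rate = rejections / n_rep
        band = 2.576 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= band


class TestPowerSimulation:
    def test_accept_rule_boundary(self):
        def three_of_ten(rng, sizes):
            # deterministic alternation: strong effect in 3 of 10 repeats
            three_of_ten.i += 1
            if three_of_ten.i % 10 < 3:
                return np.zeros(sizes[0]), np.full(sizes[1], 50.0) + rng.normal(0, 0.1, sizes[1])
            return rng.normal(0, 1, sizes[0]), rng.normal(0, 1, sizes[1])

        three_of_ten.i = -1
        frac, accepted = power_simulation((10, 10), three_of_ten, n_repeats=10, seed=0)
        assert frac == pytest.approx(0.3)
        assert accepted  # 30% > 25%

    def test_null_effect_matches_alpha_and_rejects(self):
        frac, accepted = power_simulation((10, 10), 0.0, n_repeats=1000, seed=1)
        assert abs(frac - 0.05) < 0.03
        assert not accepted

    def test_large_effect_accepted(self):
        frac, accepted = power_simulation((10, 10), 5.0, n_repeats=100, seed=2)
        assert frac > 0.95 and accepted

    def test_invalid_repeats_rejected(self):
        with pytest.raises(ValueError):
            power_simulation((5, 5), 1.0, n_repeats=0)
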