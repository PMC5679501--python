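"""Pair statistics: enumeration, delta Ct, AUC, p values, cutoffs, selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpair import (
    InsufficientDataError,
    IntegrityError,
    MultiplicityPolicy,
    Pair,
    PairStat,
    best_accuracy_cutoff,
    effective_test_count,
    enumerate_pairs,
    mann_whitney_p,
    orient_pair,
    pair_delta_ct,
    pair_statistics,
    rank_auc,
    screen_pairs,
    select_pairs,
)
from mirpair.pairs import PairValues, pairwise_mw_pvalues

from conftest import make_matrix


def brute_force_auc(values, labels):
    """O(n1*n2) win count with half credit for ties (independent oracle)."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    case, ctrl = v[y], v[~y]
    wins = sum(1.0 if c > k else 0.5 if c == k else 0.0
               for c in case for k in ctrl)
    return wins / (len(case) * len(ctrl))


def random_instance(rng, max_n=50):
    n1 = int(rng.integers(1, max_n + 1))
    n2 = int(rng.integers(1, max_n + 1))
    if rng.random() < 0.5:  # integer values force ties
        v = rng.integers(0, 8, n1 + n2).astype(float)
    else:
        v = rng.normal(size=n1 + n2)
    return v, np.array([True] * n1 + [False] * n2)


# ---------------------------------------------------------------------------
# enumeration and delta Ct
# ---------------------------------------------------------------------------

class TestEnumeratePairs:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (37, 666)])
    def test_pair_count(self, n, expected):
        assert len(enumerate_pairs([f"miR-{i:02d}" for i in range(n)])) == expected

    def test_lexicographic_and_unordered(self):
        pairs = enumerate_pairs(["c", "a", "b"])
        assert pairs == [Pair("a", "b"), Pair("a", "c"), Pair("b", "c")]

    def test_duplicates_rejected(self):
        with pytest.raises(IntegrityError):
            enumerate_pairs(["miR-16", "miR-16", "miR-132"])


class TestPairDeltaCt:
    @pytest.mark.parametrize("ct_a,ct_b,delta,ratio", [
        (30.0, 30.0, 0.0, 100.0),
        (27.0, 30.0, -3.0, 800.0),
    ])
    def test_delta_and_display_ratio(self, ct_a, ct_b, delta, ratio):
        m = make_matrix({"A": [ct_a], "B": [ct_b]})
        values = pair_delta_ct(m, Pair("A", "B"))
        assert values.delta_ct.iloc[0] == delta
        assert values.ratio.iloc[0] == pytest.approx(ratio)

    def test_missing_propagates(self):
        m = make_matrix({"A": [30.0, 30.0], "B": [np.nan, 29.0]})
        values = pair_delta_ct(m, Pair("A", "B"))
        assert values.complete.tolist() == [False, True]

    def test_unknown_mirna(self):
        m = make_matrix({"A": [30.0], "B": [30.0]})
        with pytest.raises(KeyError, match="nope"):
            pair_delta_ct(m, Pair("A", "nope"))

    @given(st.floats(min_value=-20, max_value=20,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=60, deadline=None)
    def test_ratio_roundtrip(self, delta):
        values = PairValues(Pair("A", "B"), pd.Series([delta]))
        back = -np.log2(values.ratio.iloc[0] / 100.0)
        assert back == pytest.approx(delta, abs=1e-10)


# ---------------------------------------------------------------------------
# rank AUC and Mann-Whitney
# ---------------------------------------------------------------------------

class TestRankAuc:
    @pytest.mark.parametrize("values,labels,expected", [
        ([3, 4, 1, 2], [1, 1, 0, 0], 1.0),
        ([5, 5, 5, 5], [1, 1, 0, 0], 0.5),
        ([1, 2, 3, 2, 3, 4], [1, 1, 1, 0, 0, 0], 2 / 9),
    ])
    def test_known_values(self, values, labels, expected):
        assert rank_auc(values, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            v, y = random_instance(rng)
            assert rank_auc(v, y) == pytest.approx(brute_force_auc(v, y),
                                                   abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        v, y = rng.normal(size=40), rng.random(40) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert rank_auc(np.exp(v), y) == pytest.approx(rank_auc(v, y))
        assert rank_auc(3 * v + 1, y) == pytest.approx(rank_auc(v, y))

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            rank_auc([1, 2, 3], [1, 1, 1])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        v, y = random_instance(rng, max_n=30)
        if y.all() or not y.any():
            return
        assert rank_auc(v, y) == pytest.approx(roc_auc_score(y, v), abs=1e-12)


class TestMannWhitneyP:
    def test_exact_small_sample(self):
        # most extreme split of {1..6}: both one-sided tails, 2 * 1/20
        assert mann_whitney_p([4, 5, 6, 1, 2, 3],
                              [1, 1, 1, 0, 0, 0]) == pytest.approx(0.1)

    def test_two_sided_symmetry(self, rng):
        v, y = random_instance(rng, max_n=15)
        assert mann_whitney_p(v, y) == pytest.approx(mann_whitney_p(v, ~y))

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=60)
        y = np.arange(60) < 25
        assert mann_whitney_p(np.exp(v), y) == pytest.approx(mann_whitney_p(v, y))

    def test_p_in_unit_interval(self, rng):
        for _ in range(50):
            v, y = random_instance(rng, max_n=20)
            assert 0 < mann_whitney_p(v, y) <= 1


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

class TestOrientPair:
    def _values(self, case, ctrl):
        delta = pd.Series(list(case) + list(ctrl), dtype=float)
        labels = np.array([True] * len(case) + [False] * len(ctrl))
        return PairValues(Pair("A", "B"), delta), labels

    def test_kept_when_ratio_larger_in_cases(self):
        # ratios case {200,400} ctrl {50,100} -> delta case < delta ctrl
        values, labels = self._values([-1.0, -2.0], [1.0, 0.0])
        assert orient_pair(values, labels).pair == Pair("A", "B")

    def test_swapped_when_ratio_smaller_in_cases(self):
        values, labels = self._values([2.0], [-1.0])
        oriented = orient_pair(values, labels)
        assert oriented.pair == Pair("B", "A")
        assert (oriented.delta_ct == -values.delta_ct).all()

    def test_tie_keeps_input_orientation(self):
        values, labels = self._values([-1.0, 1.0], [-1.0, 1.0])
        assert orient_pair(values, labels).pair == Pair("A", "B")

    def test_oriented_auc_is_max_of_both(self, rng):
        for _ in range(100):
            v, y = random_instance(rng, max_n=20)
            values = PairValues(Pair("A", "B"), pd.Series(v))
            a = rank_auc(-values.delta_ct, y)
            oriented = orient_pair(values, y)
            assert rank_auc(-oriented.delta_ct, y) == pytest.approx(
                max(a, 1 - a), abs=1e-12)


# ---------------------------------------------------------------------------
# best-accuracy cutoff
# ---------------------------------------------------------------------------

def exhaustive_best_accuracy(values, labels):
    """Scan every threshold (plus infinities) for the best accuracy."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    cands = np.concatenate([[-np.inf], np.unique(v) - 1e-9,
                            np.unique(v) + 1e-9, [np.inf]])
    return max(np.mean((v >= c) == y) for c in cands)


class TestBestAccuracyCutoff:
    def test_separable(self):
        cm = best_accuracy_cutoff([2, 3, 0, 1], [1, 1, 0, 0])
        assert cm.accuracy == 1.0 and 1 < cm.cutoff < 2

    def test_interleaved_is_coin_flip(self):
        cm = best_accuracy_cutoff([1, 3, 2, 4], [1, 1, 0, 0])
        assert cm.accuracy == pytest.approx(0.5)

    def test_constant_values(self):
        cm = best_accuracy_cutoff([5, 5, 5, 5], [1, 1, 0, 0])
        assert cm.accuracy == pytest.approx(0.5)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            v, y = random_instance(rng, max_n=15)
            cm = best_accuracy_cutoff(v, y)
            assert cm.accuracy == pytest.approx(exhaustive_best_accuracy(v, y),
                                                abs=1e-12)
            # metrics are mutually consistent at the returned cutoff
            n1, n0 = y.sum(), (~y).sum()
            assert cm.accuracy == pytest.approx(
                (cm.sensitivity * n1 + cm.specificity * n0) / (n1 + n0))

    def test_accuracy_at_least_prevalence(self, rng):
        for _ in range(50):
            v, y = random_instance(rng, max_n=15)
            prevalence = max(y.mean(), 1 - y.mean())
            assert best_accuracy_cutoff(v, y).accuracy >= prevalence - 1e-12

    def test_tie_broken_to_lowest_cutoff(self):
        # cutoffs 0.5 and 2.5 tie on accuracy (0.75) and Youden J (0.5)
        cm = best_accuracy_cutoff([1, 3, 0, 2], [1, 1, 0, 0])
        assert cm.cutoff == pytest.approx(0.5)

    def test_inclusive_call_at_cutoff_value(self):
        # case exactly at the optimum must be called a case
        cm = best_accuracy_cutoff([1.0, 2.0, 0.0], [1, 1, 0])
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0


# ---------------------------------------------------------------------------
# pair statistics + screening
# ---------------------------------------------------------------------------

class TestPairStatistics:
    def test_cutoff_reported_on_delta_ct_scale(self):
        m = make_matrix({"A": [27.0, 28.0, 31.0, 32.0],
                         "B": [30.0, 30.0, 30.0, 30.0]})
        labels = [True, True, False, False]
        stat = pair_statistics(pair_delta_ct(m, Pair("A", "B")), labels)
        assert stat.auc == 1.0 and stat.accuracy == 1.0
        assert -2.0 < stat.cutoff < 1.0  # cases have delta <= cutoff

    def test_incomplete_pairs_skipped(self):
        a = [25.0] * 10
        b = [30.0] * 10
        c = [np.nan] * 5 + [28.0] * 5  # 50% missing < 70% completeness
        m = make_matrix({"A": a, "B": b, "C": c})
        labels = [True] * 5 + [False] * 5
        stats = screen_pairs(m, labels)
        assert {s.pair.label for s in stats} == {"A/B"}


class TestEffectiveTestCount:
    def test_two_perfect_blocks(self, rng):
        base = rng.normal(30, 1, 25)
        other = rng.normal(28, 1, 25)
        m = make_matrix({"A": base, "B": base + 1.0,
                         "C": other, "D": other - 0.5})
        policy = effective_test_count(m, 0.8)
        assert policy.n_pairs_nominal == 6
        assert policy.n_pairs_effective == 1
        assert policy.p_threshold == pytest.approx(0.05)

    def test_uncorrelated_panel_keeps_nominal(self, rng):
        m = make_matrix({f"m{i:02d}": rng.normal(30, 1, 80) for i in range(12)})
        policy = effective_test_count(m, 0.8)
        assert policy.n_pairs_effective == policy.n_pairs_nominal == 66

    def test_single_cluster_falls_back_with_warning(self, rng):
        base = rng.normal(30, 1, 20)
        m = make_matrix({"A": base, "B": base * 1.0 + 2, "C": base - 1})
        with pytest.warns(UserWarning, match="nominal"):
            policy = effective_test_count(m, 0.8)
        assert policy.n_pairs_effective == policy.n_pairs_nominal == 3

    def test_constant_profile_excluded(self, rng):
        base = rng.normal(30, 1, 20)
        m = make_matrix({"A": base, "B": -base, "C": np.full(20, 30.0)})
        with pytest.warns(UserWarning, match="constant"):
            policy = effective_test_count(m, 0.8)
        assert policy.n_pairs_effective == 1  # A and B anticorrelated -> 2 clusters

    def test_chain_uses_single_linkage(self, rng):
        # A~B and B~C strongly, A~C weakly: single linkage joins all three
        n = 400
        shared = rng.normal(0, 1, n)
        a = shared + rng.normal(0, 0.55, n)
        c = shared + rng.normal(0, 0.55, n)
        m = make_matrix({"A": 30 + a, "B": 30 + shared, "C": 30 + c,
                         "D": rng.normal(30, 1, n)})
        rho = m.ct.corr(method="spearman")
        assert rho.loc["A", "B"] >= 0.8 and rho.loc["B", "C"] >= 0.8
        assert rho.loc["A", "C"] < 0.8
        policy = effective_test_count(m, 0.8)
        assert policy.n_pairs_effective == 1  # clusters {A,B,C} and {D}


class TestSelectPairs:
    def _stat(self, auc, p, label="A/B"):
        num, den = label.split("/")
        return PairStat(Pair(num, den), auc, p, 0.0, 1, 1, 1, 5, 5)

    def test_gates_and_sorting(self):
        policy = MultiplicityPolicy.nominal(37)
        stats = [
            self._stat(0.76, 1e-6, "A/B"),
            self._stat(0.80, 0.01, "C/D"),  # fails Bonferroni at 7.5e-5
            self._stat(0.74, 1e-9, "E/F"),  # fails AUC gate
            self._stat(0.90, 1e-8, "G/H"),
        ]
        chosen = select_pairs(stats, 0.75, policy)
        assert [s.pair.label for s in chosen] == ["G/H", "A/B"]
        assert all(s.selected for s in chosen)

    def test_p_gate_can_be_disabled(self):
        policy = MultiplicityPolicy.nominal(37)
        stats = [self._stat(0.80, 0.01)]
        assert select_pairs(stats, 0.75, policy) == []
        assert len(select_pairs(stats, 0.75, policy, use_p_gate=False)) == 1

    def test_empty_input(self):
        assert select_pairs([], 0.75, MultiplicityPolicy.nominal(5)) == []


class TestVectorizedPValues:
    def test_matches_scalar_op(self, rng):
        m = make_matrix({f"m{i}": rng.normal(30, 1, 60) for i in range(5)})
        labels = np.arange(60) < 30
        vec = pairwise_mw_pvalues(m, labels)
        for pair in enumerate_pairs(m.ct.columns):
            scalar = mann_whitney_p(pair_delta_ct(m, pair).delta_ct, labels)
            assert vec[pair.label] == pytest.approx(scalar, rel=1e-12)
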