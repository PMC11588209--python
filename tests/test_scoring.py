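import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guildfinder import (
    Grouping,
    jaccard,
    overall_score,
    performance_ceiling,
    r2_out_of_sample,
    random_grouping,
    recovery_quality,
    score_report,
)


def all_two_group_partitions(n):
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), r):
            part = frozenset(combo)
            if r == n - len(part) and min(part) != min(range(n)):
                continue  # avoid double-counting complements of equal size
            yield Grouping.from_sets([part, frozenset(range(n)) - part], n)


class TestJaccard:
    def test_identical_sets(self):
        s = set(range(16))
        assert jaccard(s, s) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({1, 2}, {3, 4}) == 0.0

    def test_half_overlap(self):
        small = set(range(16))
        assert jaccard(small, set(range(32))) == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), {1})


class TestRecoveryQuality:
    def test_verbatim_group_scores_one(self):
        g = Grouping.from_sets([{0, 1}, {2, 3}], 4)
        assert recovery_quality({2, 3}, g) == 1.0

    def test_merged_groups_score_half(self):
        truth_group = set(range(16))
        merged = Grouping.from_sets([set(range(32)), set(range(32, 48))], 48)
        assert recovery_quality(truth_group, merged) == 0.5

    def test_best_match_may_be_shared(self):
        """One output group can be the best match of several truth groups."""
        out = Grouping.from_sets([{0, 1, 2, 3}, {4, 5}], 6)
        assert recovery_quality({0, 1}, out) == 0.5
        assert recovery_quality({2, 3}, out) == 0.5


class TestOverallScore:
    def test_perfect_match(self, pool48):
        assert overall_score(pool48.truth, pool48.truth) == 1.0

    def test_universe_mismatch(self):
        a = Grouping.from_labels([0, 1])
        b = Grouping.from_labels([0, 1, 1])
        with pytest.raises(ValueError):
            overall_score(a, b)

    def test_exhaustive_two_group_maximum_is_the_ceiling(self):
        """Over all 2-group partitions of 6 species against a 3-pair truth,
        the best achievable score is exactly k/N = 2/3."""
        truth = Grouping.from_sets([{0, 1}, {2, 3}, {4, 5}], 6)
        best = max(
            overall_score(truth, cand) for cand in all_two_group_partitions(6)
        )
        assert best == pytest.approx(2 / 3)

    def test_random_grouping_mean_matches_monte_carlo_oracle(self):
        """Mean score of random 3-groupings at S=48 agrees between two
        independent streams (self-consistency of the uniform generator)."""
        truth = Grouping.from_labels(np.repeat([0, 1, 2], 16))
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        s1 = [overall_score(truth, random_grouping(48, 3, rng1)) for _ in range(2000)]
        s2 = [overall_score(truth, random_grouping(48, 3, rng2)) for _ in range(2000)]
        se = np.hypot(np.std(s1) / np.sqrt(len(s1)), np.std(s2) / np.sqrt(len(s2)))
        assert abs(np.mean(s1) - np.mean(s2)) < 3 * se


class TestPerformanceCeiling:
    @pytest.mark.parametrize(
        "k, N, expected", [(2, 3, 2 / 3), (3, 3, 1.0), (1, 4, 0.25), (7, 4, 1.0)]
    )
    def test_values(self, k, N, expected):
        assert performance_ceiling(k, N) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            performance_ceiling(0, 3)


class TestR2OutOfSample:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_out_of_sample(y, y) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_out_of_sample(np.full(3, 2.0), y) == pytest.approx(0.0)

    def test_worse_than_mean_is_negative(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_out_of_sample(np.array([3.0, 1.0, -1.0]), y) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r2_out_of_sample(np.ones(3), np.ones(3))


class TestScoreReport:
    def test_full_report(self, pool48):
        report = score_report(pool48.truth, random_grouping(48, 2, 0))
        assert report.k == 2
        assert report.ceiling == pytest.approx(2 / 3)
        assert 0 <= report.overall <= report.ceiling
        assert len(report.per_group) == 3

    def test_unequal_truth_sizes_omit_ceiling(self):
        truth = Grouping.from_sets([{0}, {1, 2, 3}], 4)
        report = score_report(truth, random_grouping(4, 2, 0))
        assert report.ceiling is None


class TestProperties:
    @settings(derandomize=True, max_examples=60)
    @given(k=st.integers(1, 8), seed=st.integers(0, 2**31 - 1))
    def test_score_never_exceeds_ceiling(self, k, seed):
        truth = Grouping.from_labels(np.repeat([0, 1, 2], 8))
        cand = random_grouping(24, k, seed)
        assert overall_score(truth, cand) <= performance_ceiling(k, 3) + 1e-12

    @settings(derandomize=True, max_examples=30)
    @given(k=st.integers(1, 10), seed=st.integers(0, 2**31 - 1), pseed=st.integers(0, 99))
    def test_invariant_under_species_relabeling(self, k, seed, pseed):
        truth = Grouping.from_labels(np.repeat([0, 1, 2, 3], 5))
        cand = random_grouping(20, k, seed)
        perm = np.random.default_rng(pseed).permutation(20)
        assert overall_score(
            truth.relabel_species(perm), cand.relabel_species(perm)
        ) == pytest.approx(overall_score(truth, cand))

    def test_exhaustive_agreement_at_small_s(self):
        """The best k-group score over *all* partitions of 6 species equals
        the analytic ceiling min(k, N)/N for every k."""
        truth = Grouping.from_sets([{0, 1}, {2, 3}, {4, 5}], 6)

        def partitions(elements):
            if len(elements) == 1:
                yield [elements]
                return
            head, *rest = elements
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[head] + part[i]] + part[i + 1 :]
                yield [[head]] + part

        best_by_k = {}
        for part in partitions(list(range(6))):
            g = Grouping.from_sets([set(p) for p in part], 6)
            sc = overall_score(truth, g)
            best_by_k[g.k] = max(best_by_k.get(g.k, 0.0), sc)
        for k in (1, 2, 3):
            assert best_by_k[k] == pytest.approx(performance_ceiling(k, 3))
        for k in (4, 5, 6):  # over-splitting can no longer reproduce all pairs
            assert best_by_k[k] < 1.0
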