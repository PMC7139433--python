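"""Rank-sum comparisons of per-picture medians: conventions and oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from emomeg import (
    CohortSpec,
    EffectSpec,
    compare_groups,
    generate_ratings,
    per_picture_medians,
    rank_sum_test,
)


def enumeration_pvalue(a, b):
    """Exhaustive two-sided rank-sum p-value for tie-free samples.

    Enumerates every assignment of the pooled ranks to the first sample and
    doubles the smaller tail (both tails include the observed statistic).
    """
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle assumes no ties"
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    total = len(sums)
    lower = sum(s <= w_obs for s in sums) / total
    upper = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2.0 * min(lower, upper))


class TestPerPictureMedians:
    def make_table(self, ratings_by_subject, group=1, category="neutral"):
        rows = []
        for sid, vals in ratings_by_subject.items():
            for pic, v in enumerate(vals):
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "picture_id": f"pic{pic}",
                        "category": category,
                        "valence": v,
                        "arousal": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_unanimous_rating_gives_that_median(self):
        t = self.make_table({"a": [4, 4], "b": [4, 4], "c": [4, 4]})
        med = per_picture_medians(t, 1, "neutral", "valence")
        assert (med == 4).all()

    def test_odd_count_median(self):
        t = self.make_table({"a": [2], "b": [3], "c": [5]})
        assert per_picture_medians(t, 1, "neutral", "valence").iloc[0] == 3

    def test_even_count_mean_of_middle_two(self):
        t = self.make_table({"a": [2], "b": [3], "c": [5], "d": [6]})
        assert per_picture_medians(t, 1, "neutral", "valence").iloc[0] == 4.0

    def test_incomplete_subject_excluded(self):
        t = self.make_table({"a": [1, 1], "b": [7, 7], "c": [7, 7]})
        t = t.drop(t[(t.subject_id == "b") & (t.picture_id == "pic1")].index)
        med = per_picture_medians(t, 1, "neutral", "valence")
        # only a and c remain complete -> median of {1, 7} = 4
        assert (med == 4.0).all()


class TestRankSumTest:
    def test_identical_samples_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_constant_samples_p_one(self):
        res = rank_sum_test([4, 4, 4], [4, 4, 4])
        assert res.p_value == 1.0

    def test_extreme_three_vs_three(self):
        """Most extreme of the C(6,3)=20 orderings, doubled: p = 0.1."""
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 6.0  # ranks 1+2+3

    def test_rank_conservation(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(size=5)
        res = rank_sum_test(a, b)
        other = rank_sum_test(b, a)
        n = res.n1 + res.n2
        assert res.statistic + other.statistic == n * (n + 1) / 2

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20) + 0.5
        p1 = rank_sum_test(a, b).p_value
        p2 = rank_sum_test(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 8), (3, 5), (4, 4), (5, 5), (2, 4)])
    def test_exact_path_equals_enumeration_oracle(self, n1, n2):
        """Exact p-values reproduce exhaustive enumeration on every layout."""
        n = n1 + n2
        values = np.arange(1.0, n + 1)
        for combo in itertools.combinations(range(n), n1):
            a = values[list(combo)]
            b = np.delete(values, list(combo))
            res = rank_sum_test(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumeration_pvalue(a, b), abs=1e-12)

    @pytest.mark.parametrize(
        "n1,n2,bound",
        [
            # coarse agreement once both groups have >= 2 members ...
            (2, 8, 0.09), (2, 6, 0.09), (3, 4, 0.09), (4, 4, 0.09),
            # ... tightening as the samples grow
            (3, 5, 0.035), (3, 7, 0.035), (4, 5, 0.025), (4, 6, 0.025), (5, 5, 0.025),
        ],
    )
    def test_normal_approximation_approaches_exact(self, n1, n2, bound):
        """Tie/continuity-corrected normal p converges to the exact p.

        Worst-case deviation over every tie-free layout of the given sizes;
        the tolerance tightens with growing samples (the approximation is
        never used below the exact-path size anyway).
        """
        from scipy import stats

        n = n1 + n2
        values = np.arange(1.0, n + 1)
        worst = 0.0
        for combo in itertools.combinations(range(n), n1):
            a = values[list(combo)]
            b = np.delete(values, list(combo))
            exact = enumeration_pvalue(a, b)
            approx = float(
                stats.mannwhitneyu(
                    a, b, alternative="two-sided", method="asymptotic", use_continuity=True
                ).pvalue
            )
            worst = max(worst, abs(exact - min(approx, 1.0)))
        assert worst < bound


class TestCompareGroups:
    def test_planted_shift_detected_only_in_pleasant_valence(self):
        spec = CohortSpec(seed=5)
        effect = EffectSpec(valence_shift_pleasant=-1.2)
        table = generate_ratings(spec, effect, seed=5, n_incomplete_patients=2)
        report = compare_groups(table)
        assert len(report) == 6
        target = report[(report.category == "pleasant") & (report.dimension == "valence")]
        assert target.iloc[0].p_value < 0.05
        # patients rate pleasant pictures more positively (lower valence)
        assert target.iloc[0].median_group0 < target.iloc[0].median_group1

    def test_sample_sizes_are_picture_counts(self):
        spec = CohortSpec(seed=6)
        table = generate_ratings(spec, seed=6, n_pictures_per_category=30)
        report = compare_groups(table)
        assert (report.n1 == 30).all() and (report.n2 == 30).all()

    def test_group_relabel_symmetry(self):
        spec = CohortSpec(seed=7)
        table = generate_ratings(spec, seed=7)
        a = compare_groups(table, group_a=1, group_b=0)
        b = compare_groups(table, group_a=0, group_b=1)
        assert np.allclose(a.p_value.to_numpy(), b.p_value.to_numpy())

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(pd.DataFrame({"category": [], "subject_id": [], "picture_id": [],
                                         "group": [], "valence": [], "arousal": []}))
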