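"""Permutation equivalence classes and permutation-based contrast scores."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from contrastfdr import (
    MeasurementPair,
    build_plan,
    contrast_from_permutations,
    count_equivalence_classes,
    permuted_statistics,
)
from contrastfdr.permutation import PermutedStatMatrix


@pytest.mark.parametrize(
    "m, n, mode, expected",
    [
        (2, 1, "enrichment", 3),
        (3, 3, "enrichment", 20),
        (3, 3, "differential", 10),
        (1, 1, "differential", 1),
        (2, 3, "differential", 10),
        (10, 10, "enrichment", comb(20, 10)),
    ],
)
def test_class_counts(m, n, mode, expected):
    assert count_equivalence_classes(m, n, mode) == expected


class TestBuildPlan:
    def test_exhaustive_2vs1(self):
        plan = build_plan(2, 1, "enrichment", h="max")
        assert plan.classes == [(0, 1), (0, 2), (1, 2)]
        assert plan.h == 2 and plan.exhaustive

    def test_differential_1vs1_unsupported(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_plan(1, 1, "differential")

    def test_seeded_determinism_and_seed_sensitivity(self):
        a = build_plan(5, 5, "enrichment", h=20, seed=7)
        b = build_plan(5, 5, "enrichment", h=20, seed=7)
        c = build_plan(5, 5, "enrichment", h=20, seed=8)
        assert a.classes == b.classes
        assert a.classes != c.classes

    def test_h_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_plan(2, 1, "enrichment", h=3)  # h_max = 2

    @pytest.mark.parametrize(
        "m, n, mode",
        [(2, 1, "enrichment"), (3, 3, "enrichment"), (3, 3, "differential"),
         (2, 3, "differential"), (4, 4, "differential")],
    )
    def test_exhaustive_matches_subset_enumeration_oracle(self, m, n, mode):
        """All C(m+n, m) splits, deduplicating complements for m=n differential."""
        plan = build_plan(m, n, mode, h="max")
        all_subsets = {frozenset(s) for s in itertools.combinations(range(m + n), m)}
        if mode == "differential" and m == n:
            full = frozenset(range(m + n))
            dedup = set()
            for s in all_subsets:
                if (full - s) not in dedup:
                    dedup.add(s)
            all_subsets = dedup
        got = {frozenset(c) for c in plan.classes}
        assert len(plan.classes) == len(got) == count_equivalence_classes(m, n, mode)
        # representatives cover every class up to complement-equivalence
        if mode == "differential" and m == n:
            full = frozenset(range(m + n))
            assert {s if 0 in s else full - s for s in all_subsets} == got
        else:
            assert got == all_subsets

    def test_sampled_classes_distinct_and_identity_first(self):
        plan = build_plan(6, 6, "enrichment", h=100, seed=3)  # h_max = 923
        assert plan.classes[0] == tuple(range(6))
        assert len({frozenset(c) for c in plan.classes}) == 101


class TestPermutedStatistics:
    def test_worked_2vs1_row(self):
        plan = build_plan(2, 1, "enrichment", h="max")
        pair = MeasurementPair(x=np.array([[10.0, 8.0]]), y=np.array([[1.0]]))
        stats_ = permuted_statistics(pair, plan)
        np.testing.assert_allclose(stats_.values, [[8.0, -2.5, -5.5]])

    def test_differential_takes_absolute_values(self):
        plan = build_plan(2, 1, "differential", h="max")
        pair = MeasurementPair(x=np.array([[10.0, 8.0]]), y=np.array([[1.0]]))
        stats_ = permuted_statistics(pair, plan)
        np.testing.assert_allclose(stats_.values, [[8.0, 2.5, 5.5]])

    def test_constant_row_is_all_zero(self):
        plan = build_plan(2, 1, "enrichment", h="max")
        pair = MeasurementPair(x=np.full((1, 2), 7.0), y=np.full((1, 1), 7.0))
        np.testing.assert_allclose(permuted_statistics(pair, plan).values, 0.0)

    def test_dimension_mismatch_rejected(self):
        plan = build_plan(2, 1, "enrichment", h="max")
        pair = MeasurementPair(x=np.ones((1, 3)), y=np.ones((1, 1)))
        with pytest.raises(ValueError, match="design"):
            permuted_statistics(pair, plan)


class TestContrastFromPermutations:
    @pytest.mark.parametrize(
        "row, kind, expected",
        [
            ([8.0, -2.5, -5.5], "minus", 10.5),
            ([8.0, -2.5, -5.5], "max", 8.0),
            ([2.0, 5.0, 1.0], "max", -5.0),
            ([2.0, 5.0, 1.0], "minus", -3.0),
            ([4.0, 4.0, 1.0], "max", 0.0),
            ([4.0, 4.0, 1.0], "minus", 0.0),
        ],
    )
    def test_worked_rows(self, row, kind, expected):
        stats_ = PermutedStatMatrix(np.array([row]))
        assert contrast_from_permutations(stats_, kind)[0] == pytest.approx(expected)

    def test_invariant_to_order_of_permuted_columns(self, rng):
        vals = rng.normal(size=(50, 6))
        shuffled = vals.copy()
        shuffled[:, 1:] = shuffled[:, 1:][:, rng.permutation(5)]
        for kind in ("minus", "max"):
            np.testing.assert_allclose(
                contrast_from_permutations(PermutedStatMatrix(vals), kind),
                contrast_from_permutations(PermutedStatMatrix(shuffled), kind),
            )

    def test_positive_max_score_implies_positive_direct_minus(self, rng):
        """A strictly maximal identity split beats its own complement, so a
        positive permutation-based max score forces x̄ > ȳ. (The converse is
        false: another split can exceed the identity even when x̄ > ȳ.)"""
        from contrastfdr import direct_contrast_scores

        pair = MeasurementPair(x=rng.gamma(2, 3, (200, 3)), y=rng.gamma(2, 3, (200, 3)))
        plan = build_plan(3, 3, "enrichment", h="max")
        c_max = contrast_from_permutations(permuted_statistics(pair, plan), "max")
        c_minus = direct_contrast_scores(pair, "minus")
        assert np.all(c_minus[c_max > 0] > 0)


def test_identity_rank_uniform_under_global_null(rng):
    """For i.i.d. pooled measurements the identity statistic's rank among
    the h+1 class statistics is uniform (exchangeability of the null)."""
    d, m, n = 5000, 2, 1
    pair = MeasurementPair(x=rng.gamma(3, 2, (d, m)), y=rng.gamma(3, 2, (d, n)))
    plan = build_plan(m, n, "enrichment", h="max")
    vals = permuted_statistics(pair, plan).values
    ranks = (vals > vals[:, [0]]).sum(axis=1)  # continuous data: ties negligible
    observed = np.bincount(ranks, minlength=plan.h + 1)
    res = stats.chisquare(observed)
    assert res.pvalue > 0.001
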