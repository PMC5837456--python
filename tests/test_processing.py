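import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenoscan.exceptions import (
    AmbiguousSingle,
    DegenerateDistribution,
    EmptyExpansion,
    MissingDataCode,
)
from phenoscan.processing import (
    IntegerRoute,
    ProcessingConfig,
    bin_to_ordered,
    classify_integer,
    collapse_field_columns,
    expand_cat_multiple,
    inverse_rank_normal,
    needs_binning,
    process_field,
    recode_values,
)
from phenoscan.types import (
    CatMultipleMissingness,
    ColumnKey,
    DataCoding,
    DataType,
    FieldMetadata,
    FieldType,
)


def cols(field_id, instance_arrays, data):
    """Build a ColumnKey->Series mapping from (instance, array) tuples."""
    return {
        ColumnKey(field_id, i, a): pd.Series(v, dtype=float)
        for (i, a), v in zip(instance_arrays, data)
    }


class TestCollapse:
    def test_mean_over_arrays_ignores_missing(self):
        columns = cols(
            3062,
            [(0, 0), (0, 1), (0, 2)],
            [[3.1, 2.0], [2.9, np.nan], [np.nan, np.nan]],
        )
        out, _ = collapse_field_columns(columns, FieldType.CONTINUOUS)
        assert out[0] == pytest.approx(3.0)
        assert out[1] == pytest.approx(2.0)

    def test_all_arrays_missing_stays_missing(self):
        columns = cols(3062, [(0, 0), (0, 1)], [[np.nan], [np.nan]])
        out, _ = collapse_field_columns(columns, FieldType.CONTINUOUS)
        assert out.isna().all()

    def test_later_instances_ignored_entirely(self):
        columns = cols(50, [(0, 0), (2, 0)], [[1.0, 2.0], [100.0, 100.0]])
        out, label = collapse_field_columns(columns, FieldType.CONTINUOUS)
        assert list(out) == [1.0, 2.0]
        assert "instance=0" in label

    def test_single_column_returned_unchanged(self):
        columns = cols(50, [(0, 0)], [[1.0, np.nan, 3.0]])
        out, _ = collapse_field_columns(columns, FieldType.INTEGER)
        assert out.equals(pd.Series([1.0, np.nan, 3.0]))

    def test_no_instance_zero_falls_back_to_smallest(self):
        columns = cols(50, [(1, 0), (2, 0)], [[5.0], [9.0]])
        out, label = collapse_field_columns(columns, FieldType.CONTINUOUS)
        assert list(out) == [5.0]
        assert "instance=1" in label

    def test_cat_single_with_multiple_arrays_is_ambiguous(self):
        columns = cols(50, [(0, 0), (0, 1)], [[1.0], [2.0]])
        with pytest.raises(AmbiguousSingle):
            collapse_field_columns(columns, FieldType.CAT_SINGLE)


class TestRecode:
    def test_categorical_negatives_become_missing(self):
        out = recode_values(pd.Series([1.0, -1.0, 3.0]), None, FieldType.CAT_SINGLE)
        assert list(out.isna()) == [False, True, False]

    def test_continuous_negatives_untouched(self):
        values = pd.Series([-2.5, 1.0])
        out = recode_values(values, None, FieldType.CONTINUOUS)
        assert out.equals(values)

    def test_reassignments_run_before_negative_rule(self):
        coding = DataCoding(1, reassignments={-10.0: 5.0})
        out = recode_values(pd.Series([-10.0, -1.0]), coding, FieldType.CAT_SINGLE)
        assert out[0] == 5.0 and np.isnan(out[1])

    def test_default_fills_missing_after_recoding(self):
        coding = DataCoding(1, default_value=0.0)
        out = recode_values(pd.Series([7.0, np.nan]), coding, FieldType.CAT_SINGLE)
        assert list(out) == [7.0, 0.0]


class TestInverseRankNormal:
    def test_middle_of_three_maps_to_zero_and_antisymmetric(self):
        out = inverse_rank_normal(pd.Series([1.0, 2.0, 3.0]), seed=1)
        assert out[1] == pytest.approx(0.0, abs=1e-15)
        assert out[0] == pytest.approx(-out[2])

    def test_matches_direct_quantile_oracle(self):
        # ranks of (5, 1, 3) are (3, 1, 2)
        out = inverse_rank_normal(pd.Series([5.0, 1.0, 3.0]), seed=1)
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.5) / 3)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)

    def test_ties_get_random_ranks_but_same_multiset(self):
        values = pd.Series([0.0, 0.0, 0.0, 1.0])
        out1 = inverse_rank_normal(values, seed=1)
        out2 = inverse_rank_normal(values, seed=2)
        assert not out1.equals(out2)  # tied zeros permuted differently
        np.testing.assert_allclose(
            np.sort(out1.to_numpy()), np.sort(out2.to_numpy()), atol=1e-15
        )
        # the untied maximum always gets the top rank
        assert out1[3] == out2[3] == out1.max()

    def test_missing_stays_missing(self):
        out = inverse_rank_normal(pd.Series([1.0, np.nan, 2.0]), seed=1)
        assert np.isnan(out[1]) and out.notna().sum() == 2

    def test_order_isomorphic_on_untied_values(self):
        rng = np.random.default_rng(5)
        values = pd.Series(rng.normal(size=50))
        out = inverse_rank_normal(values, seed=1)
        assert (np.argsort(out.to_numpy()) == np.argsort(values.to_numpy())).all()

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDistribution):
            inverse_rank_normal(pd.Series([2.0, 2.0, 2.0]), seed=1)

    @pytest.mark.parametrize("n,seed", [(100, 0), (500, 1), (2000, 2)])
    def test_output_is_approximately_standard_normal(self, n, seed):
        rng = np.random.default_rng(seed)
        values = pd.Series(rng.exponential(size=n))  # heavily skewed input
        out = inverse_rank_normal(values, seed=seed).to_numpy()
        assert abs(out.mean()) < 3 / math.sqrt(n)
        assert 0.8 < out.var() < 1.2


class TestNeedsBinning:
    def test_dominant_zero_triggers_binning(self):
        values = pd.Series([0.0] * 60 + list(np.linspace(1, 5, 40)))
        assert needs_binning(values)

    def test_all_distinct_does_not(self):
        assert not needs_binning(pd.Series(np.arange(50, dtype=float)))

    def test_share_exactly_at_threshold_does_not(self):
        # 2 of 10 observations = exactly 0.2
        values = pd.Series([7.0, 7.0] + list(np.arange(10, 18, dtype=float)))
        assert not needs_binning(values, dominance_threshold=0.2)
        assert needs_binning(values, dominance_threshold=0.19)


def binning_oracle(counts, k=3):
    """Brute-force best max-deviation over all split-point placements."""
    d = len(counts)
    n = sum(counts)
    target = n / k
    best = None
    for bounds in itertools.combinations(range(1, d), k - 1):
        edges = [0, *bounds, d]
        score = max(
            abs(sum(counts[a:b]) - target) for a, b in zip(edges, edges[1:])
        )
        if best is None or score < best[0]:
            best = (score, bounds)
    return best


class TestBinToOrdered:
    def expand(self, distinct, counts):
        return pd.Series(np.repeat(distinct, counts).astype(float))

    def test_dominant_value_gets_its_own_category(self):
        values = self.expand([0, 1, 2], [60, 20, 20])
        out = bin_to_ordered(values, 3)
        vc = out.values.value_counts().sort_index()
        assert list(vc) == [60, 20, 20]  # no split can beat 60/20/20

    def test_three_equal_values_one_category_each(self):
        values = self.expand([1, 2, 3], [30, 30, 30])
        out = bin_to_ordered(values, 3)
        assert list(out.values.value_counts().sort_index()) == [30, 30, 30]

    def test_zero_inflated_vector_gives_three_monotone_categories(self):
        rng = np.random.default_rng(0)
        raw = np.where(rng.uniform(size=600) < 0.6, 0.0, rng.lognormal(1, 0.5, 600))
        out = bin_to_ordered(pd.Series(raw), 3)
        assert out.data_type is DataType.ORDERED
        assert sorted(out.values.unique()) == [1.0, 2.0, 3.0]
        # labels preserve value order
        frame = pd.DataFrame({"raw": raw, "cat": out.values})
        assert frame.groupby("cat")["raw"].max().is_monotonic_increasing

    def test_fewer_distinct_than_k_gives_one_category_per_value(self):
        values = self.expand([1, 5, 9], [10, 20, 30])
        out = bin_to_ordered(values, k=5)
        assert list(out.values.value_counts().sort_index()) == [10, 20, 30]

    def test_two_distinct_values_rejected(self):
        with pytest.raises(DegenerateDistribution):
            bin_to_ordered(self.expand([0, 1], [5, 5]), 3)

    def test_missing_values_stay_missing(self):
        values = pd.Series([0.0] * 6 + [1.0, 2.0, 3.0, np.nan])
        out = bin_to_ordered(values, 3)
        assert np.isnan(out.values.iloc[-1])

    @given(
        st.lists(st.integers(1, 30), min_size=3, max_size=12),
        st.integers(0, 10**6),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_enumeration_oracle(self, counts, salt):
        distinct = np.cumsum(np.ones(len(counts)))  # any increasing values
        values = self.expand(distinct, counts)
        out = bin_to_ordered(values, 3)
        achieved = out.values.value_counts().sort_index().to_numpy()
        target = sum(counts) / 3
        oracle_score, _ = binning_oracle(counts, 3)
        assert max(abs(achieved - target)) == pytest.approx(oracle_score)


class TestClassifyInteger:
    @pytest.mark.parametrize(
        "n_distinct,expected",
        [
            (2, IntegerRoute.BINARY),
            (3, IntegerRoute.ORDERED),
            (20, IntegerRoute.ORDERED),
            (21, IntegerRoute.CONTINUOUS_PATH),
            (40, IntegerRoute.CONTINUOUS_PATH),
        ],
    )
    def test_distinct_value_boundaries(self, n_distinct, expected):
        values = pd.Series(np.arange(n_distinct, dtype=float).repeat(3))
        assert classify_integer(values) is expected

    def test_single_value_is_degenerate(self):
        with pytest.raises(DegenerateDistribution):
            classify_integer(pd.Series([4.0, 4.0]))


class TestExpandCatMultiple:
    WHITE, MIXED, WHOLEMEAL, SEEDED, OTHER = 1.0, 2.0, 3.0, 4.0, 5.0

    def bread_sets(self):
        return pd.Series(
            [
                {self.WHITE},
                {self.WHITE, self.WHOLEMEAL},
                {self.MIXED},
                {self.SEEDED},
                {self.OTHER},
                set(),
            ]
        )

    def test_bread_field_yields_five_binary_children(self):
        children = expand_cat_multiple(
            self.bread_sets(), CatMultipleMissingness.RESPONDERS, field_id=20091
        )
        assert len(children) == 5
        assert all(c.data_type is DataType.BINARY for c in children)
        assert [c.name for c in children] == [
            "20091#1", "20091#2", "20091#3", "20091#4", "20091#5",
        ]

    def test_true_membership_and_responder_false(self):
        children = expand_cat_multiple(
            self.bread_sets(), CatMultipleMissingness.RESPONDERS, field_id=20091
        )
        white = children[0].values
        assert white[0] == 1.0 and white[1] == 1.0  # chose white
        assert white[2] == 0.0  # responded, chose something else
        assert np.isnan(white[5])  # non-responder

    def test_midwife_not_known_participant(self):
        # participant 0 has values {midwife, not-known(-)}; children are
        # midwife (=1) and hospital_doctor (=2)
        MIDWIFE, DOCTOR, NOT_KNOWN = 1.0, 2.0, -1.0
        sets = pd.Series(
            [{MIDWIFE, NOT_KNOWN}, {DOCTOR}, {MIDWIFE}],
        )
        children = expand_cat_multiple(
            sets, CatMultipleMissingness.RESPONDERS, field_id=41228
        )
        by_name = {c.name: c.values for c in children}
        assert by_name["41228#1"][0] == 1.0  # midwife = true: known at least once
        assert np.isnan(by_name["41228#2"][0])  # hospital_doctor: unknown, NOT false

    def test_other_value_holders_option(self):
        sets = pd.Series([{1.0}, {2.0}, set()])
        children = expand_cat_multiple(
            sets, CatMultipleMissingness.OTHER_VALUE_HOLDERS, field_id=5
        )
        v1 = children[0].values
        assert v1[0] == 1.0 and v1[1] == 0.0 and np.isnan(v1[2])

    def test_all_and_responders_coincide_when_everyone_responds(self):
        sets = pd.Series([{1.0}, {2.0}, {1.0, 2.0}])
        a = expand_cat_multiple(sets, CatMultipleMissingness.ALL, field_id=5)
        r = expand_cat_multiple(sets, CatMultipleMissingness.RESPONDERS, field_id=5)
        for ca, cr in zip(a, r):
            pd.testing.assert_series_equal(ca.values, cr.values)

    def test_all_option_counts_nonresponders_as_false(self):
        sets = pd.Series([{1.0}, set()])
        children = expand_cat_multiple(sets, CatMultipleMissingness.ALL, field_id=5)
        assert children[0].values[1] == 0.0

    def test_children_invariant_to_duplicates_in_sets(self):
        # sets deduplicate by construction; same values in different array
        # order yield identical sets, hence identical children
        s1 = pd.Series([{1.0, 2.0}, {2.0}])
        s2 = pd.Series([{2.0, 1.0}, {2.0}])
        c1 = expand_cat_multiple(s1, CatMultipleMissingness.ALL, field_id=5)
        c2 = expand_cat_multiple(s2, CatMultipleMissingness.ALL, field_id=5)
        for a, b in zip(c1, c2):
            pd.testing.assert_series_equal(a.values, b.values)

    def test_reassignment_to_missing_marks_code_as_missingness(self):
        coding = DataCoding(1, reassignments={7.0: None})
        # 7 is recoded to missing: participant 0 keeps only a missing-coded
        # value, so they are TRUE nowhere and never FALSE
        sets = pd.Series([{7.0, -3.0}, {1.0}])
        children = expand_cat_multiple(
            sets, CatMultipleMissingness.RESPONDERS, coding, field_id=5
        )
        assert len(children) == 1  # only value 1 remains

    def test_no_nonnegative_values_is_empty_expansion(self):
        sets = pd.Series([{-1.0}, set()])
        with pytest.raises(EmptyExpansion):
            expand_cat_multiple(sets, CatMultipleMissingness.ALL, field_id=5)


class TestProcessField:
    def test_walking_pace_ordinal_coding(self):
        # slow(3) < average(1) < brisk(2): ordering declared in the coding
        rng = np.random.default_rng(0)
        raw = rng.choice([3.0, 1.0, 2.0], size=100)
        columns = cols(924, [(0, 0)], [raw])
        coding = DataCoding(100327, is_ordinal=True, ordering=(3.0, 1.0, 2.0))
        meta = FieldMetadata(924, FieldType.CAT_SINGLE, data_code_id=100327)
        derived, removal = process_field(meta, columns, {100327: coding})
        assert removal is None and len(derived) == 1
        v = derived[0]
        assert v.data_type is DataType.ORDERED
        # rank 1 for raw 3, rank 2 for raw 1, rank 3 for raw 2
        assert (v.values[raw == 3.0] == 1.0).all()
        assert (v.values[raw == 1.0] == 2.0).all()
        assert (v.values[raw == 2.0] == 3.0).all()

    def test_zero_inflated_continuous_routes_to_three_ordered_levels(self):
        rng = np.random.default_rng(1)
        raw = np.where(rng.uniform(size=400) < 0.6, 0.0, rng.lognormal(1, 0.5, 400))
        meta = FieldMetadata(100022, FieldType.CONTINUOUS)
        derived, removal = process_field(meta, cols(100022, [(0, 0)], [raw]), {})
        assert removal is None
        assert derived[0].data_type is DataType.ORDERED
        assert derived[0].values.nunique() == 3

    def test_cat_single_two_values_becomes_binary(self):
        raw = np.array([0.0, 1.0] * 30)
        coding = DataCoding(9, is_ordinal=False)
        meta = FieldMetadata(55, FieldType.CAT_SINGLE, data_code_id=9)
        derived, _ = process_field(meta, cols(55, [(0, 0)], [raw]), {9: coding})
        assert derived[0].data_type is DataType.BINARY

    def test_cat_single_without_coding_raises(self):
        meta = FieldMetadata(55, FieldType.CAT_SINGLE, data_code_id=None)
        with pytest.raises(MissingDataCode):
            process_field(meta, cols(55, [(0, 0)], [np.arange(5.0)]), {})

    def test_plain_continuous_gets_rank_normalised(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=300)
        meta = FieldMetadata(21001, FieldType.CONTINUOUS)
        derived, _ = process_field(meta, cols(21001, [(0, 0)], [raw]), {})
        v = derived[0]
        assert v.data_type is DataType.CONTINUOUS
        assert "irnt" in v.provenance
        assert abs(v.values.mean()) < 0.2

    def test_constant_field_removed_not_errored(self):
        meta = FieldMetadata(77, FieldType.CONTINUOUS)
        derived, removal = process_field(
            meta, cols(77, [(0, 0)], [np.full(50, 3.0)]), {}
        )
        assert derived == [] and removal == "single_value"

    def test_determinism_same_seed_identical_output(self):
        rng = np.random.default_rng(3)
        raw = rng.choice([0.0, 1.0, 2.0], size=200)  # ties everywhere
        meta = FieldMetadata(88, FieldType.CONTINUOUS)
        config = ProcessingConfig(seed=99, dominance_threshold=0.99)
        d1, _ = process_field(meta, cols(88, [(0, 0)], [raw]), {}, config)
        d2, _ = process_field(meta, cols(88, [(0, 0)], [raw]), {}, config)
        pd.testing.assert_series_equal(d1[0].values, d2[0].values)
        d3, _ = process_field(
            meta, cols(88, [(0, 0)], [raw]), {}, ProcessingConfig(seed=7, dominance_threshold=0.99)
        )
        assert not d1[0].values.equals(d3[0].values)
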