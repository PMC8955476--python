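"""Dataset I/O, unit conversion, descriptor filtering and splitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarmlr import (
    DatasetError,
    FilterPolicy,
    SplitAssignment,
    convert_ic50_to_pic50,
    filter_descriptors,
    load_dataset,
    save_dataset,
    split_train_test,
)
from qsarmlr import data as fixtures
from qsarmlr.synthetic import SyntheticSpec, generate_dataset

from conftest import make_dataset


class TestLoad:
    def test_packaged_dataset_dedupes_reprinted_rows(self, table3):
        # the source table prints each of the 26 rows twice
        assert len(fixtures.load_table3(dedupe=False)) == 52
        assert len(table3) == 26
        assert table3.descriptor_names == fixtures.DESCRIPTORS
        assert table3.has_activity

    def test_designed_compounds_have_no_activity(self, table5):
        assert len(table5) == 12
        assert not any(r.activity is not None for r in table5.records)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(DatasetError, match="empty"):
            load_dataset(p)

    def test_header_only_file_loads_as_empty_dataset(self, tmp_path):
        p = tmp_path / "header.csv"
        p.write_text("id,a,b\n")
        ds = load_dataset(p, id_column="id")
        assert len(ds) == 0 and ds.descriptor_names == ["a", "b"]

    def test_non_numeric_cell_reports_row_and_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,a\nc1,1.0\nc2,oops\n")
        with pytest.raises(DatasetError, match=r"row 3.*'a'"):
            load_dataset(p, id_column="id")

    def test_duplicate_ids_rejected_without_dedupe(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("id,a\nc1,1.0\nc1,2.0\n")
        with pytest.raises(DatasetError, match="duplicate compound id"):
            load_dataset(p, id_column="id")

    def test_tab_separated_accepted(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("id\ta\tb\nc1\t1.5\t2.5\n")
        ds = load_dataset(p, id_column="id")
        assert ds.records[0].descriptors == {"a": 1.5, "b": 2.5}

    def test_save_load_roundtrip_is_lossless(self, tmp_path, rng):
        ds, _ = generate_dataset(SyntheticSpec(n=15, pool_size=3,
                                               coefficients={"D01": 1.0}, seed=3))
        p = tmp_path / "rt.csv"
        save_dataset(ds, p)
        back = load_dataset(p, id_column="compound_id", activity_column="activity")
        assert back.ids == ds.ids
        np.testing.assert_array_equal(back.activity_vector(), ds.activity_vector())
        np.testing.assert_array_equal(back.descriptor_matrix(), ds.descriptor_matrix())


class TestUnitConversion:
    @pytest.mark.parametrize(
        "ic50,unit,expected,tol",
        [
            (1.55, "uM", 5.8097, 5e-4),  # the worked example of the modelled series
            (1.0, "uM", 6.0, 1e-12),
            (1000.0, "uM", 3.0, 1e-12),
            (1.0, "nM", 9.0, 1e-12),
            (1.0, "M", 0.0, 1e-12),
        ],
    )
    def test_known_conversions(self, ic50, unit, expected, tol):
        assert convert_ic50_to_pic50(ic50, unit) == pytest.approx(expected, abs=tol)

    def test_rejects_non_positive_and_unknown_unit(self):
        with pytest.raises(DatasetError):
            convert_ic50_to_pic50(0.0, "uM")
        with pytest.raises(DatasetError):
            convert_ic50_to_pic50(-1.0, "uM")
        with pytest.raises(DatasetError):
            convert_ic50_to_pic50(1.0, "furlong")


class TestFiltering:
    def test_all_zero_column_dropped_with_reason(self, rng):
        X = np.column_stack([rng.normal(size=10), np.zeros(10)])
        ds = make_dataset(X, names=["good", "zeros"])
        out, log = filter_descriptors(ds)
        assert out.descriptor_names == ["good"]
        assert log == [{"name": "zeros", "reason": "zero", "detail": "all values zero"}]

    def test_identical_columns_lose_exactly_one(self, rng):
        a = rng.normal(size=12)
        ds = make_dataset(np.column_stack([a, a]), names=["a1", "a2"])
        out, log = filter_descriptors(ds)
        assert len(out.descriptor_names) == 1
        assert log[0]["reason"] == "correlated"

    def test_only_the_high_correlation_pair_loses_a_member(self, rng):
        # one pair at rho = 0.95; all other pairings near zero
        n = 400
        z = rng.normal(size=n)
        x1 = z
        x2 = 0.95 * z + math.sqrt(1 - 0.95**2) * rng.normal(size=n)
        x3, x4 = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack([x1, x2, x3, x4])
        C = np.corrcoef(X, rowvar=False)  # brute-force oracle
        assert abs(C[0, 1]) > 0.85
        assert all(abs(C[i, j]) < 0.85 for i, j in [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
        ds = make_dataset(X, names=["x1", "x2", "x3", "x4"])
        out, log = filter_descriptors(ds)
        assert {e["name"] for e in log} <= {"x1", "x2"} and len(log) == 1
        assert set(out.descriptor_names) >= {"x3", "x4"}

    def test_tie_break_keeps_descriptor_more_correlated_with_activity(self, rng):
        n = 200
        z = rng.normal(size=n)
        noisy = z + 0.4 * rng.normal(size=n)  # corr(z, noisy) ~ 0.93 > cutoff
        y = z  # activity is exactly the clean copy
        ds = make_dataset(np.column_stack([noisy, z]), y=y, names=["noisy", "clean"])
        out, log = filter_descriptors(ds)
        assert out.descriptor_names == ["clean"]

    def test_constant_majority_column_dropped(self, rng):
        col = np.array([7.0] * 8 + [1.0, 2.0])  # modal frequency 0.8 > 0.5
        ds = make_dataset(np.column_stack([rng.normal(size=10), col]),
                          names=["good", "mostly7"])
        out, log = filter_descriptors(ds)
        assert out.descriptor_names == ["good"]
        assert log[0]["reason"] == "constant"

    def test_missing_values_drop_column(self, tmp_path):
        p = tmp_path / "na.csv"
        p.write_text("id,a,b\nc1,1.0,\nc2,2.0,3.0\nc3,3.5,NA\n")
        ds = load_dataset(p, id_column="id")
        out, log = filter_descriptors(ds)
        assert out.descriptor_names == ["a"]
        assert log[0]["reason"] == "missing"

    def test_filtering_is_idempotent(self, rng):
        X = rng.normal(size=(30, 6))
        X[:, 3] = X[:, 0] * 0.99 + 0.01 * rng.normal(size=30)
        X[:, 5] = 0.0
        ds = make_dataset(X)
        once, log1 = filter_descriptors(ds)
        twice, log2 = filter_descriptors(once)
        assert log1 and not log2
        assert twice.descriptor_names == once.descriptor_names

    def test_all_removed_is_an_error(self):
        ds = make_dataset(np.zeros((5, 2)))
        with pytest.raises(DatasetError, match="all descriptors removed"):
            filter_descriptors(ds)


class TestSplit:
    def test_rounding_rule(self, rng):
        for n, expected_test in [(24, 4), (26, 4)]:
            ds = make_dataset(rng.normal(size=(n, 2)), y=rng.normal(size=n))
            out = split_train_test(ds, SplitAssignment(seed=1))
            assert len(out.test_set()) == expected_test
            assert len(out.training_set()) == n - expected_test

    def test_same_seed_identical_assignment(self, table3):
        a = split_train_test(table3, SplitAssignment(seed=11))
        b = split_train_test(table3, SplitAssignment(seed=11))
        assert [r.set_label for r in a.records] == [r.set_label for r in b.records]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_split_disjoint_and_exhaustive_for_every_seed(self, seed):
        rng = np.random.default_rng(99)
        ds = make_dataset(rng.normal(size=(26, 3)), y=rng.normal(size=26))
        out = split_train_test(ds, SplitAssignment(seed=seed))
        train_ids = set(out.training_set().ids)
        test_ids = set(out.test_set().ids)
        assert train_ids.isdisjoint(test_ids)
        assert train_ids | test_ids == set(ds.ids)

    def test_activity_ranked_takes_every_sixth_of_sorted_order(self, rng):
        y = np.arange(24, dtype=float)
        ds = make_dataset(rng.normal(size=(24, 2)), y=y)
        out = split_train_test(ds, SplitAssignment(method="activity_ranked"))
        test_y = sorted(r.activity for r in out.test_set().records)
        assert test_y == [5.0, 11.0, 17.0, 23.0]

    def test_explicit_membership_lists_override(self, table3):
        test_ids = ("1", "5", "9", "13", "17", "21")
        out = split_train_test(table3, SplitAssignment(test_ids=test_ids))
        assert set(out.test_set().ids) == set(test_ids)
        assert len(out.training_set()) == 20

    def test_too_small_dataset_is_an_error(self, rng):
        ds = make_dataset(rng.normal(size=(2, 1)), y=rng.normal(size=2))
        with pytest.raises(DatasetError, match="too small"):
            split_train_test(ds, SplitAssignment(ratio=5.0))
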