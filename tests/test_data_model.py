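"""Descriptor-table IO and logRBA consensus labelling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfqsar import (
    ActivityRecord,
    BINDER,
    EXCLUDED,
    NON_BINDER,
    DescriptorTable,
    LabeledDataset,
    assemble_dataset,
    generate_dataset,
    label_compound,
    read_descriptor_table,
    write_descriptor_table,
)
from dfqsar.synthetic import SynthConfig


class TestDescriptorTableIO:
    def test_round_trip_preserves_table(self, toy_table, tmp_path):
        path = tmp_path / "t.csv"
        write_descriptor_table(toy_table, path)
        back = read_descriptor_table(path)
        assert back.compound_ids == toy_table.compound_ids
        assert back.descriptor_names == toy_table.descriptor_names
        np.testing.assert_allclose(back.values, toy_table.values, rtol=1e-9)

    def test_small_csv_parses_shape_and_order(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("compound_id,a,b\nC3,1,2\nC1,3,4\nC2,5,6\n")
        t = read_descriptor_table(path)
        assert t.compound_ids == ["C3", "C1", "C2"]  # file row order kept
        assert t.descriptor_names == ["a", "b"]
        assert t.values[0, 1] == 2.0

    def test_duplicate_id_is_named_in_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("compound_id,a\nC1,1\nC1,2\n")
        with pytest.raises(ValueError, match="C1"):
            read_descriptor_table(path)

    def test_missing_cell_error_names_row_and_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("compound_id,a,b\nC1,1,2\nC2,NA,4\n")
        with pytest.raises(ValueError, match="C2") as err:
            read_descriptor_table(path)
        assert "'a'" in str(err.value)

    def test_table_rejects_nonfinite_values(self):
        with pytest.raises(ValueError, match="non-finite"):
            DescriptorTable(["C1"], ["a"], np.array([[np.nan]]))


class TestLabelCompound:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([-5.0], BINDER),            # threshold is inclusive
            ([-5.0001], NON_BINDER),
            ([-4.0, -6.0, -4.5], BINDER),  # 2-of-3 majority
            ([-4.0, -6.0], EXCLUDED),      # exact tie
            ([-7.0], NON_BINDER),
            ([-6.0, -6.5, -4.0], NON_BINDER),
        ],
    )
    def test_consensus_rule(self, values, expected):
        assert label_compound(ActivityRecord("X", values)) == expected

    def test_empty_value_list_rejected(self):
        with pytest.raises(ValueError):
            ActivityRecord("X", [])

    @given(
        values=st.lists(st.floats(-10, 0, allow_nan=False), min_size=1, max_size=5),
        bump=st.integers(0, 4),
        delta=st.floats(0.0, 5.0, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_raising_a_value_never_flips_binder_to_nonbinder(self, values, bump, delta):
        before = label_compound(ActivityRecord("X", values))
        raised = list(values)
        raised[bump % len(values)] += delta
        after = label_compound(ActivityRecord("X", raised))
        if before == BINDER:
            assert after == BINDER


class TestAssembleDataset:
    def _table(self, ids):
        rng = np.random.default_rng(0)
        return DescriptorTable(ids, ["a", "b"], rng.normal(size=(len(ids), 2)))

    def test_counts_and_exclusions(self):
        table = self._table([f"C{i}" for i in range(5)])
        records = [
            ActivityRecord("C0", [-4.0]),
            ActivityRecord("C1", [-4.5]),
            ActivityRecord("C2", [-3.0]),
            ActivityRecord("C3", [-6.0]),
            ActivityRecord("C4", [-4.0, -6.0]),  # tie -> excluded
        ]
        ds = assemble_dataset(table, records)
        assert ds.table.n_compounds == 4
        assert (ds.n_binders, ds.n_nonbinders) == (3, 1)

    def test_row_alignment_preserved(self):
        table = self._table(["C0", "C1", "C2"])
        records = [ActivityRecord("C2", [-4.0]), ActivityRecord("C0", [-6.0])]
        ds = assemble_dataset(table, records)
        assert ds.table.compound_ids == ["C2", "C0"]
        np.testing.assert_array_equal(ds.table.values[0], table.values[2])
        np.testing.assert_array_equal(ds.table.values[1], table.values[0])

    def test_unknown_compound_is_hard_error(self):
        with pytest.raises(KeyError, match="C9"):
            assemble_dataset(self._table(["C0"]), [ActivityRecord("C9", [-4.0])])

    def test_all_excluded_is_hard_error(self):
        table = self._table(["C0"])
        with pytest.raises(ValueError):
            assemble_dataset(table, [ActivityRecord("C0", [-4.0, -6.0])])

    def test_generator_reproduces_study_class_counts(self):
        ds, _ = generate_dataset(SynthConfig(seed=3))
        assert (ds.n_binders, ds.n_nonbinders) == (2462, 30)
        assert ds.table.n_descriptors == 447

    def test_labeled_dataset_rejects_misaligned_labels(self, toy_table):
        with pytest.raises(ValueError):
            LabeledDataset(toy_table, np.zeros(3))
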