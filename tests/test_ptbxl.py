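"""Metadata parsing, label aggregation, record filters and fold splits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cardiolead.ptbxl import (
    CLASS_NAMES,
    ECGRecord,
    LabelMap,
    RawRecordMeta,
    aggregate_labels,
    assign_splits,
    filter_records,
    load_dataset,
    load_metadata,
)
from cardiolead.synthetic import SynthConfig, export_wfdb_dataset, generate_dataset

IDENTITY = LabelMap.identity()


def _meta(rid, scp, fold=1):
    return RawRecordMeta(
        record_id=rid,
        scp_codes=scp,
        strat_fold=fold,
        signal_path_100=f"records100/{rid:05d}_lr",
        signal_path_500=f"records500/{rid:05d}_hr",
    )


def _write_metadata_csv(path, rows):
    pd.DataFrame(
        rows,
        columns=["ecg_id", "scp_codes", "strat_fold", "filename_lr", "filename_hr"],
    ).to_csv(path / "ptbxl_database.csv", index=False)


class TestLoadMetadata:
    def test_toy_csv_parses_likelihoods(self, tmp_path):
        _write_metadata_csv(
            tmp_path,
            [
                {"ecg_id": 1, "scp_codes": "{'NORM': 100.0}", "strat_fold": 1,
                 "filename_lr": "a", "filename_hr": "b"},
                {"ecg_id": 2, "scp_codes": "{'IMI': 80.0, 'SR': 0.0}",
                 "strat_fold": 9, "filename_lr": "c", "filename_hr": "d"},
                {"ecg_id": 3, "scp_codes": "{'LVH': 50.0}", "strat_fold": 10,
                 "filename_lr": "e", "filename_hr": "f"},
            ],
        )
        metas = load_metadata(tmp_path)
        assert [m.record_id for m in metas] == [1, 2, 3]
        assert metas[1].scp_codes == {"IMI": 80.0, "SR": 0.0}
        assert metas[1].strat_fold == 9

    def test_empty_csv_gives_empty_list(self, tmp_path):
        _write_metadata_csv(tmp_path, [])
        assert load_metadata(tmp_path) == []

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_metadata(tmp_path / "nowhere")

    def test_malformed_scp_cell_names_the_record(self, tmp_path):
        _write_metadata_csv(
            tmp_path,
            [{"ecg_id": 7, "scp_codes": "not a dict{{", "strat_fold": 1,
              "filename_lr": "a", "filename_hr": "b"}],
        )
        with pytest.raises(ValueError, match="7"):
            load_metadata(tmp_path)


class TestAggregateLabels:
    @pytest.mark.parametrize(
        "scp, positives, flag",
        [
            ({"IMI": 80.0, "SR": 0.0}, {"IMI"}, False),   # SR is unmapped rhythm
            ({"NORM": 100.0}, {"NORM"}, False),
            ({"AMI": 0.0, "LVH": 50.0}, {"LVH"}, True),
        ],
    )
    def test_rule_applied_literally(self, scp, positives, flag):
        labels, had_zero = aggregate_labels(_meta(1, scp), IDENTITY)
        assert {CLASS_NAMES[i] for i in np.flatnonzero(labels)} == positives
        assert had_zero is flag

    def test_unknown_codes_silently_ignored(self):
        labels, flag = aggregate_labels(
            _meta(1, {"UNKNOWNCODE": 90.0, "NORM": 100.0}), IDENTITY
        )
        assert labels.sum() == 1 and not flag


class TestFilterRecords:
    def test_toy_set_audit(self):
        def item(rid, positives, flag=False):
            labels = np.zeros(20, dtype=np.int8)
            for name in positives:
                labels[CLASS_NAMES.index(name)] = 1
            return (_meta(rid, {}), labels, flag)

        items = [
            item(1, ["NORM", "IMI"]),          # conflicting
            item(2, []),                       # unlabeled
            item(3, ["LVH"], flag=True),       # zero-likelihood statement
            item(4, ["NORM"]),                 # clean
            item(5, ["CLBBB"]),                # clean
        ]
        survivors, audit = filter_records(items)
        assert [it[0].record_id for it in survivors] == [4, 5]
        assert (audit.n_conflicting, audit.n_unlabeled, audit.n_zero_likelihood) == (
            1, 1, 1,
        )
        assert audit.n_removed == len(items) - len(survivors)

    def test_clean_input_is_identity(self):
        labels = np.zeros(20, dtype=np.int8)
        labels[CLASS_NAMES.index("LMI")] = 1
        items = [(_meta(i, {}), labels, False) for i in range(4)]
        survivors, audit = filter_records(items)
        assert survivors == items and audit.n_removed == 0


class TestAssignSplits:
    def test_one_record_per_fold(self):
        metas = [_meta(i, {"NORM": 100.0}, fold=i) for i in range(1, 11)]
        split = assign_splits(metas)
        assert (len(split.train), len(split.validation), len(split.test)) == (8, 1, 1)
        assert split.validation[0].strat_fold == 9
        assert split.test[0].strat_fold == 10

    def test_empty_input(self):
        split = assign_splits([])
        assert (split.train, split.validation, split.test) == ([], [], [])

    def test_partition_property(self, rng):
        metas = [
            _meta(i, {"NORM": 100.0}, fold=int(rng.integers(1, 11)))
            for i in range(200)
        ]
        split = assign_splits(metas)
        ids = [m.record_id for part in split for m in part]
        assert sorted(ids) == sorted(m.record_id for m in metas)

    def test_bad_fold_rejected(self):
        rec = ECGRecord(1, np.zeros((12, 10)), 100,
                        np.eye(20, dtype=np.int8)[0], fold=11)
        with pytest.raises(ValueError, match="fold"):
            assign_splits([rec])


class TestWfdbRoundTrip:
    def test_export_then_load_preserves_labels_and_folds(self, tmp_path, small_dataset):
        records, manifest = small_dataset
        root = export_wfdb_dataset(records, manifest, tmp_path / "synthds")
        loaded, audit = load_dataset(root, fs=500)
        assert audit.n_removed == 0
        assert len(loaded) == len(records)
        by_id = {r.record_id: r for r in records}
        for rec in loaded:
            orig = by_id[rec.record_id]
            assert rec.fold == orig.fold
            np.testing.assert_array_equal(rec.labels, orig.labels)
            assert rec.signal.shape == (12, 5000)
            # format-16 quantization at 1000 units/mV
            np.testing.assert_allclose(rec.signal, orig.signal, atol=5.1e-4)

    def test_100hz_files_have_1000_samples(self, tmp_path, small_dataset):
        records, manifest = small_dataset
        root = export_wfdb_dataset(records[:3], manifest.iloc[:3],
                                   tmp_path / "ds100")
        loaded, _ = load_dataset(root, fs=100)
        assert all(r.signal.shape == (12, 1000) for r in loaded)


class TestLabelMapFromScpStatements:
    def test_restricted_to_the_20_subclasses(self, tmp_path):
        df = pd.DataFrame(
            {
                "code": ["NORM", "IMI", "PMI", "SR", "ILMI"],
                "diagnostic": [1, 1, 1, 0, 1],
                "diagnostic_class": ["NORM", "MI", "MI", "", "MI"],
                "diagnostic_subclass": ["NORM", "IMI", "PMI", "", "IMI"],
            }
        ).set_index("code")
        path = tmp_path / "scp_statements.csv"
        df.to_csv(path)
        lm = LabelMap.from_scp_statements(path)
        assert lm.code_to_class == {"NORM": "NORM", "IMI": "IMI", "ILMI": "IMI"}

    def test_targets_outside_class_list_rejected(self):
        with pytest.raises(ValueError):
            LabelMap(code_to_class={"XX": "NOTACLASS"})
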