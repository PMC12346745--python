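"""Corpus reading: WFDB records, metadata tables, label mapping, splits."""

import numpy as np
import pandas as pd
import pytest

import ecgfusion as ef
from ecgfusion.records import assign_split
from ecgfusion.synth import SynthesisConfig, disjoint_lead_spec
from ecgfusion.taxonomy import SUBCLASSES, superclass_of
from ecgfusion.wfdb_io import WFDBFormatError, read_wfdb, write_wfdb


def _fixture_dir(tmp_path, fs=100, n=5, seed=0):
    config = SynthesisConfig(
        n_records=n, class_spec=disjoint_lead_spec(["NORM", "IMI"]),
        fs=fs, seed=seed,
    )
    corpus = ef.generate_corpus(config)
    ef.write_wfdb_fixture(corpus, str(tmp_path))
    return corpus


@pytest.mark.parametrize("fs,expected", [(100, 1000), (500, 5000)])
def test_read_record_shape_matches_sampling_rate(tmp_path, fs, expected):
    corpus = _fixture_dir(tmp_path, fs=fs)
    sub = "records100" if fs == 100 else "records500"
    rec = ef.read_record(str(tmp_path / sub / corpus.records[0].record_id), fs=fs)
    assert rec.signal.shape == (expected, 12)
    assert rec.fs == fs


def test_read_record_rejects_wrong_channel_count(tmp_path):
    sig = np.zeros((1000, 3))
    write_wfdb(str(tmp_path / "bad"), sig, 100, ["a", "b", "c"])
    with pytest.raises(WFDBFormatError):
        ef.read_record(str(tmp_path / "bad"), fs=100)


def test_read_record_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        ef.read_record(str(tmp_path / "nope"), fs=100)


def test_read_record_truncated_signal(tmp_path):
    sig = np.zeros((1000, 12))
    write_wfdb(str(tmp_path / "t"), sig, 100, [f"c{i}" for i in range(12)])
    dat = tmp_path / "t.dat"
    dat.write_bytes(dat.read_bytes()[:-100])
    with pytest.raises(WFDBFormatError):
        ef.read_record(str(tmp_path / "t"), fs=100)


def test_wfdb_roundtrip_within_quantization(tmp_path):
    rng = np.random.default_rng(0)
    sig = rng.normal(0, 0.5, size=(1000, 12))
    write_wfdb(str(tmp_path / "r"), sig, 100, [f"c{i}" for i in range(12)])
    back, fs, names = read_wfdb(str(tmp_path / "r"))
    assert fs == 100
    assert np.abs(back - sig).max() <= 0.5 / 1000  # half an ADU at gain 1000


def test_load_metadata_parses_all_valid_rows(tmp_path):
    _fixture_dir(tmp_path, n=20)
    meta, tax = ef.load_metadata(
        str(tmp_path / "ptbxl_database.csv"),
        str(tmp_path / "scp_statements.csv"),
    )
    assert len(meta) == 20
    assert all(isinstance(v, dict) for v in meta["scp_codes"])


def test_load_metadata_drops_malformed_scp_codes(tmp_path, caplog):
    _fixture_dir(tmp_path, n=20)
    db = tmp_path / "ptbxl_database.csv"
    frame = pd.read_csv(db, index_col=0)
    frame.iloc[0, frame.columns.get_loc("scp_codes")] = "not-a-dict{"
    frame.to_csv(db)
    with caplog.at_level("WARNING"):
        meta, _ = ef.load_metadata(str(db), str(tmp_path / "scp_statements.csv"))
    assert len(meta) == 19
    assert "dropped 1" in caplog.text


def test_load_metadata_requires_diagnostic_class_column(tmp_path):
    _fixture_dir(tmp_path)
    scp = tmp_path / "scp_statements.csv"
    frame = pd.read_csv(scp, index_col=0).drop(columns=["diagnostic_class"])
    frame.to_csv(scp)
    with pytest.raises(ValueError, match="diagnostic_class"):
        ef.load_metadata(str(tmp_path / "ptbxl_database.csv"), str(scp))


class TestMapScpToLabel:
    def test_single_code_maps_through_taxonomy(self, taxonomy_df):
        label = ef.map_scp_to_label({"IMI": 100.0}, taxonomy_df)
        assert label == ef.DiagnosticLabel("MI", "IMI")
        assert ef.map_scp_to_label({"NORM": 100.0}, taxonomy_df) == (
            ef.DiagnosticLabel("NORM", "NORM")
        )

    def test_empty_codes_are_unlabeled(self, taxonomy_df):
        assert ef.map_scp_to_label({}, taxonomy_df) == "unlabeled"

    def test_two_superclasses_are_ambiguous(self, taxonomy_df):
        result = ef.map_scp_to_label(
            {"IMI": 100.0, "CLBBB": 100.0}, taxonomy_df
        )
        assert result == "ambiguous"

    def test_low_likelihood_codes_are_ignored(self, taxonomy_df):
        result = ef.map_scp_to_label(
            {"IMI": 100.0, "CLBBB": 50.0}, taxonomy_df, min_likelihood=100.0
        )
        assert result == ef.DiagnosticLabel("MI", "IMI")

    def test_unknown_codes_are_ignored(self, taxonomy_df):
        result = ef.map_scp_to_label(
            {"SR": 100.0, "IMI": 100.0}, taxonomy_df  # SR = sinus rhythm
        )
        assert result == ef.DiagnosticLabel("MI", "IMI")

    def test_taxonomy_closure(self, taxonomy_df):
        """Every emitted subclass sits under its emitted superclass."""
        for code in SUBCLASSES:
            label = ef.map_scp_to_label({code: 100.0}, taxonomy_df)
            assert isinstance(label, ef.DiagnosticLabel)
            if label.subclass is not None:
                assert superclass_of(label.subclass) == label.superclass


class TestAssignSplit:
    @pytest.mark.parametrize(
        "fold,expected",
        [(1, "train"), (3, "train"), (8, "train"),
         (9, "validation"), (10, "test")],
    )
    def test_fold_mapping(self, fold, expected):
        assert assign_split(fold) == expected

    @pytest.mark.parametrize("fold", [0, 11, -1])
    def test_out_of_range_fold(self, fold):
        with pytest.raises(ValueError):
            assign_split(fold)


def test_corpus_partitions_disjoint_and_exhaustive(fiveclass_corpus):
    ids = {p: set() for p in ("train", "validation", "test")}
    for rec, _ in fiveclass_corpus:
        ids[assign_split(rec.fold)].add(rec.record_id)
    assert ids["train"] | ids["validation"] | ids["test"] == {
        r.record_id for r, _ in fiveclass_corpus
    }
    assert not ids["train"] & ids["validation"]
    assert not ids["train"] & ids["test"]
    assert not ids["validation"] & ids["test"]


def test_load_corpus_merges_demographics(tmp_path):
    corpus = _fixture_dir(tmp_path, n=6)
    pairs = ef.load_corpus(str(tmp_path))
    assert len(pairs) == 6
    for (rec, label), orig in zip(pairs, corpus.records):
        assert rec.record_id == orig.record_id
        assert rec.fold == orig.fold
        assert rec.sex == orig.sex
        assert rec.scp_codes == orig.scp_codes
        assert rec.age == pytest.approx(orig.age)
        assert isinstance(label, ef.DiagnosticLabel)
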