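"""Core data model and serialization behaviour."""

import json
import os

import numpy as np
import pytest

import mzpipe as mp
from mzpipe.io import ASARI_DIALECT, TableDialect
from mzpipe.models import AnnotationRecord, EmpiricalCompound, IonRelation, MS2Spectrum

from conftest import make_table


# ---------------------------------------------------------------------------
# metadata -> Experiment
# ---------------------------------------------------------------------------

class TestLoadMetadata:
    def test_minimal_csv_gives_unknown_sample_types(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("name,path\ns1,a.mzML\ns2,b.mzML\ns3,c.mzML\n")
        exp = mp.load_metadata(str(p))
        assert [a.name for a in exp.acquisitions] == ["s1", "s2", "s3"]
        assert all(a.sample_type == "unknown" for a in exp.acquisitions)
        assert exp.table_registry == {} and exp.empcpd_registry == {}
        assert len(exp.command_log) == 1

    def test_duplicate_sample_names_rejected_by_name(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("name,path\ns1,a.mzML\ns1,b.mzML\n")
        with pytest.raises(ValueError, match="s1"):
            mp.load_metadata(str(p))

    def test_missing_required_columns_lists_expected(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text("sample_id,location\ns1,a.mzML\n")
        with pytest.raises(ValueError, match="sample-name column"):
            mp.load_metadata(str(p))

    def test_sample_type_and_batch_round_trip(self, tmp_path):
        p = tmp_path / "meta.csv"
        p.write_text(
            "name,path,sample_type,batch\n"
            "s1,a.mzML,study,b1\ns2,b.mzML,blank,b1\ns3,c.mzML,pool_qc,b2\n"
        )
        exp = mp.load_metadata(str(p), directory=str(tmp_path / "exp"))
        assert [a.sample_type for a in exp.acquisitions] == ["study", "blank", "pool_qc"]
        assert exp.batches() == {"s1": "b1", "s2": "b1", "s3": "b2"}
        exp.save()
        reloaded = mp.Experiment.load(exp.directory)
        assert [a.to_dict() for a in reloaded.acquisitions] == [
            a.to_dict() for a in exp.acquisitions
        ]


# ---------------------------------------------------------------------------
# feature-table TSV
# ---------------------------------------------------------------------------

class TestFeatureTableIO:
    def test_read_basic(self, tmp_path):
        p = tmp_path / "ft.tsv"
        p.write_text(
            "id_number\tmz\trtime\tsA\tsB\tsC\n"
            "F1\t100.5\t60.0\t10\t0\t30\n"
            "F2\t200.25\t120.0\t5\t6\t7\n"
        )
        t = mp.read_feature_table(str(p))
        assert t.n_features == 2 and t.sample_columns == ["sA", "sB", "sC"]
        assert t.frame.loc["F1", "sB"] == 0.0
        assert t.frame.loc["F2", "mz"] == 200.25

    def test_round_trip_identity(self, tmp_path, basic_bundle):
        t = basic_bundle.table
        path = tmp_path / "rt.tsv"
        mp.write_feature_table(t, str(path))
        back = mp.read_feature_table(str(path), moniker=t.moniker)
        assert back.equals(t)

    def test_zero_intensity_written_as_zero_not_blank(self, tmp_path):
        t = make_table([100.0], [10.0], np.array([[0.0, 5.5]]))
        path = tmp_path / "z.tsv"
        mp.write_feature_table(t, str(path))
        row = path.read_text().splitlines()[1].split("\t")
        assert row[3] == "0" and row[4] == "5.5"

    def test_non_numeric_mz_names_offending_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id_number\tmz\trtime\tsA\nF1\tabc\t60\t10\n")
        with pytest.raises(ValueError, match="F1"):
            mp.read_feature_table(str(p))

    def test_unparseable_intensity_is_an_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id_number\tmz\trtime\tsA\nF1\t100.0\t60\tNOPE\n")
        with pytest.raises(ValueError, match="sA"):
            mp.read_feature_table(str(p))

    def test_missing_required_column_is_an_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id_number\tmass\trtime\tsA\nF1\t100.0\t60\t1\n")
        with pytest.raises(ValueError, match="mz"):
            mp.read_feature_table(str(p))

    def test_empty_table_writes_header_only(self, tmp_path):
        import pandas as pd

        frame = pd.DataFrame(columns=["mz", "rtime", "sA"]).astype(float)
        frame.index.name = "feature_id"
        t = mp.FeatureTable("empty", frame, ["sA"])
        path = tmp_path / "empty.tsv"
        mp.write_feature_table(t, str(path))
        lines = path.read_text().splitlines()
        assert lines == ["id_number\tmz\trtime\tsA"]
        assert mp.read_feature_table(str(path)).n_features == 0

    def test_minutes_dialect_converts_to_seconds(self, tmp_path):
        p = tmp_path / "ft.tsv"
        p.write_text("id\tm/z\tRT\ts1\nF1\t100.0\t2.0\t10\n")
        dialect = TableDialect(id_col="id", mz_col="m/z", rtime_col="RT", rtime_unit="min")
        t = mp.read_feature_table(str(p), dialect=dialect)
        assert t.frame.loc["F1", "rtime"] == 120.0

    def test_extra_columns_preserved_opaquely(self, tmp_path):
        p = tmp_path / "ft.tsv"
        p.write_text(
            "id_number\tmz\trtime\tcSelectivity\tsA\nF1\t100.0\t60\t0.9\t10\n"
        )
        dialect = TableDialect(extra_metadata_cols=("cSelectivity",))
        t = mp.read_feature_table(str(p), dialect=dialect)
        assert t.extra_columns == ["cSelectivity"]
        assert t.sample_columns == ["sA"]

    def test_random_tables_round_trip_bit_faithful(self, tmp_path):
        rng = np.random.default_rng(7)
        for k in range(100):
            n, m = int(rng.integers(1, 8)), int(rng.integers(1, 5))
            t = make_table(
                list(rng.uniform(50, 1000, n)),
                list(rng.uniform(0, 3000, n)),
                np.where(rng.random((n, m)) < 0.2, 0.0, rng.lognormal(10, 2, (n, m))),
            )
            path = tmp_path / f"t{k}.tsv"
            mp.write_feature_table(t, str(path))
            assert mp.read_feature_table(str(path), moniker="t").equals(t)


# ---------------------------------------------------------------------------
# empirical-compound JSON
# ---------------------------------------------------------------------------

def _random_empcpd(rng: np.random.Generator, k: int) -> EmpiricalCompound:
    n_members = int(rng.integers(1, 5))
    members = []
    for i in range(n_members):
        ion = None
        if rng.random() < 0.7:
            ion = IonRelation("M0", "M+H+", 1, float(rng.uniform(0.5, 25)))
        members.append((f"F{k}_{i}", ion))
    anns = [
        AnnotationRecord(
            level=str(rng.choice(["1a", "1b", "2", "4"])),
            candidate_name=f"cpd{int(rng.integers(100))}",
            score=float(rng.random()),
            source="db",
            evidence={"ppm_error": float(rng.normal())},
        )
        for _ in range(int(rng.integers(0, 3)))
    ]
    spectra = [
        MS2Spectrum(
            float(rng.uniform(100, 500)),
            float(rng.uniform(0, 600)),
            [(float(m), float(i)) for m, i in zip(
                np.sort(rng.uniform(50, 400, 4)), rng.uniform(1, 100, 4))],
            provenance="experimental",
        )
        for _ in range(int(rng.integers(0, 2)))
    ]
    return EmpiricalCompound(
        empcpd_id=f"E{k}",
        members=members,
        neutral_mass=float(rng.uniform(100, 800)) if rng.random() < 0.8 else None,
        ms2_spectra=spectra,
        annotations=anns,
    )


class TestEmpcpdJSON:
    def test_round_trip_identity_random_documents(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            empcpds = [_random_empcpd(rng, k) for k in range(int(rng.integers(1, 6)))]
            doc = mp.empcpds_to_json(empcpds)
            # through actual JSON text, as on disk
            back = mp.empcpds_from_json(json.loads(json.dumps(doc)))
            assert mp.empcpds_to_json(back) == doc

    def test_structure_preserved(self):
        rng = np.random.default_rng(1)
        e = EmpiricalCompound(
            empcpd_id="E1",
            members=[("F1", None), ("F2", None), ("F3", None)],
            annotations=[AnnotationRecord("4", "glucose", source="db")],
        )
        doc = mp.empcpds_to_json([e])
        entry = doc["empirical_compounds"]["E1"]
        assert len(entry["members"]) == 3
        assert len(entry["annotations"]) == 1

    def test_duplicate_ids_rejected(self):
        e1 = EmpiricalCompound("E1", [("F1", None)])
        e2 = EmpiricalCompound("E1", [("F2", None)])
        with pytest.raises(ValueError, match="E1"):
            mp.empcpds_to_json([e1, e2])

    def test_annotations_chain_across_sources(self):
        e = EmpiricalCompound("E1", [("F1", None)], neutral_mass=180.06339)
        db1 = [mp.CompoundRecord(name="glucose", neutral_mass=180.06339)]
        db2 = [mp.CompoundRecord(name="fructose", neutral_mass=180.06339)]
        mp.annotate_level4([e], db1, 5.0, source="db1")
        mp.annotate_level4([e], db2, 5.0, source="db2")
        assert len(e.annotations) == 2
        assert {a.source for a in e.annotations} == {"db1", "db2"}


# ---------------------------------------------------------------------------
# three-table output
# ---------------------------------------------------------------------------

class TestThreeTables:
    def _experiment(self, tmp_path):
        exp = mp.Experiment(
            str(tmp_path),
            [mp.Acquisition("s1", sample_type="study", batch="b1"),
             mp.Acquisition("s2", sample_type="blank", batch="b1")],
        )
        return exp

    def test_multiple_annotations_give_multiple_rows(self, tmp_path):
        t = make_table([100.0], [10.0], np.array([[1.0, 2.0]]))
        e = EmpiricalCompound(
            "E1", [("f1", None)],
            annotations=[
                AnnotationRecord("4", "glucose", source="db"),
                AnnotationRecord("4", "fructose", source="db"),
            ],
        )
        _, ann_path, _ = mp.emit_three_tables(self._experiment(tmp_path), t, [e],
                                              str(tmp_path / "out"))
        rows = open(ann_path).read().splitlines()
        assert len(rows) == 3  # header + 2
        assert all(r.startswith("f1\tE1\t4") for r in rows[1:])

    def test_no_annotations_emits_header_only_annotation_table(self, tmp_path):
        t = make_table([100.0], [10.0], np.array([[1.0, 2.0]]))
        e = EmpiricalCompound("E1", [("f1", None)])
        fpath, ann_path, mpath = mp.emit_three_tables(
            self._experiment(tmp_path), t, [e], str(tmp_path / "out"))
        assert len(open(ann_path).read().splitlines()) == 1
        assert os.path.exists(fpath) and os.path.exists(mpath)

    def test_dangling_feature_id_is_an_error(self, tmp_path):
        t = make_table([100.0], [10.0], np.array([[1.0, 2.0]]))
        e = EmpiricalCompound("E1", [("F999", None)])
        with pytest.raises(ValueError, match="F999"):
            mp.emit_three_tables(self._experiment(tmp_path), t, [e], str(tmp_path / "out"))

    def test_cross_reference_integrity(self, tmp_path, combined_bundle):
        import pandas as pd

        b = combined_bundle
        ecs = mp.build_empirical_compounds(b.table)
        mp.annotate_level4(ecs, b.compound_db, 5.0)
        fpath, ann_path, mpath = mp.emit_three_tables(
            b.experiment, b.table, ecs, str(tmp_path / "out"))
        feat = pd.read_csv(fpath, sep="\t")
        ann = pd.read_csv(ann_path, sep="\t")
        meta = pd.read_csv(mpath, sep="\t")
        assert set(ann["feature_id"]) <= set(feat["id_number"])
        acq = meta[meta["record_type"] == "acquisition"]
        assert set(acq["name"]) == {a.name for a in b.experiment.acquisitions}
        assert {"batch", "sample_type"} <= set(meta.columns)


# ---------------------------------------------------------------------------
# command log
# ---------------------------------------------------------------------------

class TestCommandLog:
    def test_log_grows_by_one(self, tmp_path):
        exp = mp.Experiment(str(tmp_path))
        assert len(exp.command_log) == 0
        exp.log_step("normalize", {"mode": "two_pass"})
        assert len(exp.command_log) == 1

    def test_chronological_append_only(self, tmp_path):
        exp = mp.Experiment(str(tmp_path))
        for i in range(3):
            exp.log_step(f"step{i}")
        stamps = [e["timestamp"] for e in exp.command_log]
        assert stamps == sorted(stamps)
        assert [e["command"] for e in exp.command_log] == ["step0", "step1", "step2"]

    def test_log_survives_persistence(self, tmp_path):
        exp = mp.Experiment(str(tmp_path))
        exp.log_step("a", {"x": 1})
        exp.log_step("b")
        exp.save()
        assert mp.Experiment.load(str(tmp_path)).command_log == exp.command_log


# ---------------------------------------------------------------------------
# mzML MS2 extraction
# ---------------------------------------------------------------------------

class TestExtractMS2:
    def _spectra(self, n=5):
        rng = np.random.default_rng(3)
        out = []
        for k in range(n):
            n_peaks = 4 + k
            mzs = np.sort(rng.uniform(50, 400, n_peaks))
            out.append(MS2Spectrum(
                precursor_mz=150.0 + 10 * k,
                precursor_rtime=30.0 * (k + 1),
                peaks=list(zip(mzs.tolist(), rng.uniform(1, 100, n_peaks).tolist())),
            ))
        return out

    def test_known_scans_recovered(self, tmp_path):
        from mzpipe.synthetic import write_mzml

        spectra = self._spectra(5)
        path = str(tmp_path / "five.mzML")
        write_mzml(spectra, path)
        got = mp.extract_ms2(path, min_peaks=2)
        assert len(got) == 5
        assert [s.precursor_mz for s in got] == [s.precursor_mz for s in spectra]
        assert [s.precursor_rtime for s in got] == [s.precursor_rtime for s in spectra]
        assert all(g.peaks == s.peaks for g, s in zip(got, spectra))

    def test_min_peaks_filter(self, tmp_path):
        from mzpipe.synthetic import write_mzml

        spectra = self._spectra(4)
        spectra.append(MS2Spectrum(500.0, 10.0, [(100.0, 1.0), (200.0, 2.0)]))
        path = str(tmp_path / "mixed.mzML")
        write_mzml(spectra, path)
        assert len(mp.extract_ms2(path, min_peaks=3)) == 4

    def test_ms1_only_file_gives_empty_list(self, tmp_path):
        from mzpipe.synthetic import write_mzml

        path = str(tmp_path / "ms1.mzML")
        write_mzml([], path, ms1_scans=4)
        assert mp.extract_ms2(path) == []

    def test_unreadable_file_is_an_error(self, tmp_path):
        path = tmp_path / "junk.mzML"
        path.write_text("this is not xml <<<")
        with pytest.raises(ValueError, match="cannot read"):
            mp.extract_ms2(str(path))
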