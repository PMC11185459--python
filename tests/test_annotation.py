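"""Level 4 / 1b / 2 / 1a annotation, precursor indexing and MS2 scoring."""

import numpy as np
import pytest

import mzpipe as mp
from mzpipe.annotation import (
    PrecursorIndex,
    annotate_level1b,
    annotate_level4,
    annotate_ms2,
    cosine_score,
    linear_scan_query,
    map_annotations_to_features,
    map_ms2_to_empcpds,
)
from mzpipe.models import AnnotationRecord, CompoundRecord, EmpiricalCompound, MS2Spectrum, StandardRecord

from conftest import make_table


def _empcpd(mass=None, members=(("f1", None),), eid="E1"):
    return EmpiricalCompound(eid, list(members), neutral_mass=mass)


class TestLevel4:
    def test_isomers_both_annotated(self):
        e = _empcpd(mass=180.063389)
        db = [CompoundRecord("glucose", 180.06339), CompoundRecord("fructose", 180.06339)]
        annotate_level4([e], db, 5.0)
        assert sorted(a.candidate_name for a in e.annotations) == ["fructose", "glucose"]
        assert all(a.level == "4" for a in e.annotations)
        assert all(abs(a.evidence["ppm_error"]) <= 5.0 for a in e.annotations)

    def test_20_ppm_away_not_annotated(self):
        e = _empcpd(mass=500.0)
        annotate_level4([e], [CompoundRecord("x", 500.01)], 5.0)
        assert e.annotations == []

    def test_absent_neutral_mass_untouched(self):
        e = _empcpd(mass=None)
        annotate_level4([e], [CompoundRecord("x", 500.0)], 5.0)
        assert e.annotations == []

    def test_empty_database_warns_and_noops(self):
        e = _empcpd(mass=500.0)
        with pytest.warns(UserWarning, match="empty"):
            annotate_level4([e], [], 5.0)
        assert e.annotations == []

    def test_one_query_per_empcpd_not_per_feature(self, monkeypatch, basic_bundle):
        # the efficiency contract of pre-annotation: the database sees one
        # query per empirical compound even when compounds have many members
        ecs = mp.build_empirical_compounds(basic_bundle.table)
        calls = {"n": 0}
        orig = np.searchsorted

        def counting(*args, **kwargs):
            calls["n"] += 1
            return orig(*args, **kwargs)

        monkeypatch.setattr(np, "searchsorted", counting)
        annotate_level4(ecs, basic_bundle.compound_db, 5.0)
        with_mass = sum(1 for e in ecs if e.neutral_mass is not None)
        assert calls["n"] == 2 * with_mass  # lo + hi bound per empcpd
        assert with_mass < basic_bundle.table.n_features


class TestLevel1b:
    def _setup(self, std_rt):
        table = make_table([181.070665], [100.0])
        e = _empcpd(members=(("f1", None),))
        std = StandardRecord("glucose", 181.070665, std_rt)
        return table, e, std

    def test_both_gates_pass(self):
        table, e, std = self._setup(102.0)
        annotate_level1b([e], table, [std], 5.0, 5.0)
        assert len(e.annotations) == 1
        ann = e.annotations[0]
        assert ann.level == "1b" and ann.candidate_name == "glucose"
        assert ann.evidence["rt_error_s"] == pytest.approx(-2.0)

    def test_rt_gate_fails(self):
        table, e, std = self._setup(120.0)
        annotate_level1b([e], table, [std], 5.0, 5.0)
        assert e.annotations == []

    def test_mz_gate_fails_despite_exact_rt(self):
        table = make_table([181.070665 * (1 + 10e-6)], [100.0])
        e = _empcpd()
        std = StandardRecord("glucose", 181.070665, 100.0)
        annotate_level1b([e], table, [std], 5.0, 5.0)
        assert e.annotations == []


class TestPrecursorIndex:
    def test_stabbing_query_hits_only_the_right_member(self):
        table = make_table([100.0, 200.0, 300.0], [10.0, 20.0, 30.0])
        e = _empcpd(members=(("f1", None), ("f2", None), ("f3", None)))
        idx = PrecursorIndex.build([e], table, 5.0)
        hits = idx.query(200.0005)
        assert [h[1] for h in hits] == ["f2"]

    def test_query_far_from_all_is_empty(self):
        table = make_table([100.0, 200.0], [10.0, 20.0])
        e = _empcpd(members=(("f1", None), ("f2", None)))
        idx = PrecursorIndex.build([e], table, 5.0)
        assert idx.query(150.0) == []

    def test_equivalent_to_linear_scan_on_random_instances(self):
        rng = np.random.default_rng(21)
        n = 1000
        table = make_table(
            list(rng.uniform(80, 1200, n)), list(rng.uniform(0, 3000, n)),
            np.full((n, 2), 100.0),
        )
        ecs = [
            _empcpd(members=((fid, None),), eid=f"E{i}")
            for i, fid in enumerate(table.feature_ids)
        ]
        idx = PrecursorIndex.build(ecs, table, 5.0)
        mzs = table.mz.to_numpy()
        queries = np.concatenate([
            rng.uniform(80, 1200, 700),
            # adversarial: exactly on and just off window boundaries
            rng.choice(mzs, 100) * (1 + 5e-6),
            rng.choice(mzs, 100) * (1 - 5e-6),
            rng.choice(mzs, 100) * (1 + 5.001e-6),
        ])
        for q in queries:
            assert idx.query(float(q)) == linear_scan_query(ecs, table, float(q), 5.0)


class TestMapMS2:
    def _fixture(self, rt_tol):
        table = make_table([181.070665], [100.0])
        e = _empcpd(members=(("f1", None),))
        spec = MS2Spectrum(181.0707, 101.0, [(85.0, 10.0), (95.0, 20.0)])
        idx = PrecursorIndex.build([e], table, 30.0)
        unassigned = map_ms2_to_empcpds([spec], [e], idx, rt_tol)
        return e, unassigned

    def test_attaches_within_tolerances(self):
        e, unassigned = self._fixture(30.0)
        assert len(e.ms2_spectra) == 1 and unassigned == []

    def test_rt_gate_sends_to_unassigned_pool(self):
        e, unassigned = self._fixture(0.5)
        assert e.ms2_spectra == [] and len(unassigned) == 1

    def test_empty_spectra_list_is_a_noop(self):
        table = make_table([181.070665], [100.0])
        e = _empcpd()
        idx = PrecursorIndex.build([e], table, 5.0)
        assert map_ms2_to_empcpds([], [e], idx, 30.0) == []
        assert e.ms2_spectra == []


class TestCosine:
    def test_identity_scores_one(self):
        q = MS2Spectrum(100.0, 0.0, [(100.0, 1.0), (150.0, 0.5), (200.0, 2.0)])
        m = cosine_score(q, q, 0.01, 3)
        assert m.score == pytest.approx(1.0, abs=1e-12)
        assert m.n_matched_peaks == 3 and not m.below_threshold

    def test_disjoint_scores_zero(self):
        q = MS2Spectrum(100.0, 0.0, [(100.0, 1.0), (150.0, 0.5)])
        r = MS2Spectrum(100.0, 0.0, [(300.0, 1.0), (350.0, 0.5)])
        assert cosine_score(q, r, 0.01, 1).score == 0.0

    def test_two_peak_worked_example(self):
        q = MS2Spectrum(100.0, 0.0, [(100.0, 1.0), (150.0, 0.5)])
        r = MS2Spectrum(100.0, 0.0, [(100.0, 0.5), (150.0, 1.0)])
        m = cosine_score(q, r, 0.01, 2)
        assert m.score == pytest.approx(0.8, abs=1e-12)
        assert m.n_matched_peaks == 2

    def test_symmetry_and_bounds_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            def spec():
                n = int(rng.integers(2, 15))
                return MS2Spectrum(
                    100.0, 0.0,
                    list(zip(np.sort(rng.uniform(50, 500, n)).tolist(),
                             rng.uniform(1, 100, n).tolist())),
                )
            a, b = spec(), spec()
            sab = cosine_score(a, b, 0.01, 1)
            sba = cosine_score(b, a, 0.01, 1)
            assert sab.score == pytest.approx(sba.score, abs=1e-12)
            assert 0.0 <= sab.score <= 1.0
            assert sab.n_matched_peaks <= min(len(a.peaks), len(b.peaks))

    @staticmethod
    def _peaks_strategy():
        from hypothesis import strategies as st

        peak = st.tuples(
            st.floats(min_value=50.0, max_value=500.0, allow_nan=False),
            st.floats(min_value=0.1, max_value=100.0, allow_nan=False),
        )
        return st.lists(peak, min_size=1, max_size=12)

    def test_cosine_invariants_hold_for_arbitrary_spectra(self):
        from hypothesis import given, settings

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(self._peaks_strategy(), self._peaks_strategy())
        def check(p1, p2):
            a = MS2Spectrum(100.0, 0.0, p1)
            b = MS2Spectrum(100.0, 0.0, p2)
            ab = cosine_score(a, b, 0.01, 1)
            ba = cosine_score(b, a, 0.01, 1)
            assert 0.0 <= ab.score <= 1.0
            assert ab.score == pytest.approx(ba.score, abs=1e-12)
            assert ab.n_matched_peaks == ba.n_matched_peaks
            assert ab.n_matched_peaks <= min(len(a.peaks), len(b.peaks))
            assert cosine_score(a, a, 0.01, 1).score == pytest.approx(1.0, abs=1e-9)

        check()

    def test_empty_peak_list_is_an_error(self):
        q = MS2Spectrum(100.0, 0.0, [(100.0, 1.0)])
        bad = MS2Spectrum.__new__(MS2Spectrum)
        bad.precursor_mz, bad.precursor_rtime, bad.peaks = 100.0, 0.0, []
        bad.source, bad.provenance = "", "experimental"
        with pytest.raises(ValueError, match="empty"):
            cosine_score(q, bad, 0.01, 1)

    def test_agrees_with_matchms_greedy_cosine(self):
        # dev-time cross-validation against the established implementation
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(42)
        scorer = CosineGreedy(tolerance=0.01)
        for _ in range(100):
            n1, n2 = int(rng.integers(5, 20)), int(rng.integers(5, 20))
            mz1 = np.sort(rng.uniform(50, 500, n1))
            i1 = rng.uniform(1, 100, n1)
            shared = mz1[: n1 // 2] + rng.uniform(-0.005, 0.005, n1 // 2)
            mz2 = np.sort(np.concatenate([shared, rng.uniform(50, 500, n2)]))
            i2 = rng.uniform(1, 100, len(mz2))
            q = MS2Spectrum(100.0, 0.0, list(zip(mz1.tolist(), i1.tolist())))
            r = MS2Spectrum(100.0, 0.0, list(zip(mz2.tolist(), i2.tolist())))
            mine = cosine_score(q, r, 0.01, 1)
            res = scorer.pair(
                Spectrum(mz=q.mz_array, intensities=q.intensity_array,
                         metadata={"precursor_mz": 100.0}),
                Spectrum(mz=r.mz_array, intensities=r.intensity_array,
                         metadata={"precursor_mz": 100.0}),
            )
            assert mine.score == pytest.approx(float(res["score"]), abs=1e-6)
            assert mine.n_matched_peaks == int(res["matches"])


class TestAnnotateMS2:
    def _planted(self, provenance):
        rng = np.random.default_rng(5)
        mzs = np.sort(rng.uniform(50, 400, 10))
        ints = rng.uniform(10, 100, 10)
        ref = MS2Spectrum(181.07, 100.0, list(zip(mzs.tolist(), ints.tolist())),
                          source="lib:glucose", provenance=provenance)
        noisy = ints * (1 + rng.uniform(-0.05, 0.05, 10))
        query = MS2Spectrum(181.0707, 101.0, list(zip(mzs.tolist(), noisy.tolist())),
                            source="run1:scan=5")
        e = _empcpd()
        e.ms2_spectra.append(query)
        return e, ref

    def test_public_library_gives_level2_high_score(self):
        e, ref = self._planted("reference_public")
        annotate_ms2([e], [ref], 0.01, 0.7, 3)
        assert len(e.annotations) == 1
        ann = e.annotations[0]
        assert ann.level == "2" and ann.score > 0.95
        assert ann.candidate_name == "glucose"

    def test_authentic_library_gives_level1a(self):
        e, ref = self._planted("reference_authentic")
        annotate_ms2([e], [ref], 0.01, 0.7, 3)
        assert e.annotations[0].level == "1a"

    def test_unattainable_cutoff_gives_nothing(self):
        e, ref = self._planted("reference_public")
        annotate_ms2([e], [ref], 0.01, 1.01, 3)
        assert e.annotations == []

    def test_experimental_provenance_library_rejected(self):
        e, _ = self._planted("reference_public")
        bad = MS2Spectrum(100.0, 0.0, [(50.0, 1.0)], provenance="experimental")
        with pytest.raises(ValueError, match="provenance"):
            annotate_ms2([e], [bad], 0.01, 0.7, 1)


class TestMapToFeatures:
    def test_intersection_semantics(self):
        table = make_table([100.0], [10.0])
        e = EmpiricalCompound("E1", [("f1", None), ("zz", None)],
                              annotations=[AnnotationRecord("4", "x", source="db")])
        rows = map_annotations_to_features([e], table)
        assert [r["feature_id"] for r in rows] == ["f1"]

    def test_product_count(self):
        table = make_table([100.0, 101.0, 102.0], [10.0, 10.0, 10.0])
        e = EmpiricalCompound(
            "E1", [("f1", None), ("f2", None), ("f3", None)],
            annotations=[AnnotationRecord("4", "x", source="db"),
                         AnnotationRecord("4", "y", source="db")],
        )
        assert len(map_annotations_to_features([e], table)) == 6

    def test_no_annotations_no_rows(self):
        table = make_table([100.0], [10.0])
        assert map_annotations_to_features([_empcpd()], table) == []

    def test_rows_ranked_by_level_precedence(self):
        table = make_table([100.0], [10.0])
        e = EmpiricalCompound(
            "E1", [("f1", None)],
            annotations=[AnnotationRecord("4", "massonly", source="db"),
                         AnnotationRecord("1a", "confirmed", score=0.99, source="lib"),
                         AnnotationRecord("2", "probable", score=0.9, source="lib")],
        )
        rows = map_annotations_to_features([e], table)
        assert [r["level"] for r in rows] == ["1a", "2", "4"]
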