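"""Multi-level annotation of empirical compounds.

Level 4: inferred neutral mass vs. a compound database. Level 1b: feature
m/z + retention time vs. authentic standards. Levels 2 / 1a: MS2 spectral
similarity vs. a public library / authentic-standards library. All
annotation stages append to the empirical compound's annotation list, never
overwrite, so independent sources chain. Precursor lookups go through an
interval-tree index whose results are exactly those of a linear ppm scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .models import (
    AnnotationRecord,
    CompoundRecord,
    EmpiricalCompound,
    FeatureTable,
    MS2Spectrum,
    StandardRecord,
)
from .preannotation import ppm_error


# ---------------------------------------------------------------------------
# level 4: neutral mass vs compound database
# ---------------------------------------------------------------------------

def annotate_level4(
    empcpds: list[EmpiricalCompound],
    compound_db: list[CompoundRecord],
    mz_tol_ppm: float = 5.0,
    source: str = "compound_db",
) -> list[EmpiricalCompound]:
    """Append a level-4 annotation for every database compound whose neutral
    mass lies within ``mz_tol_ppm`` (relative to the record's mass) of the
    empirical compound's inferred neutral mass.

    Isomers at equal mass all match: multiple records are appended, ranking
    happens at read-out. Empirical compounds without a neutral mass (e.g.
    singletons with unknown ion) are left untouched. One database query is
    issued per empirical compound, not per feature.
    """
    if not compound_db:
        import warnings

        warnings.warn("empty compound database: level-4 annotation is a no-op")
        return empcpds
    masses = np.array([c.neutral_mass for c in compound_db])
    order = np.argsort(masses)
    sorted_masses = masses[order]
    for e in empcpds:
        if e.neutral_mass is None:
            continue
        # window in Daltons around the query, tolerance on each record's mass
        half = sorted_masses * mz_tol_ppm * 1e-6
        lo = np.searchsorted(sorted_masses + half, e.neutral_mass, side="left")
        hi = np.searchsorted(sorted_masses - half, e.neutral_mass, side="right")
        for k in range(lo, hi):
            rec = compound_db[order[k]]
            err = ppm_error(e.neutral_mass, rec.neutral_mass)
            if abs(err) <= mz_tol_ppm:
                e.annotations.append(
                    AnnotationRecord(
                        level="4",
                        candidate_name=rec.name,
                        candidate_id=rec.identifiers.get("id"),
                        score=None,
                        source=source,
                        evidence={"ppm_error": err, "formula": rec.formula},
                    )
                )
    return empcpds


# ---------------------------------------------------------------------------
# level 1b: m/z + RT vs authentic standards
# ---------------------------------------------------------------------------

def annotate_level1b(
    empcpds: list[EmpiricalCompound],
    table: FeatureTable,
    standards: list[StandardRecord],
    mz_tol_ppm: float = 5.0,
    rt_tol_s: float = 5.0,
    source: str = "standards",
) -> list[EmpiricalCompound]:
    """Append a level-1b annotation when a member feature matches an authentic
    standard on both m/z (<= mz_tol_ppm) and retention time (<= rt_tol_s)."""
    for e in empcpds:
        for fid, _ in e.members:
            if fid not in table.frame.index:
                continue
            mz = float(table.frame.loc[fid, "mz"])
            rt = float(table.frame.loc[fid, "rtime"])
            for std in standards:
                err = ppm_error(mz, std.mz)
                drt = rt - std.rtime
                if abs(err) <= mz_tol_ppm and abs(drt) <= rt_tol_s:
                    e.annotations.append(
                        AnnotationRecord(
                            level="1b",
                            candidate_name=std.name,
                            score=None,
                            source=source,
                            evidence={"feature_id": fid, "ppm_error": err, "rt_error_s": drt},
                        )
                    )
    return empcpds


# ---------------------------------------------------------------------------
# precursor interval index
# ---------------------------------------------------------------------------

class PrecursorIndex:
    """Interval-tree index over member-feature m/z ppm windows.

    Each member feature of each empirical compound contributes the window
    [mz (1 - tol), mz (1 + tol)]; a stabbing query returns exactly the
    (empcpd_id, feature_id, rtime) triples whose window contains the query
    m/z — identical to a linear scan with the ppm test (the tree intervals
    are padded a hair and the exact test re-applied, so boundary behaviour
    cannot differ from the scan).
    """

    def __init__(self, mz_tol_ppm: float = 5.0):
        self.mz_tol_ppm = mz_tol_ppm
        self._tree = IntervalTree()
        self._entries: list[tuple[str, str, float, float]] = []

    @classmethod
    def build(
        cls,
        empcpds: list[EmpiricalCompound],
        table: FeatureTable,
        mz_tol_ppm: float = 5.0,
    ) -> "PrecursorIndex":
        idx = cls(mz_tol_ppm)
        tol = mz_tol_ppm * 1e-6
        for e in empcpds:
            for fid, _ in e.members:
                if fid not in table.frame.index:
                    continue
                mz = float(table.frame.loc[fid, "mz"])
                rt = float(table.frame.loc[fid, "rtime"])
                k = len(idx._entries)
                idx._entries.append((e.empcpd_id, fid, rt, mz))
                pad = 2e-9 * mz
                idx._tree.addi(mz * (1 - tol) - pad, mz * (1 + tol) + pad, k)
        return idx

    def query(self, mz_query: float) -> list[tuple[str, str, float]]:
        """(empcpd_id, feature_id, rtime) of members whose window contains mz."""
        hits = []
        for iv in self._tree.at(mz_query):
            empcpd_id, fid, rt, mz = self._entries[iv.data]
            if abs(ppm_error(mz_query, mz)) <= self.mz_tol_ppm:
                hits.append((empcpd_id, fid, rt))
        hits.sort()
        return hits

    def __len__(self) -> int:
        return len(self._entries)


def linear_scan_query(
    empcpds: list[EmpiricalCompound],
    table: FeatureTable,
    mz_query: float,
    mz_tol_ppm: float = 5.0,
) -> list[tuple[str, str, float]]:
    """Brute-force reference for :meth:`PrecursorIndex.query`."""
    hits = []
    for e in empcpds:
        for fid, _ in e.members:
            if fid not in table.frame.index:
                continue
            mz = float(table.frame.loc[fid, "mz"])
            if abs(ppm_error(mz_query, mz)) <= mz_tol_ppm:
                hits.append((e.empcpd_id, fid, float(table.frame.loc[fid, "rtime"])))
    hits.sort()
    return hits


def map_ms2_to_empcpds(
    spectra: list[MS2Spectrum],
    empcpds: list[EmpiricalCompound],
    index: PrecursorIndex,
    rt_tol_s: float = 30.0,
) -> list[MS2Spectrum]:
    """Attach each spectrum to every empirical compound owning a member whose
    m/z window contains the precursor and whose RT is within ``rt_tol_s``.

    Returns the spectra that matched nothing (the unassigned pool).
    """
    by_id = {e.empcpd_id: e for e in empcpds}
    unassigned = []
    for spec in spectra:
        matched_ids = set()
        for empcpd_id, _, rt in index.query(spec.precursor_mz):
            if abs(rt - spec.precursor_rtime) <= rt_tol_s:
                matched_ids.add(empcpd_id)
        if not matched_ids:
            unassigned.append(spec)
            continue
        for eid in sorted(matched_ids):
            by_id[eid].ms2_spectra.append(spec)
    return unassigned


# ---------------------------------------------------------------------------
# MS2 similarity
# ---------------------------------------------------------------------------

@dataclass
class SpectralMatch:
    """Greedy-cosine comparison of a query spectrum against a reference."""

    query: MS2Spectrum
    reference: MS2Spectrum
    score: float
    n_matched_peaks: int
    below_threshold: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError("score must lie in [0, 1]")


def cosine_score(
    query: MS2Spectrum,
    reference: MS2Spectrum,
    frag_tol_da: float = 0.01,
    min_matched: int = 3,
) -> SpectralMatch:
    """Greedy one-to-one cosine similarity on raw intensities.

    Candidate peak pairs within ``frag_tol_da`` are taken in descending order
    of intensity product, each peak used at most once; the score is the sum
    of matched intensity products over the product of the spectra's L2 norms,
    so identical spectra score exactly 1 and disjoint spectra 0. Matches with
    fewer than ``min_matched`` pairs are reported but flagged below-threshold.
    """
    if not query.peaks or not reference.peaks:
        raise ValueError("cannot score an empty peak list")
    qmz, qint = query.mz_array, query.intensity_array
    rmz, rint = reference.mz_array, reference.intensity_array
    pairs = [
        (float(qint[i] * rint[j]), i, j)
        for i in range(len(qmz))
        for j in range(len(rmz))
        if abs(qmz[i] - rmz[j]) <= frag_tol_da
    ]
    pairs.sort(key=lambda t: -t[0])
    used_q: set[int] = set()
    used_r: set[int] = set()
    dot = 0.0
    n_matched = 0
    for prod, i, j in pairs:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        dot += prod
        n_matched += 1
    denom = float(np.linalg.norm(qint) * np.linalg.norm(rint))
    score = min(dot / denom, 1.0) if denom > 0 else 0.0
    return SpectralMatch(
        query=query,
        reference=reference,
        score=score,
        n_matched_peaks=n_matched,
        below_threshold=n_matched < min_matched,
    )


def annotate_ms2(
    empcpds: list[EmpiricalCompound],
    library: list[MS2Spectrum],
    frag_tol_da: float = 0.01,
    score_cutoff: float = 0.7,
    min_matched: int = 3,
    source: str = "ms2_library",
) -> list[EmpiricalCompound]:
    """Score attached experimental spectra against a spectral library.

    Each (attached spectrum, library spectrum) pair with score >=
    ``score_cutoff`` and enough matched peaks appends one annotation:
    level 1a when the library spectrum comes from authentic standards
    (provenance ``reference_authentic``), level 2 for public references.
    All qualifying hits are retained; ranking happens at read-out.
    """
    from .io import library_compound_name

    bad = [s.source for s in library if s.provenance == "experimental"]
    if bad:
        raise ValueError(
            f"library spectra must carry reference provenance; experimental: {bad[:5]}"
        )
    for e in empcpds:
        for spec in e.ms2_spectra:
            for ref in library:
                match = cosine_score(spec, ref, frag_tol_da, min_matched)
                if match.score >= score_cutoff and not match.below_threshold:
                    level = "1a" if ref.provenance == "reference_authentic" else "2"
                    e.annotations.append(
                        AnnotationRecord(
                            level=level,
                            candidate_name=library_compound_name(ref),
                            score=match.score,
                            source=source,
                            evidence={
                                "n_matched_peaks": match.n_matched_peaks,
                                "query_source": spec.source,
                                "reference_source": ref.source,
                            },
                        )
                    )
    return empcpds


# ---------------------------------------------------------------------------
# mapping annotations back to features
# ---------------------------------------------------------------------------

def map_annotations_to_features(
    empcpds: list[EmpiricalCompound],
    table: FeatureTable,
) -> list[dict]:
    """One row per (member feature present in the table, annotation).

    Features absent from the table are skipped silently: the same empirical
    compounds can be mapped onto any table derived from the experiment. The
    rows feed the three-table output.
    """
    known = set(table.feature_ids)
    rows = []
    for e in empcpds:
        for ann in e.sorted_annotations():
            for fid in e.feature_ids:
                if fid not in known:
                    continue
                rows.append(
                    {
                        "feature_id": fid,
                        "empcpd_id": e.empcpd_id,
                        "level": ann.level,
                        "candidate_name": ann.candidate_name,
                        "candidate_id": ann.candidate_id,
                        "score": ann.score,
                        "source": ann.source,
                        "evidence": dict(ann.evidence),
                    }
                )
    return rows
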