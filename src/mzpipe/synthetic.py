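"""Synthetic LC-MS experiments with planted ground truth.

The generator emulates the post-preprocessing view of an untargeted LC-MS
run: each planted compound contributes a co-eluting block of features (its
adducts and isotopologues at exact ion-mass offsets plus bounded ppm noise),
per-sample intensities are log-normal around a compound abundance and scaled
by per-batch factors, and the design can plant blank contamination, failed
injections and missing values. Every input the pipeline consumes (metadata
CSV, feature-table TSV, compound DB, standards CSV, MSP library, centroided
mzML with MS2 scans) is written to disk, alongside a GroundTruth object
mapping every feature to its compound and ion species.
"""

from __future__ import annotations

import base64
import os
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .models import (
    Acquisition,
    CompoundRecord,
    EmpiricalCompound,
    Experiment,
    FeatureTable,
    MS2Spectrum,
    StandardRecord,
)
from .preannotation import DEFAULT_ADDUCTS_POS, DEFAULT_ISOTOPE_STEPS

#: relative intensity of each adduct (vs M+H) and of M+1 vs M0
ADDUCT_FRACTIONS = {"M+H+": 1.0, "M+Na+": 0.4, "M+NH4+": 0.3}
ISOTOPE_FRACTIONS = {"M0": 1.0, "13C/3C1": 0.25, "13C/3C2": 0.0625}

_ADDUCT_OFFSETS = dict(DEFAULT_ADDUCTS_POS)
_ISOTOPE_OFFSETS = dict(DEFAULT_ISOTOPE_STEPS)


@dataclass
class PlantedCompound:
    name: str
    neutral_mass: float
    rtime: float
    abundance: float
    features: dict[str, tuple[str, str]]  # feature_id -> (isotope, adduct)
    contaminant: bool = False
    has_standard: bool = False
    has_ms2: bool = False


@dataclass
class GroundTruth:
    compounds: list[PlantedCompound]
    batches: dict[str, str]
    failed_samples: list[str]
    blank_names: list[str]
    study_names: list[str]
    params: dict = field(default_factory=dict)

    def feature_to_compound(self) -> dict[str, str]:
        return {fid: c.name for c in self.compounds for fid in c.features}

    def planted_groups(self) -> dict[str, set[str]]:
        return {c.name: set(c.features) for c in self.compounds}


@dataclass
class SyntheticExperiment:
    """Everything make_experiment produced, in memory and on disk."""

    experiment: Experiment
    table: FeatureTable
    truth: GroundTruth
    compound_db: list[CompoundRecord]
    standards: list[StandardRecord]
    library: list[MS2Spectrum]
    query_spectra: list[MS2Spectrum]
    metadata_path: str
    table_path: str
    db_path: str
    standards_path: str
    library_path: str
    mzml_path: str | None


def make_experiment(
    directory: str,
    n_compounds: int = 50,
    n_samples: int = 20,
    n_batches: int = 1,
    batch_scale_factors: tuple[float, ...] | None = None,
    adduct_set: tuple[str, ...] = ("M+H+", "M+Na+"),
    isotope_set: tuple[str, ...] = ("M0", "13C/3C1"),
    mz_noise_ppm: float = 2.0,
    intensity_cv: float = 0.3,
    missing_rate: float = 0.05,
    n_blanks: int = 0,
    contamination_fraction: float = 0.0,
    n_failed: int = 0,
    n_standards: int = 0,
    n_ms2: int = 0,
    seed: int = 0,
) -> SyntheticExperiment:
    """Generate a complete synthetic experiment with planted ground truth.

    m/z noise is uniform in [-mz_noise_ppm, +mz_noise_ppm] (bounded, so a
    grouping tolerance of 2.5x the noise can never be violated by a planted
    pair); intensities are log-normal with the stated CV around a per-compound
    abundance, times the batch scale factor. Failed injections retain under
    10% of their features; contaminant compounds appear in blanks at or above
    study level. Identical (params, seed) give bit-identical output.
    """
    if n_failed >= n_samples:
        raise ValueError("n_failed must be smaller than n_samples")
    if not 0 <= missing_rate <= 1 or not 0 <= contamination_fraction <= 1:
        raise ValueError("rates must lie in [0, 1]")
    for a in adduct_set:
        if a not in _ADDUCT_OFFSETS:
            raise ValueError(f"unknown adduct {a!r}")
    for i in isotope_set:
        if i not in _ISOTOPE_OFFSETS:
            raise ValueError(f"unknown isotope {i!r}")
    if batch_scale_factors is None:
        batch_scale_factors = tuple(1.0 for _ in range(n_batches))
    if len(batch_scale_factors) != n_batches:
        raise ValueError("need one scale factor per batch")

    rng = np.random.default_rng(seed)
    os.makedirs(directory, exist_ok=True)

    study_names = [f"S{i + 1:03d}" for i in range(n_samples)]
    blank_names = [f"B{i + 1:02d}" for i in range(n_blanks)]
    sample_columns = study_names + blank_names
    batch_of = {
        s: f"batch{(i % n_batches) + 1}" for i, s in enumerate(study_names)
    }
    for b in blank_names:
        batch_of[b] = "batch1"
    study_factor = np.array(
        [batch_scale_factors[i % n_batches] for i in range(n_samples)]
    )
    failed = study_names[-n_failed:] if n_failed else []

    n_contaminants = int(round(contamination_fraction * n_compounds))
    # compounds: masses spaced ~9.4 Da apart with jitter, retention times
    # spaced so distinct compounds never co-elute (planted groups stay clean)
    masses = 150.0 + 9.37 * np.arange(n_compounds) + rng.uniform(0.0, 1.0, n_compounds)
    rt_order = rng.permutation(n_compounds)
    rts = 60.0 + rt_order * (540.0 / max(n_compounds, 1)) + rng.uniform(-0.5, 0.5, n_compounds)
    abundances = 10 ** rng.uniform(5.0, 7.0, n_compounds)
    contaminant_idx = set(rng.choice(n_compounds, n_contaminants, replace=False).tolist())
    clean = [i for i in range(n_compounds) if i not in contaminant_idx]
    standard_idx = set(clean[:n_standards])
    ms2_idx = set(clean[n_standards : n_standards + n_ms2])

    compounds: list[PlantedCompound] = []
    fids: list[str] = []
    mz_list: list[float] = []
    rt_list: list[float] = []
    rows: list[np.ndarray] = []
    k = 0
    for ci in range(n_compounds):
        name = f"CPD{ci + 1:03d}"
        features: dict[str, tuple[str, str]] = {}
        # per-sample compound abundance (shared across the compound's ions)
        study_level = (
            abundances[ci]
            * study_factor
            * np.exp(rng.normal(0.0, intensity_cv, n_samples))
        )
        for adduct in adduct_set:
            for iso in isotope_set:
                fid = f"F{k + 1}"
                k += 1
                true_mz = masses[ci] + _ADDUCT_OFFSETS[adduct] + _ISOTOPE_OFFSETS[iso]
                noise = rng.uniform(-mz_noise_ppm, mz_noise_ppm) * 1e-6
                mz_obs = true_mz * (1.0 + noise)
                rt_obs = rts[ci] + rng.uniform(-0.4, 0.4)
                frac = ADDUCT_FRACTIONS[adduct] * ISOTOPE_FRACTIONS[iso]
                study = study_level * frac * np.exp(rng.normal(0.0, 0.05, n_samples))
                # plant missing values, keeping each feature observed somewhere
                if missing_rate > 0:
                    gone = rng.random(n_samples) < missing_rate
                    if gone.all():
                        gone[rng.integers(n_samples)] = False
                    study = np.where(gone, 0.0, study)
                if n_blanks:
                    if ci in contaminant_idx:
                        blank = (
                            abundances[ci]
                            * frac
                            * 1.2
                            * np.exp(rng.normal(0.0, 0.05, n_blanks))
                        )
                    else:
                        blank = np.zeros(n_blanks)
                    row = np.concatenate([study, blank])
                else:
                    row = study
                features[fid] = (iso, adduct)
                fids.append(fid)
                mz_list.append(mz_obs)
                rt_list.append(rt_obs)
                rows.append(row)
        compounds.append(
            PlantedCompound(
                name=name,
                neutral_mass=float(masses[ci]),
                rtime=float(rts[ci]),
                abundance=float(abundances[ci]),
                features=features,
                contaminant=ci in contaminant_idx,
                has_standard=ci in standard_idx,
                has_ms2=ci in ms2_idx,
            )
        )

    intensities = np.vstack(rows)
    # failed injections keep a random <10% of features at 1% intensity
    for s in failed:
        j = sample_columns.index(s)
        col = intensities[:, j]
        keep = rng.random(len(col)) < 0.05
        intensities[:, j] = np.where(keep, col * 0.01, 0.0)

    table = FeatureTable.from_arrays(
        "synthetic", fids, mz_list, rt_list, intensities, sample_columns
    )

    # ------------------------------------------------------------------ disk
    metadata_path = os.path.join(directory, "metadata.csv")
    with open(metadata_path, "w") as fh:
        fh.write("name,path,sample_type,batch\n")
        for s in study_names:
            fh.write(f"{s},{s}.mzML,study,{batch_of[s]}\n")
        for b in blank_names:
            fh.write(f"{b},{b}.mzML,blank,{batch_of[b]}\n")

    from . import io

    table_path = os.path.join(directory, "feature_table.tsv")
    io.write_feature_table(table, table_path)

    compound_db = [
        CompoundRecord(name=c.name, neutral_mass=c.neutral_mass) for c in compounds
    ]
    db_path = os.path.join(directory, "compounds.tsv")
    with open(db_path, "w") as fh:
        fh.write("name\tformula\tneutral_mass\n")
        for c in compounds:
            fh.write(f"{c.name}\t\t{c.neutral_mass!r}\n")

    standards = [
        StandardRecord(
            name=c.name,
            mz=c.neutral_mass + _ADDUCT_OFFSETS["M+H+"],
            rtime=c.rtime,
            mode="pos",
        )
        for c in compounds
        if c.has_standard
    ]
    standards_path = os.path.join(directory, "standards.csv")
    with open(standards_path, "w") as fh:
        fh.write("name,mz,rtime,mode\n")
        for s in standards:
            fh.write(f"{s.name},{s.mz!r},{s.rtime!r},{s.mode}\n")

    library: list[MS2Spectrum] = []
    query_spectra: list[MS2Spectrum] = []
    for c in compounds:
        if not c.has_ms2:
            continue
        n_peaks = int(rng.integers(8, 15))
        frag_mz = np.sort(rng.uniform(50.0, max(60.0, c.neutral_mass - 10.0), n_peaks))
        frag_int = rng.uniform(10.0, 100.0, n_peaks)
        precursor = c.neutral_mass + _ADDUCT_OFFSETS["M+H+"]
        library.append(
            MS2Spectrum(
                precursor_mz=precursor,
                precursor_rtime=c.rtime,
                peaks=list(zip(frag_mz.tolist(), frag_int.tolist())),
                source=f"library:{c.name}",
                provenance="reference_public",
            )
        )
        noisy = frag_int * (1.0 + rng.uniform(-0.05, 0.05, n_peaks))
        query_spectra.append(
            MS2Spectrum(
                precursor_mz=precursor * (1.0 + rng.uniform(-2e-6, 2e-6)),
                precursor_rtime=c.rtime + rng.uniform(-2.0, 2.0),
                peaks=list(zip(frag_mz.tolist(), noisy.tolist())),
                source=f"experimental:{c.name}",
                provenance="experimental",
            )
        )

    library_path = os.path.join(directory, "library.msp")
    write_msp(library, library_path)

    mzml_path = None
    if query_spectra:
        mzml_path = os.path.join(directory, "ms2_scans.mzML")
        write_mzml(query_spectra, mzml_path)

    acquisitions = [
        Acquisition(name=s, source_path=f"{s}.mzML", sample_type="study", batch=batch_of[s])
        for s in study_names
    ] + [
        Acquisition(name=b, source_path=f"{b}.mzML", sample_type="blank", batch=batch_of[b])
        for b in blank_names
    ]
    experiment = Experiment(directory, acquisitions)
    experiment.log_step(
        "make_experiment",
        {"seed": seed, "n_compounds": n_compounds, "n_samples": n_samples},
    )
    experiment.store_table(table, "raw")
    experiment.save()

    truth = GroundTruth(
        compounds=compounds,
        batches=batch_of,
        failed_samples=failed,
        blank_names=blank_names,
        study_names=study_names,
        params={
            "seed": seed,
            "n_compounds": n_compounds,
            "n_samples": n_samples,
            "n_batches": n_batches,
            "batch_scale_factors": list(batch_scale_factors),
            "mz_noise_ppm": mz_noise_ppm,
            "intensity_cv": intensity_cv,
            "missing_rate": missing_rate,
        },
    )
    return SyntheticExperiment(
        experiment=experiment,
        table=table,
        truth=truth,
        compound_db=compound_db,
        standards=standards,
        library=library,
        query_spectra=query_spectra,
        metadata_path=metadata_path,
        table_path=table_path,
        db_path=db_path,
        standards_path=standards_path,
        library_path=library_path,
        mzml_path=mzml_path,
    )


PRESETS = {
    "basic": {},
    "batch_effect": {"n_batches": 2, "batch_scale_factors": (1.0, 2.0)},
    "failed_injection": {"n_failed": 1},
    "blank_contamination": {"n_blanks": 3, "contamination_fraction": 0.1},
    "combined": {
        "n_batches": 2,
        "batch_scale_factors": (1.0, 2.0),
        "n_blanks": 3,
        "contamination_fraction": 0.1,
        "n_failed": 1,
        "n_standards": 10,
        "n_ms2": 10,
    },
}


def make_preset(directory: str, preset: str, seed: int = 0, **overrides) -> SyntheticExperiment:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return make_experiment(directory, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    feature_accuracy: float  # fraction of features in exactly their planted group
    group_recovery: float  # fraction of planted groups recovered exactly
    neutral_mass_ppm_errors: dict[str, float]  # compound name -> signed ppm error
    n_features: int
    n_groups: int


def score_recovery(empcpds: list[EmpiricalCompound], truth: GroundTruth) -> RecoveryMetrics:
    """Compare a grouping against the planted partition.

    A feature counts as correctly assigned when its empirical compound's
    member set equals its planted group (both restricted to the features the
    grouping actually saw, so the metric is meaningful after curation drops
    features). Neutral-mass errors are reported for exactly recovered groups.
    """
    universe = {fid for e in empcpds for fid in e.feature_ids}
    empcpd_of = {fid: e for e in empcpds for fid in e.feature_ids}
    correct = 0
    recovered = 0
    n_groups = 0
    ppm_errors: dict[str, float] = {}
    for c in truth.compounds:
        planted = set(c.features) & universe
        if not planted:
            continue
        n_groups += 1
        group_ok = True
        for fid in planted:
            e = empcpd_of.get(fid)
            if e is not None and set(e.feature_ids) == planted:
                correct += 1
            else:
                group_ok = False
        if group_ok:
            recovered += 1
            e = empcpd_of[next(iter(planted))]
            if e.neutral_mass is not None:
                ppm_errors[c.name] = (
                    (e.neutral_mass - c.neutral_mass) / c.neutral_mass * 1e6
                )
    n_features = len(universe & set(truth.feature_to_compound()))
    return RecoveryMetrics(
        feature_accuracy=correct / n_features if n_features else 0.0,
        group_recovery=recovered / n_groups if n_groups else 0.0,
        neutral_mass_ppm_errors=ppm_errors,
        n_features=n_features,
        n_groups=n_groups,
    )


def planted_annotation_level(compound: PlantedCompound) -> str:
    """The best annotation level the fixture design supports for a compound.

    Compounds with planted MS2 spectra should reach level 2, those with an
    authentic standard level 1b, and every compound is in the database, so
    level 4 is always attainable (given a grouped empirical compound).
    """
    if compound.has_ms2:
        return "2"
    if compound.has_standard:
        return "1b"
    return "4"


def score_annotation_recovery(
    empcpds: list[EmpiricalCompound], truth: GroundTruth
) -> tuple[float, int, int]:
    """Fraction of annotatable planted compounds whose empirical compound
    carries a correct annotation (right name) at the planted level.

    Contaminant compounds are excluded: the default workflow blank-masks
    their features away, so they are not annotatable by design.
    """
    owner: dict[str, EmpiricalCompound] = {
        fid: e for e in empcpds for fid in e.feature_ids
    }
    hits, total = 0, 0
    for c in truth.compounds:
        if c.contaminant:
            continue
        total += 1
        level = planted_annotation_level(c)
        owners = {id(owner[fid]): owner[fid] for fid in c.features if fid in owner}
        if any(
            any(a.level == level and a.candidate_name == c.name for a in e.annotations)
            for e in owners.values()
        ):
            hits += 1
    return (hits / total if total else 0.0), hits, total


# ---------------------------------------------------------------------------
# minimal centroided mzML writer
# ---------------------------------------------------------------------------

def _encode_array(values: np.ndarray) -> tuple[str, int]:
    raw = struct.pack(f"<{len(values)}d", *values)
    compressed = zlib.compress(raw)
    text = base64.b64encode(compressed).decode("ascii")
    return text, len(text)


def _binary_array_xml(values: np.ndarray, kind_accession: str, kind_name: str) -> str:
    text, enc_len = _encode_array(np.asarray(values, dtype=float))
    return (
        f'<binaryDataArray encodedLength="{enc_len}">'
        f'<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        f'<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
        f'<cvParam cvRef="MS" accession="{kind_accession}" name="{kind_name}" value=""/>'
        f"<binary>{text}</binary>"
        f"</binaryDataArray>"
    )


def write_mzml(spectra: list[MS2Spectrum], path: str, ms1_scans: int = 0) -> str:
    """Write a minimal centroided mzML file readable by standard parsers.

    MS2 spectra come from the given list; ``ms1_scans`` optional empty-ish MS1
    scans are interleaved first (for testing MS1-only files pass an empty
    spectra list and a positive count).
    """
    chunks: list[str] = []
    index = 0
    for k in range(ms1_scans):
        mzs = np.array([200.0 + k, 300.0 + k])
        ints = np.array([1000.0, 2000.0])
        chunks.append(
            f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mzs)}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '<scanList count="1"><scan>'
            '<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{10.0 * (k + 1)}" unitAccession="UO:0000010" unitName="second" unitCvRef="UO"/>'
            "</scan></scanList>"
            "<binaryDataArrayList count=\"2\">"
            + _binary_array_xml(mzs, "MS:1000514", "m/z array")
            + _binary_array_xml(ints, "MS:1000515", "intensity array")
            + "</binaryDataArrayList></spectrum>"
        )
        index += 1
    for spec in spectra:
        mzs = spec.mz_array
        ints = spec.intensity_array
        chunks.append(
            f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mzs)}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '<scanList count="1"><scan>'
            '<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{spec.precursor_rtime!r}" unitAccession="UO:0000010" unitName="second" unitCvRef="UO"/>'
            "</scan></scanList>"
            '<precursorList count="1"><precursor>'
            '<selectedIonList count="1"><selectedIon>'
            '<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{spec.precursor_mz!r}" unitAccession="MS:1000040" unitName="m/z" unitCvRef="MS"/>'
            "</selectedIon></selectedIonList></precursor></precursorList>"
            "<binaryDataArrayList count=\"2\">"
            + _binary_array_xml(mzs, "MS:1000514", "m/z array")
            + _binary_array_xml(ints, "MS:1000515", "intensity array")
            + "</binaryDataArrayList></spectrum>"
        )
        index += 1

    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
        '<run id="synthetic_run">'
        f'<spectrumList count="{index}" defaultDataProcessingRef="dp1">'
        + "".join(chunks)
        + "</spectrumList></run></mzML>"
    )
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(doc)
    return path


def write_msp(spectra: list[MS2Spectrum], path: str) -> str:
    """Write spectra as an MSP library (one record per spectrum)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for spec in spectra:
            name = spec.source.partition(":")[2] or spec.source
            fh.write(f"Name: {name}\n")
            fh.write(f"PrecursorMZ: {spec.precursor_mz!r}\n")
            fh.write(f"RetentionTime: {spec.precursor_rtime!r}\n")
            fh.write(f"Provenance: {spec.provenance}\n")
            fh.write(f"Num Peaks: {len(spec.peaks)}\n")
            for m, i in spec.peaks:
                fh.write(f"{m!r} {i!r}\n")
            fh.write("\n")
    return path
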