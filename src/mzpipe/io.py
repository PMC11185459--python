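"""Readers and writers: metadata CSV, feature-table TSV, empirical-compound
JSON, the three-table output, mzML MS2 extraction and spectral libraries.

Feature tables use the upstream preprocessor's TSV dialect by default
(columns ``id_number``, ``mz``, ``rtime`` plus one column per sample);
other dialects are declared with :class:`TableDialect`. Retention time is
converted to seconds at the reader boundary when the dialect declares
minutes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .models import (
    Acquisition,
    AnnotationRecord,
    CompoundRecord,
    EmpiricalCompound,
    Experiment,
    FeatureTable,
    MS2Spectrum,
    StandardRecord,
)

EMPCPD_SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def load_metadata(csv_path: str, directory: str | None = None) -> Experiment:
    """Assemble an Experiment from a sample-metadata CSV.

    The CSV minimally maps sample names to acquisition file paths (columns
    ``name`` or ``sample_name``, and ``path`` or ``file_path``); optional
    columns ``sample_type`` and ``batch`` are carried onto the acquisitions,
    any other columns become extra tags.
    """
    df = pd.read_csv(csv_path, dtype=str).fillna("")
    cols = {c.lower().strip(): c for c in df.columns}
    name_col = cols.get("name") or cols.get("sample_name") or cols.get("sample")
    path_col = cols.get("path") or cols.get("file_path") or cols.get("filepath")
    if name_col is None or path_col is None:
        raise ValueError(
            "metadata CSV must have a sample-name column (name/sample_name/sample) "
            f"and a file-path column (path/file_path); found {list(df.columns)}"
        )
    names = df[name_col].tolist()
    dups = sorted({n for n in names if names.count(n) > 1})
    if dups:
        raise ValueError(f"duplicate sample names in metadata: {dups}")

    known = {name_col, path_col, cols.get("sample_type"), cols.get("batch")}
    extra_cols = [c for c in df.columns if c not in known]
    acquisitions = []
    for _, row in df.iterrows():
        acquisitions.append(
            Acquisition(
                name=row[name_col],
                source_path=row[path_col],
                sample_type=(row[cols["sample_type"]] or "unknown")
                if "sample_type" in cols
                else "unknown",
                batch=(row[cols["batch"]] or None) if "batch" in cols else None,
                extra_tags={c: row[c] for c in extra_cols if row[c]},
            )
        )
    if directory is None:
        directory = os.path.dirname(os.path.abspath(csv_path))
    exp = Experiment(directory, acquisitions)
    exp.log_step("load_metadata", {"csv_path": str(csv_path)})
    return exp


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass
class TableDialect:
    """Column naming of a feature-table TSV."""

    id_col: str = "id_number"
    mz_col: str = "mz"
    rtime_col: str = "rtime"
    rtime_unit: str = "s"  # "s" or "min"; minutes are converted on read
    #: columns that are feature metadata rather than samples
    extra_metadata_cols: tuple[str, ...] = ()


ASARI_DIALECT = TableDialect()


def _format_number(v: float) -> str:
    """Full-precision, round-trippable text for a float (integral -> int)."""
    if v == int(v) and abs(v) < 2**53:
        return str(int(v))
    return repr(float(v))


def read_feature_table(
    tsv_path: str,
    dialect: TableDialect = ASARI_DIALECT,
    moniker: str | None = None,
) -> FeatureTable:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    for col in (dialect.id_col, dialect.mz_col, dialect.rtime_col):
        if col not in df.columns:
            raise ValueError(
                f"feature table {tsv_path} is missing required column {col!r}; "
                f"expected at least ({dialect.id_col}, {dialect.mz_col}, {dialect.rtime_col})"
            )
    meta_cols = {dialect.id_col, dialect.mz_col, dialect.rtime_col, *dialect.extra_metadata_cols}
    sample_columns = [c for c in df.columns if c not in meta_cols]
    if not sample_columns:
        raise ValueError(f"feature table {tsv_path} has no sample columns")

    def parse_column(col: str, what: str) -> np.ndarray:
        # float() is correctly rounded, so repr-formatted values round-trip
        # bit-faithfully (pandas' own string parser can be off by 1 ulp)
        values = np.empty(len(df), dtype=float)
        bad = []
        for i, cell in enumerate(df[col]):
            try:
                values[i] = float(cell)
            except (TypeError, ValueError):
                bad.append(df[dialect.id_col].iloc[i])
        if bad:
            raise ValueError(f"{what} in column {col!r} for features {bad} in {tsv_path}")
        return values

    frame = pd.DataFrame(index=pd.Index(df[dialect.id_col], name="feature_id"))
    frame["mz"] = parse_column(dialect.mz_col, "non-numeric m/z")
    frame["rtime"] = parse_column(dialect.rtime_col, "non-numeric retention time")
    if dialect.rtime_unit == "min":
        frame["rtime"] = frame["rtime"] * 60.0
    for col in dialect.extra_metadata_cols:
        if col in df.columns:
            frame[col] = df[col].to_numpy()
    for col in sample_columns:
        frame[col] = parse_column(col, "unparseable intensity")
    if moniker is None:
        moniker = os.path.splitext(os.path.basename(tsv_path))[0]
    return FeatureTable(moniker, frame, sample_columns)


def write_feature_table(
    table: FeatureTable,
    tsv_path: str,
    dialect: TableDialect = ASARI_DIALECT,
) -> str:
    """Write a TSV readable by :func:`read_feature_table` (column order kept).

    Zero intensities are written as ``0``, never as an empty cell: zero *is*
    the missing-value encoding downstream.
    """
    os.makedirs(os.path.dirname(os.path.abspath(tsv_path)), exist_ok=True)
    extra = table.extra_columns
    header = [dialect.id_col, dialect.mz_col, dialect.rtime_col, *extra, *table.sample_columns]
    rt_scale = 1.0 / 60.0 if dialect.rtime_unit == "min" else 1.0
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for fid, row in table.frame.iterrows():
            cells = [str(fid), _format_number(row["mz"]), _format_number(row["rtime"] * rt_scale)]
            cells += [str(row[c]) for c in extra]
            cells += [_format_number(row[c]) for c in table.sample_columns]
            fh.write("\t".join(cells) + "\n")
    return tsv_path


# ---------------------------------------------------------------------------
# empirical-compound JSON
# ---------------------------------------------------------------------------

def empcpds_to_json(empcpds: Iterable[EmpiricalCompound]) -> dict[str, Any]:
    """Serialize empirical compounds as a document keyed by empcpd_id.

    The JSON layout is the interoperability contract that lets independent
    annotation tools chain their results: each entry lists the MS1 members
    with ion relations, attached MS2 spectra, and the cumulative annotation
    list with level and source.
    """
    doc: dict[str, Any] = {"schema_version": EMPCPD_SCHEMA_VERSION, "empirical_compounds": {}}
    for e in empcpds:
        if e.empcpd_id in doc["empirical_compounds"]:
            raise ValueError(f"duplicate empcpd_id {e.empcpd_id!r}")
        doc["empirical_compounds"][e.empcpd_id] = e.to_dict()
    return doc


def empcpds_from_json(doc: Mapping[str, Any]) -> list[EmpiricalCompound]:
    entries = doc.get("empirical_compounds", doc)
    return [EmpiricalCompound.from_dict(eid, d) for eid, d in entries.items()]


def save_empcpds(empcpds: Iterable[EmpiricalCompound], path: str) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(empcpds_to_json(empcpds), fh, indent=1)
    return path


def load_empcpds(path: str) -> list[EmpiricalCompound]:
    with open(path) as fh:
        return empcpds_from_json(json.load(fh))


# ---------------------------------------------------------------------------
# three-table output
# ---------------------------------------------------------------------------

def emit_three_tables(
    experiment: Experiment,
    table: FeatureTable,
    empcpds: list[EmpiricalCompound],
    out_dir: str,
) -> tuple[str, str, str]:
    """Write the standardized output: feature table, annotation table, metadata.

    The annotation table has one row per (feature id, annotation) pair so
    multiple candidate identities per feature are kept, not collapsed. Every
    feature id it references must exist in the feature table.
    """
    os.makedirs(out_dir, exist_ok=True)
    known = set(table.feature_ids)
    dangling = sorted(
        {fid for e in empcpds for fid in e.feature_ids if fid not in known}
    )
    if dangling:
        raise ValueError(f"empirical compounds reference features absent from table: {dangling}")

    feature_path = os.path.join(out_dir, "feature_table.tsv")
    write_feature_table(table, feature_path)

    annotation_path = os.path.join(out_dir, "annotation_table.tsv")
    ann_cols = [
        "feature_id", "empcpd_id", "level", "candidate_name", "candidate_id",
        "score", "source", "evidence",
    ]
    with open(annotation_path, "w") as fh:
        fh.write("\t".join(ann_cols) + "\n")
        for e in empcpds:
            for ann in e.sorted_annotations():
                for fid in e.feature_ids:
                    fh.write(
                        "\t".join(
                            [
                                fid,
                                e.empcpd_id,
                                ann.level,
                                ann.candidate_name,
                                ann.candidate_id or "",
                                "" if ann.score is None else repr(float(ann.score)),
                                ann.source,
                                json.dumps(ann.evidence, sort_keys=True),
                            ]
                        )
                        + "\n"
                    )

    metadata_path = os.path.join(out_dir, "metadata_table.tsv")
    meta_cols = ["record_type", "name", "sample_type", "batch", "source_path", "key", "value"]
    with open(metadata_path, "w") as fh:
        fh.write("\t".join(meta_cols) + "\n")
        for a in experiment.acquisitions:
            fh.write(
                "\t".join(
                    ["acquisition", a.name, a.sample_type, a.batch or "", a.source_path, "", ""]
                )
                + "\n"
            )
        exp_meta = {
            "directory": experiment.directory,
            "n_acquisitions": str(len(experiment.acquisitions)),
            "n_features": str(table.n_features),
            "n_empirical_compounds": str(len(empcpds)),
            "n_commands": str(len(experiment.command_log)),
        }
        for k, v in exp_meta.items():
            fh.write("\t".join(["experiment", "", "", "", "", k, v]) + "\n")
    return feature_path, annotation_path, metadata_path


# ---------------------------------------------------------------------------
# mzML MS2 extraction
# ---------------------------------------------------------------------------

def _decode_binary_array(node, ns: str) -> np.ndarray | None:
    """Decode one <binaryDataArray>: returns values, or None for non-peak data."""
    import base64
    import struct
    import zlib

    accessions = {p.get("accession") for p in node.findall(f"{ns}cvParam")}
    binary = node.find(f"{ns}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    if "MS:1000521" in accessions:  # 32-bit float
        values = np.array(struct.unpack(f"<{len(raw) // 4}f", raw), dtype=float)
    else:  # default / MS:1000523 64-bit float
        values = np.array(struct.unpack(f"<{len(raw) // 8}d", raw), dtype=float)
    if "MS:1000514" in accessions:
        return ("mz", values)  # type: ignore[return-value]
    if "MS:1000515" in accessions:
        return ("intensity", values)  # type: ignore[return-value]
    return None


def extract_ms2(mzml_path: str, min_peaks: int = 2) -> list[MS2Spectrum]:
    """Extract MS2 spectra from a centroided mzML file.

    Spectra with fewer than ``min_peaks`` fragment peaks are dropped.
    Profile-mode spectra are rejected with a pointer to centroiding.
    mzML binary arrays (64/32-bit float, zlib or uncompressed) are decoded
    directly from the XML.
    """
    import xml.etree.ElementTree as ET

    ns = "{http://psi.hupo.org/ms/mzml}"
    spectra: list[MS2Spectrum] = []
    try:
        tree = ET.parse(mzml_path)
    except ET.ParseError as exc:
        raise ValueError(f"cannot read mzML file {mzml_path}: {exc}") from exc
    root = tree.getroot()
    if not root.tag.endswith("mzML") and root.find(f".//{ns}mzML") is None:
        # indexedmzML wrappers nest the mzML element one level down
        raise ValueError(f"{mzml_path} does not look like an mzML document")

    for i, spec in enumerate(root.iter(f"{ns}spectrum")):
        params = {p.get("accession"): p for p in spec.findall(f"{ns}cvParam")}
        ms_level = params.get("MS:1000511")
        if ms_level is None or int(ms_level.get("value")) != 2:
            continue
        if "MS:1000128" in params:  # profile spectrum
            raise ValueError(
                f"{mzml_path} contains profile-mode MS2 scans; centroid the data "
                "first (e.g. peak-pick during mzML conversion)"
            )
        ion = spec.find(
            f"{ns}precursorList/{ns}precursor/{ns}selectedIonList/{ns}selectedIon"
        )
        if ion is None:
            continue
        pmz = None
        for p in ion.findall(f"{ns}cvParam"):
            if p.get("accession") == "MS:1000744":
                pmz = float(p.get("value"))
        if pmz is None:
            continue
        rt = 0.0
        scan = spec.find(f"{ns}scanList/{ns}scan")
        if scan is not None:
            for p in scan.findall(f"{ns}cvParam"):
                if p.get("accession") == "MS:1000016":
                    rt = float(p.get("value"))
                    if "minute" in (p.get("unitName") or ""):
                        rt *= 60.0
        arrays: dict[str, np.ndarray] = {}
        for node in spec.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            decoded = _decode_binary_array(node, ns)
            if decoded is not None:
                kind, values = decoded
                arrays[kind] = values
        mzs = arrays.get("mz")
        intens = arrays.get("intensity")
        if mzs is None or intens is None or len(mzs) != len(intens):
            continue
        keep = intens > 0
        peaks = list(zip(mzs[keep].tolist(), intens[keep].tolist()))
        if len(peaks) < min_peaks:
            continue
        spectra.append(
            MS2Spectrum(
                precursor_mz=pmz,
                precursor_rtime=rt,
                peaks=peaks,
                source=f"{os.path.basename(mzml_path)}:scan={spec.get('index', i)}",
                provenance="experimental",
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# compound databases, standards, spectral libraries
# ---------------------------------------------------------------------------

def read_compound_db(path: str) -> list[CompoundRecord]:
    """Read a compound database from TSV (name/formula/neutral mass) or JSON."""
    if path.endswith(".json"):
        with open(path) as fh:
            entries = json.load(fh)
        return [
            CompoundRecord(
                name=e["name"],
                neutral_mass=float(e["neutral_mass"]),
                formula=e.get("formula"),
                identifiers=dict(e.get("identifiers", {})),
            )
            for e in entries
        ]
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    mass_col = cols.get("neutral_mass") or cols.get("monoisotopic_mass") or cols.get("mass")
    if "name" not in cols or mass_col is None:
        raise ValueError(
            f"compound DB {path} needs 'name' and 'neutral_mass' columns; found {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        formula = row.get(cols["formula"]) if "formula" in cols else None
        records.append(
            CompoundRecord(
                name=str(row[cols["name"]]),
                neutral_mass=float(row[mass_col]),
                formula=None if pd.isna(formula) else str(formula),
            )
        )
    return records


def read_standards(path: str) -> list[StandardRecord]:
    """Read an authentic-standards table (CSV: name, mz, rtime[, mode])."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("name", "mz", "rtime"):
        if required not in cols:
            raise ValueError(f"standards table {path} needs columns name, mz, rtime")
    return [
        StandardRecord(
            name=str(row[cols["name"]]),
            mz=float(row[cols["mz"]]),
            rtime=float(row[cols["rtime"]]),
            mode=str(row[cols["mode"]]) if "mode" in cols else "pos",
        )
        for _, row in df.iterrows()
    ]


def read_msp(path: str, provenance: str = "reference_public") -> list[MS2Spectrum]:
    """Read an MSP spectral library.

    MSP is line-oriented: ``Key: value`` headers, a ``Num Peaks:`` count,
    then one ``mz intensity`` pair per line; blank line between records.
    A ``Provenance:`` header overrides the default provenance.
    """
    spectra: list[MS2Spectrum] = []
    header: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    in_peaks = False

    def flush() -> None:
        nonlocal header, peaks, in_peaks
        if header and peaks:
            pmz = header.get("precursormz") or header.get("precursor_mz")
            if pmz is None:
                raise ValueError(f"MSP record {header.get('name', '?')!r} lacks PrecursorMZ")
            spectra.append(
                MS2Spectrum(
                    precursor_mz=float(pmz),
                    precursor_rtime=float(header.get("retentiontime", 0.0)),
                    peaks=peaks,
                    source=f"{os.path.basename(path)}:{header.get('name', '')}",
                    provenance=header.get("provenance", provenance),
                )
            )
        header, peaks, in_peaks = {}, [], False

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            if ":" in line and not in_peaks:
                key, _, value = line.partition(":")
                key = key.strip().lower().replace(" ", "_")
                header[key] = value.strip()
                if key == "num_peaks":
                    in_peaks = True
                continue
            parts = line.replace(",", " ").split()
            if len(parts) >= 2:
                peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return spectra


def library_compound_name(spectrum: MS2Spectrum) -> str:
    """Compound name of a library spectrum (text after the file prefix)."""
    return spectrum.source.partition(":")[2] or spectrum.source


def read_mgf(path: str, provenance: str = "reference_public") -> list[MS2Spectrum]:
    """Read an MGF spectral library via pyteomics."""
    from pyteomics import mgf as pymgf

    spectra = []
    with pymgf.read(path) as reader:
        for spec in reader:
            params = spec.get("params", {})
            pepmass = params.get("pepmass", (None,))
            pmz = pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass
            if pmz is None:
                continue
            rt = params.get("rtinseconds", 0.0)
            mzs = np.asarray(spec["m/z array"], dtype=float)
            intens = np.asarray(spec["intensity array"], dtype=float)
            keep = intens > 0
            spectra.append(
                MS2Spectrum(
                    precursor_mz=float(pmz),
                    precursor_rtime=float(rt),
                    peaks=list(zip(mzs[keep].tolist(), intens[keep].tolist())),
                    source=f"{os.path.basename(path)}:{params.get('title', '')}",
                    provenance=str(params.get("provenance", provenance)),
                )
            )
    return spectra
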