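"""Core data models for LC-MS metabolomics post-processing.

The unit of measurement is the *feature* (an m/z, retention-time signal with
per-sample intensities); degenerate features (isotopologues, adducts) are
grouped into *empirical compounds*, which carry a chainable list of
annotations at Schymanski-style confidence levels. An *experiment* ties
acquisitions, on-disk intermediates and a command log together so that
pipeline stages can be chained and replayed.

Conventions: retention time is in seconds everywhere; an intensity of 0
encodes a missing value (the convention of the upstream preprocessor).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("study", "blank", "pool_qc", "standard", "unknown")
ANNOTATION_LEVELS = ("1a", "1b", "2", "4")

#: ranking of annotation confidence, best first
LEVEL_PRECEDENCE = {"1a": 0, "1b": 1, "2": 2, "4": 3}

MS2_PROVENANCES = ("experimental", "reference_public", "reference_authentic")


@dataclass
class Acquisition:
    """One data file produced by analyzing a sample."""

    name: str
    source_path: str = ""
    sample_type: str = "unknown"
    batch: str | None = None
    extra_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_type:
            self.sample_type = "unknown"
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample_type {self.sample_type!r}; expected one of {SAMPLE_TYPES}"
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Acquisition":
        return cls(
            name=d["name"],
            source_path=d.get("source_path", ""),
            sample_type=d.get("sample_type", "unknown"),
            batch=d.get("batch"),
            extra_tags=dict(d.get("extra_tags", {})),
        )


@dataclass
class AnnotationRecord:
    """One candidate identity for an empirical compound.

    ``level`` follows the Schymanski confidence scheme as used here:
    1a (MS2 match to authentic standard), 1b (m/z + RT match to authentic
    standard), 2 (MS2 match to a public library), 4 (neutral-mass match).
    """

    level: str
    candidate_name: str
    candidate_id: str | None = None
    score: float | None = None
    source: str = ""
    evidence: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ANNOTATION_LEVELS:
            raise ValueError(f"annotation level must be one of {ANNOTATION_LEVELS}")
        if self.level in ("1a", "2") and self.score is None:
            raise ValueError(f"MS2-based level {self.level} annotation requires a score")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnnotationRecord":
        return cls(
            level=d["level"],
            candidate_name=d["candidate_name"],
            candidate_id=d.get("candidate_id"),
            score=d.get("score"),
            source=d.get("source", ""),
            evidence=dict(d.get("evidence", {})),
        )


@dataclass
class IonRelation:
    """Isotopologue/adduct assignment of one member feature.

    ``mass_offset`` is the total offset in Daltons of the observed ion
    relative to the neutral monoisotopic mass M, i.e. for a singly charged
    ion m/z = M + mass_offset.
    """

    isotope_label: str
    adduct_label: str
    charge: int
    mass_offset: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("charge must be nonzero")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "IonRelation":
        return cls(
            isotope_label=d["isotope_label"],
            adduct_label=d["adduct_label"],
            charge=int(d["charge"]),
            mass_offset=float(d["mass_offset"]),
        )


@dataclass
class MS2Spectrum:
    """A centroided fragment spectrum with its precursor coordinates."""

    precursor_mz: float
    precursor_rtime: float
    peaks: list[tuple[float, float]]
    source: str = ""
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if self.provenance not in MS2_PROVENANCES:
            raise ValueError(f"provenance must be one of {MS2_PROVENANCES}")
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError("fragment intensities must be positive")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks], dtype=float)

    def to_dict(self) -> dict[str, Any]:
        return {
            "precursor_mz": self.precursor_mz,
            "precursor_rtime": self.precursor_rtime,
            "peaks": [[m, i] for m, i in self.peaks],
            "source": self.source,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MS2Spectrum":
        return cls(
            precursor_mz=float(d["precursor_mz"]),
            precursor_rtime=float(d["precursor_rtime"]),
            peaks=[(float(m), float(i)) for m, i in d["peaks"]],
            source=d.get("source", ""),
            provenance=d.get("provenance", "experimental"),
        )


@dataclass
class EmpiricalCompound:
    """A group of degenerate features attributed to one tentative compound.

    ``members`` maps each feature id to its ion relation (None when the ion
    species could not be determined, e.g. for singleton features). The
    annotation list is append-only: successive annotation stages chain their
    results without overwriting earlier ones.
    """

    empcpd_id: str
    members: list[tuple[str, IonRelation | None]]
    neutral_mass: float | None = None
    charge_state_mode: str = "pos"
    ms2_spectra: list[MS2Spectrum] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empirical compound must have at least one member")
        ids = [fid for fid, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("member feature_ids must be distinct")
        if self.charge_state_mode not in ("pos", "neg"):
            raise ValueError("charge_state_mode must be 'pos' or 'neg'")

    @property
    def feature_ids(self) -> list[str]:
        return [fid for fid, _ in self.members]

    def sorted_annotations(self) -> list[AnnotationRecord]:
        """Annotations ranked by level precedence (1a > 1b > 2 > 4), then score."""
        return sorted(
            self.annotations,
            key=lambda a: (LEVEL_PRECEDENCE[a.level], -(a.score if a.score is not None else 0.0)),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "neutral_mass": self.neutral_mass,
            "charge_state_mode": self.charge_state_mode,
            "members": [
                {"feature_id": fid, "ion_relation": ion.to_dict() if ion else None}
                for fid, ion in self.members
            ],
            "ms2_spectra": [s.to_dict() for s in self.ms2_spectra],
            "annotations": [a.to_dict() for a in self.annotations],
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, empcpd_id: str, d: Mapping[str, Any]) -> "EmpiricalCompound":
        return cls(
            empcpd_id=empcpd_id,
            members=[
                (
                    m["feature_id"],
                    IonRelation.from_dict(m["ion_relation"]) if m.get("ion_relation") else None,
                )
                for m in d["members"]
            ],
            neutral_mass=d.get("neutral_mass"),
            charge_state_mode=d.get("charge_state_mode", "pos"),
            ms2_spectra=[MS2Spectrum.from_dict(s) for s in d.get("ms2_spectra", [])],
            annotations=[AnnotationRecord.from_dict(a) for a in d.get("annotations", [])],
            flags=list(d.get("flags", [])),
        )


@dataclass
class CompoundRecord:
    """A database entry: a metabolite or xenobiotic with known neutral mass."""

    name: str
    neutral_mass: float
    formula: str | None = None
    identifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")


@dataclass
class StandardRecord:
    """An authentic chemical standard observed at a known m/z and RT."""

    name: str
    mz: float
    rtime: float
    mode: str = "pos"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.rtime < 0:
            raise ValueError("rtime must be nonnegative")
        if self.mode not in ("pos", "neg"):
            raise ValueError("mode must be 'pos' or 'neg'")


class FeatureTable:
    """A feature-by-sample intensity matrix with m/z and RT per feature.

    Backed by a pandas DataFrame indexed by feature id with columns
    ``mz``, ``rtime``, the sample columns, and any extra (opaque) metadata
    columns preserved from the input file.
    """

    METADATA_COLUMNS = ("mz", "rtime")

    def __init__(self, moniker: str, frame: pd.DataFrame, sample_columns: list[str]):
        if not sample_columns:
            raise ValueError("sample_columns must be nonempty")
        missing = [c for c in ("mz", "rtime", *sample_columns) if c not in frame.columns]
        if missing:
            raise ValueError(f"frame is missing columns: {missing}")
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if len(frame) and (frame["mz"] <= 0).any():
            bad = frame.index[frame["mz"] <= 0].tolist()
            raise ValueError(f"nonpositive m/z for features: {bad}")
        if len(frame) and (frame[sample_columns].to_numpy(dtype=float) < 0).any():
            raise ValueError("intensities must be nonnegative")
        self.moniker = moniker
        self.frame = frame
        self.sample_columns = list(sample_columns)

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_features(self) -> int:
        return len(self.frame)

    @property
    def n_samples(self) -> int:
        return len(self.sample_columns)

    @property
    def mz(self) -> pd.Series:
        return self.frame["mz"]

    @property
    def rtime(self) -> pd.Series:
        return self.frame["rtime"]

    @property
    def intensities(self) -> pd.DataFrame:
        """Features x samples intensity matrix (0 = missing)."""
        return self.frame[self.sample_columns]

    @property
    def extra_columns(self) -> list[str]:
        reserved = set(self.METADATA_COLUMNS) | set(self.sample_columns)
        return [c for c in self.frame.columns if c not in reserved]

    def with_frame(
        self,
        frame: pd.DataFrame,
        sample_columns: list[str] | None = None,
        moniker: str | None = None,
    ) -> "FeatureTable":
        return FeatureTable(
            moniker if moniker is not None else self.moniker,
            frame,
            sample_columns if sample_columns is not None else self.sample_columns,
        )

    def copy(self, moniker: str | None = None) -> "FeatureTable":
        return self.with_frame(self.frame.copy(), moniker=moniker)

    @classmethod
    def from_arrays(
        cls,
        moniker: str,
        feature_ids: Iterable[str],
        mz: Iterable[float],
        rtime: Iterable[float],
        intensities: np.ndarray | pd.DataFrame,
        sample_columns: list[str],
    ) -> "FeatureTable":
        frame = pd.DataFrame({"mz": list(mz), "rtime": list(rtime)}, index=list(feature_ids))
        frame.index.name = "feature_id"
        inten = np.asarray(intensities, dtype=float)
        for j, col in enumerate(sample_columns):
            frame[col] = inten[:, j]
        return cls(moniker, frame, list(sample_columns))

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.sample_columns == other.sample_columns
            and list(self.frame.columns) == list(other.frame.columns)
            and list(self.frame.index) == list(other.frame.index)
            and self.frame.equals(other.frame)
        )


class Experiment:
    """Acquisitions plus an on-disk registry of named intermediates.

    Feature tables and empirical-compound sets are stored under monikers so
    pipeline stages can chain: each stage reads an input moniker and writes
    an output moniker. Every operation is recorded in an append-only,
    timestamped command log.
    """

    def __init__(self, directory: str, acquisitions: list[Acquisition] | None = None):
        self.directory = str(directory)
        self.acquisitions: list[Acquisition] = list(acquisitions or [])
        names = [a.name for a in self.acquisitions]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate acquisition names: {dups}")
        self.table_registry: dict[str, str] = {}
        self.empcpd_registry: dict[str, str] = {}
        self.command_log: list[dict[str, Any]] = []

    # -- acquisition lookups ------------------------------------------------
    def acquisition_names(self, sample_type: str | None = None) -> list[str]:
        return [
            a.name
            for a in self.acquisitions
            if sample_type is None or a.sample_type == sample_type
        ]

    def batches(self) -> dict[str, str]:
        """Map acquisition name -> batch label ('' when unassigned)."""
        return {a.name: (a.batch or "") for a in self.acquisitions}

    # -- provenance ---------------------------------------------------------
    def log_step(self, command_text: str, params: Mapping[str, Any] | None = None) -> "Experiment":
        entry = {
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "command": command_text,
            "params": dict(params or {}),
        }
        self.command_log.append(entry)
        return self

    # -- registry -----------------------------------------------------------
    def _subdir(self, name: str) -> str:
        path = os.path.join(self.directory, name)
        os.makedirs(path, exist_ok=True)
        return path

    def store_table(self, table: FeatureTable, moniker: str) -> str:
        from . import io  # local import to avoid a cycle

        path = os.path.join(self._subdir("tables"), f"{moniker}.tsv")
        io.write_feature_table(table, path)
        self.table_registry[moniker] = os.path.relpath(path, self.directory)
        return path

    def get_table(self, moniker: str) -> FeatureTable:
        from . import io

        if moniker not in self.table_registry:
            raise KeyError(
                f"no feature table registered under {moniker!r}; "
                f"available: {sorted(self.table_registry)}"
            )
        path = os.path.join(self.directory, self.table_registry[moniker])
        return io.read_feature_table(path, moniker=moniker)

    def store_empcpds(self, empcpds: list[EmpiricalCompound], moniker: str) -> str:
        from . import io

        path = os.path.join(self._subdir("empcpds"), f"{moniker}.json")
        io.save_empcpds(empcpds, path)
        self.empcpd_registry[moniker] = os.path.relpath(path, self.directory)
        return path

    def get_empcpds(self, moniker: str) -> list[EmpiricalCompound]:
        from . import io

        if moniker not in self.empcpd_registry:
            raise KeyError(
                f"no empirical compounds registered under {moniker!r}; "
                f"available: {sorted(self.empcpd_registry)}"
            )
        path = os.path.join(self.directory, self.empcpd_registry[moniker])
        return io.load_empcpds(path)

    # -- persistence ---------------------------------------------------------
    STATE_FILENAME = "experiment.json"

    def save(self) -> str:
        os.makedirs(self.directory, exist_ok=True)
        path = os.path.join(self.directory, self.STATE_FILENAME)
        doc = {
            "acquisitions": [a.to_dict() for a in self.acquisitions],
            "table_registry": self.table_registry,
            "empcpd_registry": self.empcpd_registry,
            "command_log": self.command_log,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
        return path

    @classmethod
    def load(cls, directory: str) -> "Experiment":
        path = os.path.join(str(directory), cls.STATE_FILENAME)
        with open(path) as fh:
            doc = json.load(fh)
        exp = cls(str(directory), [Acquisition.from_dict(a) for a in doc["acquisitions"]])
        exp.table_registry = dict(doc.get("table_registry", {}))
        exp.empcpd_registry = dict(doc.get("empcpd_registry", {}))
        exp.command_log = list(doc.get("command_log", []))
        return exp
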