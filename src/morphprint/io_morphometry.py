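"""Morphometry table model and flat-file I/O.

The canonical interchange format is a long-format TSV with one measurement
per row::

    subject_id  group  age  sex  cohort_tag  icv  region  hemisphere  metric  value

Hemisphere is the literal token ``none`` for midline/global regions.
FreeSurfer stats files (aseg.stats, ?h.aparc.stats, hippocampal-subfield
and amygdalar-nuclei volume tables) are supported as convenience importers;
everything downstream consumes the long table.

Tables are sparse: a missing (subject, region, hemisphere, metric) cell is
allowed, and downstream group statistics use pairwise-complete subjects per
key.  Skipped data are always logged, never silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import registry as reg
from .errors import (
    DuplicateKeyError,
    InconsistentDemographicsError,
    MissingICVError,
    ParseError,
    ReconciliationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

GROUPS = ("control", "AD", "exposed")
SEXES = ("male", "female", "unknown")
HEMISPHERES = ("left", "right", "none")

PROV_AGE_CORRECTED = "age_corrected"
PROV_NORMALIZED = "normalized"

SUBJECT_COLUMNS = ["subject_id", "group", "age", "sex", "cohort_tag", "icv"]
DATA_COLUMNS = ["subject_id", "region", "hemisphere", "metric", "value"]
LONG_COLUMNS = SUBJECT_COLUMNS + DATA_COLUMNS[1:]


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics for one subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    cohort_tag: str
    icv: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"bad group {self.group!r} for {self.subject_id!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"bad sex {self.sex!r} for {self.subject_id!r}")
        if not self.age > 0:
            raise ValidationError(f"age must be > 0 for {self.subject_id!r}")
        if not self.icv > 0:
            raise ValidationError(f"icv must be > 0 for {self.subject_id!r}")


@dataclass
class MorphometryTable:
    """Per-subject, per-region, per-hemisphere, per-metric measurements.

    ``subjects`` is indexed by subject_id with columns group/age/sex/
    cohort_tag/icv; ``data`` is a long DataFrame with DATA_COLUMNS.
    ``provenance`` is the subset of {age_corrected, normalized} stages the
    values have passed through (empty = raw).
    """

    subjects: pd.DataFrame
    data: pd.DataFrame
    provenance: frozenset[str] = frozenset()

    def __post_init__(self):
        self.subjects = self.subjects[["group", "age", "sex", "cohort_tag", "icv"]]
        self.data = self.data[DATA_COLUMNS].reset_index(drop=True)
        self.provenance = frozenset(self.provenance)
        if PROV_NORMALIZED in self.provenance and PROV_AGE_CORRECTED not in self.provenance:
            raise ValidationError("normalized tables must also be age_corrected")
        unknown = set(self.data["subject_id"]) - set(self.subjects.index)
        if unknown:
            raise ValidationError(f"measurements for unregistered subjects: {sorted(unknown)[:5]}")

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        subjects: list[SubjectRecord],
        data: pd.DataFrame,
        provenance: frozenset[str] = frozenset(),
    ) -> "MorphometryTable":
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject_id")
        frame = pd.DataFrame(
            {
                "group": [s.group for s in subjects],
                "age": [s.age for s in subjects],
                "sex": [s.sex for s in subjects],
                "cohort_tag": [s.cohort_tag for s in subjects],
                "icv": [s.icv for s in subjects],
            },
            index=pd.Index(ids, name="subject_id"),
        )
        return cls(subjects=frame, data=data, provenance=provenance)

    # -- accessors -----------------------------------------------------------

    @property
    def is_raw(self) -> bool:
        return not self.provenance

    def subject_ids(self) -> list[str]:
        return list(self.subjects.index)

    def subject_records(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(subject_id=sid, **row)
            for sid, row in self.subjects.to_dict("index").items()
        ]

    def n_subjects(self) -> int:
        return len(self.subjects)

    def select_group(self, group: str) -> "MorphometryTable":
        ids = self.subjects.index[self.subjects["group"] == group]
        return self.select_subjects(list(ids))

    def select_subjects(self, ids: list[str]) -> "MorphometryTable":
        missing = set(ids) - set(self.subjects.index)
        if missing:
            raise ValidationError(f"unknown subjects: {sorted(missing)[:5]}")
        return MorphometryTable(
            subjects=self.subjects.loc[ids].copy(),
            data=self.data[self.data["subject_id"].isin(ids)].copy(),
            provenance=self.provenance,
        )

    def merged(self) -> pd.DataFrame:
        """Long data joined with demographics (one row per measurement)."""
        return self.data.join(self.subjects, on="subject_id")

    def with_data(self, data: pd.DataFrame, provenance: frozenset[str]) -> "MorphometryTable":
        return MorphometryTable(subjects=self.subjects.copy(), data=data, provenance=provenance)

    def equals(self, other: "MorphometryTable") -> bool:
        if self.provenance != other.provenance:
            return False
        a = self.subjects.sort_index()
        b = other.subjects.sort_index()
        if not a.equals(b):
            return False
        key = ["subject_id", "region", "hemisphere", "metric"]
        da = self.data.sort_values(key).reset_index(drop=True)
        db = other.data.sort_values(key).reset_index(drop=True)
        return da.equals(db)

    # -- validation ----------------------------------------------------------

    def validate(self, registry: reg.RegionRegistry) -> None:
        """Check every measurement key against the registry and value ranges."""
        bad: list[str] = []
        for (region, hemisphere, metric), _ in self.data.groupby(
            ["region", "hemisphere", "metric"], sort=False
        ):
            desc = registry.lookup(region)  # raises UnknownRegionError
            if metric not in desc.metrics:
                bad.append(f"{region}/{metric}: metric not measured on this region")
            if desc.hemispheric and hemisphere not in ("left", "right"):
                bad.append(f"{region}/{hemisphere}: hemispheric region needs left/right")
            if not desc.hemispheric and hemisphere != "none":
                bad.append(f"{region}/{hemisphere}: midline region must use hemisphere 'none'")
        if bad:
            raise ValidationError("registry validation failed: " + "; ".join(bad[:10]))
        dup = self.data.duplicated(["subject_id", "region", "hemisphere", "metric"])
        if dup.any():
            rows = self.data[dup].head(3).to_dict("records")
            raise DuplicateKeyError(f"duplicate measurement keys, e.g. {rows}")
        if self.is_raw:
            thick = self.data.loc[self.data["metric"] == reg.THICKNESS, "value"]
            if ((thick <= 0) | (thick >= 10)).any():
                raise ValidationError("raw thickness values must lie in (0, 10) mm")
            vol = self.data.loc[self.data["metric"] == reg.VOLUME, "value"]
            if (vol <= 0).any():
                raise ValidationError("raw volumes must be positive")


# ---------------------------------------------------------------------------
# Long-format TSV
# ---------------------------------------------------------------------------


def _parse_float(token: str, what: str, path: str, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"malformed {what} {token!r}", path, lineno) from None
    if not math.isfinite(value):
        raise ParseError(f"non-finite {what} {token!r}", path, lineno)
    return value


def read_long_tsv(
    path: str | Path, registry: reg.RegionRegistry | None = None
) -> MorphometryTable:
    """Read the canonical long-format TSV into a validated table.

    Region labels are canonicalized against the registry (default registry
    when none is given); unknown regions, malformed values, duplicate keys
    and inconsistent per-subject demographics are rejected.
    """
    registry = registry or reg.build_default_registry()
    path = Path(path)
    provenance: set[str] = set()
    subjects: dict[str, SubjectRecord] = {}
    rows: list[tuple] = []
    seen: set[tuple] = set()
    with open(path, encoding="utf-8") as fh:
        lineno = 0
        header: list[str] | None = None
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("provenance:"):
                    stages = body.split(":", 1)[1].strip()
                    provenance = {
                        s.strip() for s in stages.split(",") if s.strip() and s.strip() != "raw"
                    }
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header != LONG_COLUMNS:
                    raise ParseError(
                        f"bad header: expected {LONG_COLUMNS}, got {header}", str(path), lineno
                    )
                continue
            if len(parts) != len(LONG_COLUMNS):
                raise ParseError(
                    f"expected {len(LONG_COLUMNS)} columns, got {len(parts)}", str(path), lineno
                )
            rec = dict(zip(LONG_COLUMNS, parts))
            age = _parse_float(rec["age"], "age", str(path), lineno)
            icv = _parse_float(rec["icv"], "icv", str(path), lineno)
            value = _parse_float(rec["value"], "value", str(path), lineno)
            try:
                subject = SubjectRecord(
                    subject_id=rec["subject_id"],
                    group=rec["group"],
                    age=age,
                    sex=rec["sex"],
                    cohort_tag=rec["cohort_tag"],
                    icv=icv,
                )
            except ValidationError as exc:
                raise ParseError(str(exc), str(path), lineno) from None
            prior = subjects.get(subject.subject_id)
            if prior is None:
                subjects[subject.subject_id] = subject
            elif prior != subject:
                raise InconsistentDemographicsError(
                    f"subject {subject.subject_id!r} has conflicting demographics "
                    f"(line {lineno} of {path})"
                )
            desc = registry.lookup(rec["region"])
            if rec["hemisphere"] not in HEMISPHERES:
                raise ParseError(f"bad hemisphere {rec['hemisphere']!r}", str(path), lineno)
            key = (subject.subject_id, desc.name, rec["hemisphere"], rec["metric"])
            if key in seen:
                raise DuplicateKeyError(f"duplicate row for {key} (line {lineno} of {path})")
            seen.add(key)
            rows.append((subject.subject_id, desc.name, rec["hemisphere"], rec["metric"], value))
    if header is None:
        raise ParseError("empty file (no header)", str(path), 1)
    data = pd.DataFrame(rows, columns=DATA_COLUMNS)
    table = MorphometryTable.from_records(
        list(subjects.values()), data, provenance=frozenset(provenance)
    )
    table.validate(registry)
    return table


def write_long_tsv(table: MorphometryTable, path: str | Path) -> None:
    """Write a table as the canonical long TSV (full-precision values).

    Rows are sorted by (subject_id, region, hemisphere, metric) and floats
    are written with ``repr`` so a read-back round trip is bit-exact.
    """
    merged = table.merged().sort_values(["subject_id", "region", "hemisphere", "metric"])
    stages = sorted(table.provenance) or ["raw"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# morphprint long-format morphometry v1\n")
        fh.write(f"# provenance: {','.join(stages)}\n")
        fh.write("\t".join(LONG_COLUMNS) + "\n")
        for row in merged.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.subject_id,
                        row.group,
                        repr(float(row.age)),
                        row.sex,
                        row.cohort_tag,
                        repr(float(row.icv)),
                        row.region,
                        row.hemisphere,
                        row.metric,
                        repr(float(row.value)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FreeSurfer stats dialects
# ---------------------------------------------------------------------------

# aseg "# Measure" ids ingested as regions (hemisphere inferred from lh/rh
# prefix) or used for ICV.
_ICV_MEASURE = "EstimatedTotalIntraCranialVol"
_MEASURE_REGIONS = {
    "lhCortexVol": ("Cortex", "left"),
    "rhCortexVol": ("Cortex", "right"),
    "lhCerebralWhiteMatterVol": ("Cerebral white matter", "left"),
    "rhCerebralWhiteMatterVol": ("Cerebral white matter", "right"),
    "BrainSegVol": ("Brain Seg Vol", "none"),
    "TotalGrayVol": ("Total Gray Vol", "none"),
}


def _strip_laterality(label: str) -> tuple[str, str]:
    for prefix, hemi in (("Left-", "left"), ("Right-", "right"), ("lh.", "left"), ("rh.", "right")):
        if label.startswith(prefix):
            return label[len(prefix):], hemi
    return label, "none"


def _parse_aseg(path: Path, registry: reg.RegionRegistry) -> tuple[float, list[tuple]]:
    """Return (icv, rows) where rows are (region, hemisphere, 'volume', value)."""
    icv: float | None = None
    rows: list[tuple] = []
    col_headers: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# Measure"):
                parts = [p.strip() for p in line[len("# Measure"):].split(",")]
                if len(parts) < 4:
                    continue
                measure_id, value_token = parts[1], parts[-2]
                if measure_id == _ICV_MEASURE or parts[0] == _ICV_MEASURE:
                    icv = _parse_float(value_token, "ICV", str(path), lineno)
                elif measure_id in _MEASURE_REGIONS:
                    region, hemi = _MEASURE_REGIONS[measure_id]
                    value = _parse_float(value_token, "measure", str(path), lineno)
                    rows.append((region, hemi, reg.VOLUME, value))
                continue
            if line.startswith("# ColHeaders"):
                col_headers = line[len("# ColHeaders"):].split()
                continue
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if col_headers is not None:
                try:
                    vol_idx = col_headers.index("Volume_mm3")
                    name_idx = col_headers.index("StructName")
                except ValueError:
                    raise ParseError("aseg table lacks Volume_mm3/StructName", str(path), lineno)
            else:
                vol_idx, name_idx = 3, 4
            if len(parts) <= max(vol_idx, name_idx):
                raise ParseError("short aseg table row", str(path), lineno)
            label = parts[name_idx]
            value = _parse_float(parts[vol_idx], "volume", str(path), lineno)
            stripped, hemi = _strip_laterality(label)
            if stripped not in registry:
                logger.warning("%s:%d: skipping unregistered structure %r", path, lineno, label)
                continue
            desc = registry.lookup(stripped)
            rows.append((desc.name, hemi if desc.hemispheric else "none", reg.VOLUME, value))
    if icv is None:
        raise MissingICVError(f"{path}: no {_ICV_MEASURE} measure line")
    return icv, rows


def _parse_aparc(path: Path, registry: reg.RegionRegistry) -> list[tuple]:
    """Parse a ?h.aparc.stats file into (region, hemi, metric, value) rows."""
    hemi: str | None = None
    col_headers: list[str] | None = None
    rows: list[tuple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# hemi"):
                token = line.split()[-1]
                hemi = {"lh": "left", "rh": "right"}.get(token)
                continue
            if line.startswith("# ColHeaders"):
                col_headers = line[len("# ColHeaders"):].split()
                continue
            if line.startswith("#") or not line.strip():
                continue
            if hemi is None:
                raise ParseError("aparc table row before '# hemi' line", str(path), lineno)
            parts = line.split()
            if col_headers is not None:
                try:
                    name_idx = col_headers.index("StructName")
                    vol_idx = col_headers.index("GrayVol")
                    thick_idx = col_headers.index("ThickAvg")
                except ValueError:
                    raise ParseError("aparc table lacks expected columns", str(path), lineno)
            else:
                name_idx, vol_idx, thick_idx = 0, 3, 4
            if len(parts) <= max(name_idx, vol_idx, thick_idx):
                raise ParseError("short aparc table row", str(path), lineno)
            label = parts[name_idx]
            if label not in registry:
                logger.warning("%s:%d: skipping unregistered parcel %r", path, lineno, label)
                continue
            desc = registry.lookup(label)
            rows.append((desc.name, hemi, reg.VOLUME, _parse_float(parts[vol_idx], "GrayVol", str(path), lineno)))
            rows.append((desc.name, hemi, reg.THICKNESS, _parse_float(parts[thick_idx], "ThickAvg", str(path), lineno)))
    return rows


def _parse_label_value(path: Path, hemi: str, registry: reg.RegionRegistry) -> list[tuple]:
    """Parse a two-column label/value table (subfield or nucleus volumes)."""
    rows: list[tuple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"expected 'label value', got {len(parts)} tokens", str(path), lineno)
            label, token = parts
            if label not in registry:
                logger.warning("%s:%d: skipping unregistered label %r", path, lineno, label)
                continue
            desc = registry.lookup(label)
            rows.append((desc.name, hemi, reg.VOLUME, _parse_float(token, "volume", str(path), lineno)))
    return rows


def _classify_stats_file(path: Path) -> tuple[str, str | None]:
    """Map a stats filename to (kind, hemisphere)."""
    name = path.name
    if name == "aseg.stats":
        return "aseg", None
    if name.endswith("aparc.stats"):
        return "aparc", {"lh": "left", "rh": "right"}.get(name.split(".")[0])
    lowered = name.lower()
    hemi = "left" if name.startswith("lh.") else "right" if name.startswith("rh.") else None
    if "hipposfvolumes" in lowered:
        return "hipposf", hemi
    if "amygnucvolumes" in lowered:
        return "amygnuc", hemi
    return "unknown", None


def read_demographics_tsv(path: str | Path) -> pd.DataFrame:
    """Read a demographics TSV (subject_id, group, age, sex, cohort_tag)."""
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, comment="#")
    required = {"subject_id", "group", "age", "sex", "cohort_tag"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"demographics table missing columns {sorted(missing)}", str(path))
    if frame["subject_id"].duplicated().any():
        raise InconsistentDemographicsError(f"duplicate subject_id in {path}")
    return frame.set_index("subject_id")


def read_freesurfer_stats(
    subject_dir_or_files: str | Path | dict[str, list[str | Path]],
    demographics: str | Path | pd.DataFrame,
    registry: reg.RegionRegistry | None = None,
) -> MorphometryTable:
    """Merge FreeSurfer stats outputs across files into a raw table.

    ``subject_dir_or_files`` is either a root directory whose immediate
    subdirectories are subject ids (stats files found in ``<subj>/`` or
    ``<subj>/stats/``) or an explicit mapping subject_id -> list of files.
    ICV comes from each subject's aseg.stats; demographics are supplied
    separately (TSV path or DataFrame) and must cover exactly the subjects
    with stats files.
    """
    registry = registry or reg.build_default_registry()
    if isinstance(demographics, (str, Path)):
        demographics = read_demographics_tsv(demographics)

    if isinstance(subject_dir_or_files, dict):
        per_subject = {sid: [Path(p) for p in files] for sid, files in subject_dir_or_files.items()}
    else:
        root = Path(subject_dir_or_files)
        per_subject = {}
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            files = [p for p in sub.glob("*") if p.is_file()]
            stats_dir = sub / "stats"
            if stats_dir.is_dir():
                files += [p for p in stats_dir.glob("*") if p.is_file()]
            per_subject[sub.name] = files

    stats_ids = set(per_subject)
    demo_ids = set(demographics.index)
    if stats_ids != demo_ids:
        raise ReconciliationError(
            f"stats-only subjects: {sorted(stats_ids - demo_ids)[:5]}; "
            f"demographics-only subjects: {sorted(demo_ids - stats_ids)[:5]}"
        )

    subjects: list[SubjectRecord] = []
    all_rows: list[tuple] = []
    for sid in sorted(per_subject):
        icv: float | None = None
        rows: list[tuple] = []
        for path in per_subject[sid]:
            kind, hemi = _classify_stats_file(path)
            if kind == "aseg":
                icv, aseg_rows = _parse_aseg(path, registry)
                rows += aseg_rows
            elif kind == "aparc":
                rows += _parse_aparc(path, registry)
            elif kind in ("hipposf", "amygnuc"):
                if hemi is None:
                    raise ParseError("cannot infer hemisphere from filename", str(path))
                rows += _parse_label_value(path, hemi, registry)
            else:
                logger.warning("skipping unrecognized stats file %s", path)
        if icv is None:
            raise MissingICVError(f"subject {sid!r}: no aseg.stats with ICV among inputs")
        demo = demographics.loc[sid]
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=str(demo["group"]),
                age=float(demo["age"]),
                sex=str(demo["sex"]),
                cohort_tag=str(demo["cohort_tag"]),
                icv=icv,
            )
        )
        all_rows += [(sid, *row) for row in rows]

    data = pd.DataFrame(all_rows, columns=DATA_COLUMNS)
    table = MorphometryTable.from_records(subjects, data)
    table.validate(registry)
    return table
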