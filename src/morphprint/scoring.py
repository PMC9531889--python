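"""Individual-subject scoring against a fingerprint.

Each subject's normalized, age-corrected values are z-scored against the
control mean/SD per fingerprint key.  A fingerprint entry is flagged when
the z-score exceeds the threshold in the entry's disease direction in
EITHER hemisphere (single test for midline entries); deviations in the
anti-disease direction never count.  The per-subject outlier count is
compared against a cutoff of control-count mean + 2 control-count SDs to
label subjects at risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    DegenerateStatisticsError,
    MissingDataError,
    ValidationError,
)
from .fingerprint import ATROPHY, Fingerprint
from .io_morphometry import PROV_NORMALIZED, MorphometryTable

logger = logging.getLogger(__name__)


@dataclass
class ControlReference:
    """Control mean/SD of normalized values per fingerprint key.

    ``params`` is indexed by (region, hemisphere, metric) with columns
    mean, sd, n; keys cover exactly the hemispheres of the fingerprint's
    entries.
    """

    params: pd.DataFrame

    def __post_init__(self):
        self.params = self.params[["mean", "sd", "n"]]
        if (self.params["sd"] <= 0).any():
            bad = list(self.params.index[self.params["sd"] <= 0][:3])
            raise DegenerateReferenceError(f"zero/negative control SD for {bad}")

    def to_tsv(self, path: str | Path) -> None:
        out = self.params.reset_index()
        for col in ("mean", "sd"):
            out[col] = out[col].map(lambda v: repr(float(v)))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ControlReference":
        frame = pd.read_csv(path, sep="\t")
        params = frame.set_index(["region", "hemisphere", "metric"])[["mean", "sd", "n"]]
        return cls(params=params)


def build_control_reference(
    controls: MorphometryTable, fp: Fingerprint
) -> ControlReference:
    """Compute per-key control mean and sample SD for a fingerprint.

    Uses pairwise-complete controls per key.  A key with zero variance (or
    fewer than 2 controls) raises :class:`DegenerateReferenceError`.
    """
    if PROV_NORMALIZED not in controls.provenance:
        raise ValidationError("control reference requires a normalized table")
    if len(fp) == 0:
        raise ValidationError("cannot build a reference for an empty fingerprint")
    wanted = [
        (e.region, s.hemisphere, e.metric) for e in fp.entries for s in e.stats()
    ]
    grouped = controls.data.groupby(["region", "hemisphere", "metric"])["value"]
    stats = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    idx = pd.MultiIndex.from_tuples(wanted, names=["region", "hemisphere", "metric"])
    missing = idx.difference(stats.index)
    if len(missing):
        raise MissingDataError(f"controls lack fingerprint keys, e.g. {list(missing[:3])}")
    params = stats.loc[idx]
    params["n"] = params["n"].astype(int)
    if params["sd"].isna().any() or (params["sd"] <= 0).any():
        bad = list(params.index[(params["sd"].isna()) | (params["sd"] <= 0)][:3])
        raise DegenerateReferenceError(f"degenerate control reference for {bad}")
    return ControlReference(params=params)


@dataclass
class OutlierProfile:
    """Region-wise z-scores and outlier counts for one subject.

    ``records`` has one row per fingerprint entry per hemisphere with
    columns region, metric, hemisphere, direction, z, flagged (entry-level
    flag repeated on both hemisphere rows for convenience is NOT done:
    ``flagged`` marks the hemisphere that breached the threshold; the
    entry-level flag is their OR).
    """

    subject_id: str
    records: pd.DataFrame
    outlier_count: int
    region_count: int
    n_missing: int = 0

    def flagged_entries(self) -> list[tuple[str, str]]:
        flagged = self.records.loc[self.records["flagged"], ["region", "metric"]]
        return sorted(set(map(tuple, flagged.to_numpy())))


def score_subject(
    table: MorphometryTable,
    subject_id: str,
    fp: Fingerprint,
    ref: ControlReference,
    z_threshold: float = 2.0,
    strict: bool = False,
) -> OutlierProfile:
    """Score one subject of a normalized table against a fingerprint.

    An entry is flagged iff the direction-signed z exceeds ``z_threshold``
    in at least one hemisphere: z < -threshold for atrophy entries,
    z > +threshold for dilation entries.  Missing keys are treated as
    unflagged with a log message (``strict=True`` errors instead).

    ``outlier_count`` counts flagged region x metric entries;
    ``region_count`` counts distinct flagged regions.
    """
    if PROV_NORMALIZED not in table.provenance:
        raise ValidationError("scoring requires a normalized table")
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be positive")
    sub = table.data[table.data["subject_id"] == subject_id]
    if subject_id not in table.subjects.index:
        raise ValidationError(f"unknown subject {subject_id!r}")
    values = sub.set_index(["region", "hemisphere", "metric"])["value"]

    rows = []
    n_missing = 0
    flagged_entries: set[tuple[str, str]] = set()
    for entry in fp.entries:
        for stat in entry.stats():
            key = (entry.region, stat.hemisphere, entry.metric)
            mean, sd = ref.params.loc[key, "mean"], ref.params.loc[key, "sd"]
            if key in values.index:
                z = float((values.loc[key] - mean) / sd)
                if entry.direction == ATROPHY:
                    hit = z < -z_threshold
                else:
                    hit = z > z_threshold
            else:
                n_missing += 1
                if strict:
                    raise MissingDataError(f"subject {subject_id!r} missing key {key}")
                logger.info("subject %s missing %s; treated as unflagged", subject_id, key)
                z, hit = np.nan, False
            if hit:
                flagged_entries.add((entry.region, entry.metric))
            rows.append(
                {
                    "region": entry.region,
                    "metric": entry.metric,
                    "hemisphere": stat.hemisphere,
                    "direction": entry.direction,
                    "z": z,
                    "flagged": bool(hit),
                }
            )
    records = pd.DataFrame(
        rows, columns=["region", "metric", "hemisphere", "direction", "z", "flagged"]
    )
    return OutlierProfile(
        subject_id=subject_id,
        records=records,
        outlier_count=len(flagged_entries),
        region_count=len({r for r, _ in flagged_entries}),
        n_missing=n_missing,
    )


def score_cohort(
    table: MorphometryTable,
    fp: Fingerprint,
    ref: ControlReference,
    z_threshold: float = 2.0,
    strict: bool = False,
    leave_one_out: bool = False,
) -> list[OutlierProfile]:
    """Score every subject in a table (vectorized across subjects).

    ``leave_one_out`` is meant for self-scoring the reference controls: each
    subject's z uses the control mean/SD with that subject's own value
    removed, undoing the shrinkage that naive self-scoring introduces.  It
    assumes the scored table IS the table the reference was built from.
    """
    if PROV_NORMALIZED not in table.provenance:
        raise ValidationError("scoring requires a normalized table")
    if z_threshold <= 0:
        raise ValidationError("z_threshold must be positive")

    key_cols = ["region", "hemisphere", "metric"]
    wanted = pd.DataFrame(
        [(e.region, s.hemisphere, e.metric, e.direction) for e in fp.entries for s in e.stats()],
        columns=key_cols + ["direction"],
    )
    data = table.data.merge(wanted, on=key_cols, how="inner")
    idx = pd.MultiIndex.from_frame(data[key_cols])
    mean = ref.params["mean"].reindex(idx).to_numpy(float)
    sd = ref.params["sd"].reindex(idx).to_numpy(float)
    value = data["value"].to_numpy(float)
    if leave_one_out:
        n = ref.params["n"].reindex(idx).to_numpy(float)
        if (n < 4).any():
            raise DegenerateStatisticsError("leave-one-out needs >= 4 controls per key")
        loo_mean = (n * mean - value) / (n - 1)
        ss = (n - 1) * sd**2 - (n / (n - 1)) * (value - mean) ** 2
        loo_var = np.maximum(ss, 0.0) / (n - 2)
        if (loo_var <= 0).any():
            raise DegenerateStatisticsError("degenerate leave-one-out variance")
        mean, sd = loo_mean, np.sqrt(loo_var)
    data = data.assign(z=(value - mean) / sd)
    atrophy = (data["direction"] == ATROPHY).to_numpy()
    z = data["z"].to_numpy(float)
    data = data.assign(flagged=np.where(atrophy, z < -z_threshold, z > z_threshold))

    profiles = []
    expected_per_subject = len(wanted)
    by_subject = dict(list(data.groupby("subject_id", sort=False)))
    for sid in table.subjects.index:
        sub = by_subject.get(sid)
        if sub is None:
            sub = data.iloc[0:0]
        present = len(sub)
        n_missing = expected_per_subject - present
        if n_missing:
            if strict:
                raise MissingDataError(
                    f"subject {sid!r} missing {n_missing} fingerprint keys"
                )
            logger.info("subject %s missing %d fingerprint keys", sid, n_missing)
        flagged = sub.loc[sub["flagged"], ["region", "metric"]]
        pairs = set(map(tuple, flagged.to_numpy()))
        profiles.append(
            OutlierProfile(
                subject_id=sid,
                records=sub[["region", "metric", "hemisphere", "direction", "z", "flagged"]]
                .reset_index(drop=True),
                outlier_count=len(pairs),
                region_count=len({r for r, _ in pairs}),
                n_missing=n_missing,
            )
        )
    return profiles


def risk_cutoff(control_counts) -> float:
    """Cutoff = mean + 2 * sample SD of the control outlier counts.

    Degenerate (zero-variance) control counts give cutoff = mean, so any
    case strictly above the common control count is flagged.
    """
    counts = np.asarray(list(control_counts), float)
    if len(counts) < 3:
        raise DegenerateStatisticsError("need >= 3 control counts for a cutoff")
    return float(counts.mean() + 2.0 * counts.std(ddof=1))


@dataclass
class RiskClassification:
    """Cohort-level at-risk classification at the mean+2SD cutoff."""

    cutoff: float
    cases: pd.DataFrame       # subject_id, outlier_count, at_risk
    controls: pd.DataFrame    # subject_id, outlier_count, at_risk
    n: int = field(init=False)
    n_at_risk: int = field(init=False)
    percent_at_risk: float = field(init=False)

    def __post_init__(self):
        self.n = len(self.cases)
        self.n_at_risk = int(self.cases["at_risk"].sum())
        self.percent_at_risk = 100.0 * self.n_at_risk / self.n if self.n else float("nan")

    def summary(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n": self.n,
            "n_at_risk": self.n_at_risk,
            "percent_at_risk": self.percent_at_risk,
            "control_n": len(self.controls),
            "control_n_at_risk": int(self.controls["at_risk"].sum()),
        }


def classify_cohort(
    profiles_cases: list[OutlierProfile],
    profiles_controls: list[OutlierProfile],
    basis: str = "entries",
) -> RiskClassification:
    """Classify cases as at risk using the control count distribution.

    ``basis`` selects the count: ``entries`` (region x metric, default) or
    ``regions`` (distinct regions).  At-risk is strict: count > cutoff.
    """
    if basis not in ("entries", "regions"):
        raise ValidationError(f"bad count basis {basis!r}")
    if len(profiles_controls) < 3:
        raise DegenerateStatisticsError("need >= 3 control profiles to set a cutoff")

    def _count(p: OutlierProfile) -> int:
        return p.outlier_count if basis == "entries" else p.region_count

    control_counts = [_count(p) for p in profiles_controls]
    cutoff = risk_cutoff(control_counts)

    def _frame(profiles: list[OutlierProfile]) -> pd.DataFrame:
        counts = [_count(p) for p in profiles]
        return pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in profiles],
                "outlier_count": counts,
                "at_risk": [c > cutoff for c in counts],
            }
        )

    return RiskClassification(
        cutoff=cutoff, cases=_frame(profiles_cases), controls=_frame(profiles_controls)
    )


def profiles_to_tsv(profiles: list[OutlierProfile], path: str | Path) -> None:
    """Write per-subject, per-key z-scores and flags as one long TSV."""
    frames = []
    for p in profiles:
        frame = p.records.copy()
        frame.insert(0, "subject_id", p.subject_id)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject_id", "region", "metric", "hemisphere", "direction", "z", "flagged"]
    )
    out.to_csv(path, sep="\t", index=False)
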