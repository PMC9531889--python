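"""Neuropsychological composites and their correlation with atrophy burden.

Consumes already-standardized scores: per-subtest throughput Z-scores from
the ANAM battery and a WRAT reading standard score converted to Z (the
premorbid estimate).  The composite is the mean of the subtests a subject
actually took.  Decline is flagged when the composite falls below the
premorbid estimate (composite_z < wrat_z); note the construct-driven sign
convention is documented on :func:`decline_flag`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateStatisticsError, MissingDataError, ParseError, ValidationError
from .scoring import OutlierProfile

ANAM_SUBTESTS = ("SRT", "CDS", "CDD", "M2S", "MTH", "PRO", "SPD", "ST6", "SR2")
COMPOSITE = "composite"


def composite(anam_z: dict[str, float]) -> float:
    """Mean of the available (non-missing) subtest Z-scores."""
    unknown = set(anam_z) - set(ANAM_SUBTESTS)
    if unknown:
        raise ValidationError(f"unknown ANAM subtests {sorted(unknown)}")
    values = [v for v in anam_z.values() if v is not None and not math.isnan(v)]
    if not values:
        raise MissingDataError("no ANAM subtests present; composite undefined")
    return float(np.mean(values))


def decline_flag(composite_z: float, wrat_z: float) -> bool:
    """True when current performance sits below the premorbid estimate.

    Decline iff composite_z < wrat_z.  (Equality is not decline.)
    """
    for name, value in (("composite_z", composite_z), ("wrat_z", wrat_z)):
        if value is None or math.isnan(value):
            raise MissingDataError(f"{name} is missing")
    return composite_z < wrat_z


@dataclass
class NeuropsychRecord:
    """Scores for one subject; composite/decline derived on construction."""

    subject_id: str
    anam_z: dict[str, float]
    wrat_z: float | None = None
    composite_z: float = field(init=False)
    decline: bool | None = field(init=False)

    def __post_init__(self):
        self.composite_z = composite(self.anam_z)
        self.decline = (
            decline_flag(self.composite_z, self.wrat_z) if self.wrat_z is not None else None
        )


def decline_rate(records: list[NeuropsychRecord]) -> float:
    """Percent of subjects (with both scores) flagged as declined."""
    flags = [r.decline for r in records if r.decline is not None]
    if not flags:
        raise MissingDataError("no subjects with both composite and WRAT scores")
    return 100.0 * sum(flags) / len(flags)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with two-sided t-based p; errors on zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValidationError("length mismatch")
    if len(x) < 3:
        raise DegenerateStatisticsError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateStatisticsError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlate_with_atrophy(
    records: list[NeuropsychRecord],
    profiles: list[OutlierProfile],
    basis: str = "entries",
) -> pd.DataFrame:
    """Per-subtest Pearson correlation between Z-scores and outlier counts.

    Pairs subjects present in both inputs; returns one row per subtest plus
    a composite row, with columns subtest, r, p, n.  Subtests with fewer
    than 3 paired subjects are dropped from the output.
    """
    if basis not in ("entries", "regions"):
        raise ValidationError(f"bad count basis {basis!r}")
    counts = {
        p.subject_id: (p.outlier_count if basis == "entries" else p.region_count)
        for p in profiles
    }
    rows = []
    for subtest in (*ANAM_SUBTESTS, COMPOSITE):
        xs, ys = [], []
        for rec in records:
            if rec.subject_id not in counts:
                continue
            score = rec.composite_z if subtest == COMPOSITE else rec.anam_z.get(subtest)
            if score is None or math.isnan(score):
                continue
            xs.append(counts[rec.subject_id])
            ys.append(score)
        if len(xs) < 3:
            continue
        r, p = pearson(xs, ys)
        rows.append({"subtest": subtest, "r": r, "p": p, "n": len(xs)})
    return pd.DataFrame(rows, columns=["subtest", "r", "p", "n"])


# ---------------------------------------------------------------------------
# Flat-file I/O
# ---------------------------------------------------------------------------


def read_neuropsych_tsvs(
    anam_path: str | Path, wrat_path: str | Path | None = None
) -> list[NeuropsychRecord]:
    """Read ANAM (subject_id, subtest, z) and optional WRAT (subject_id, wrat_z)."""
    anam = pd.read_csv(anam_path, sep="\t", dtype={"subject_id": str}, comment="#")
    for col in ("subject_id", "subtest", "z"):
        if col not in anam.columns:
            raise ParseError(f"ANAM table missing column {col!r}", str(anam_path))
    wrat: dict[str, float] = {}
    if wrat_path is not None:
        wf = pd.read_csv(wrat_path, sep="\t", dtype={"subject_id": str}, comment="#")
        for col in ("subject_id", "wrat_z"):
            if col not in wf.columns:
                raise ParseError(f"WRAT table missing column {col!r}", str(wrat_path))
        wrat = dict(zip(wf["subject_id"], wf["wrat_z"].astype(float)))
    records = []
    for sid, grp in anam.groupby("subject_id", sort=True):
        if grp["subtest"].duplicated().any():
            raise ParseError(f"duplicate subtest rows for subject {sid!r}", str(anam_path))
        records.append(
            NeuropsychRecord(
                subject_id=str(sid),
                anam_z=dict(zip(grp["subtest"], grp["z"].astype(float))),
                wrat_z=wrat.get(str(sid)),
            )
        )
    return records


def write_correlation_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
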