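"""Case-control screening and the bilateral disease fingerprint.

Every (region, hemisphere, metric) key is compared between cases and
controls with a two-sided Student's t-test (pooled variance by default, to
match the source method; Welch available as an option).  Percent change is
expressed relative to the control mean, signed so that positive means
atrophy (case below control) and negative means dilation.

A fingerprint keeps exactly the (region, metric) pairs that are significant
at alpha in BOTH hemispheres with concordant direction; midline/global
regions degenerate to their single test.  No multiple-testing correction is
applied (matching the method); the summary reports the expected
false-positive count as a caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import registry as reg
from .errors import ParseError, ValidationError
from .io_morphometry import PROV_NORMALIZED, MorphometryTable
from .preprocess import KEY

logger = logging.getLogger(__name__)

ATROPHY = "atrophy"
DILATION = "dilation"


@dataclass(frozen=True)
class RegionStat:
    """One case-control comparison for a single measurement key."""

    region: str
    hemisphere: str
    metric: str
    case_mean: float
    control_mean: float
    percent_change: float
    t_statistic: float
    p_value: float
    n_case: int
    n_control: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValidationError(f"p_value out of [0,1] for {self.region}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError(f"need >= 2 subjects per group for {self.region}")

    @property
    def direction(self) -> str:
        return ATROPHY if self.percent_change > 0 else DILATION


def two_sample_t(
    case: np.ndarray, control: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance Student's by default."""
    case = np.asarray(case, float)
    control = np.asarray(control, float)
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValidationError("two_sample_t needs >= 2 observations per group")
    m1, m2 = case.mean(), control.mean()
    v1 = case.var(ddof=1)
    v2 = control.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return (0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)), (1.0 if m1 == m2 else 0.0)
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            return (0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)), (1.0 if m1 == m2 else 0.0)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def compare_groups(
    cases: MorphometryTable,
    controls: MorphometryTable,
    welch: bool = False,
    require_normalized: bool = True,
) -> list[RegionStat]:
    """Compare every shared measurement key between cases and controls.

    Both tables must be normalized (unless ``require_normalized`` is
    disabled for calibration experiments) with disjoint subject sets.  Keys
    with fewer than two pairwise-complete subjects in either group are
    skipped with a warning.
    """
    if require_normalized:
        for name, table in (("cases", cases), ("controls", controls)):
            if PROV_NORMALIZED not in table.provenance:
                raise ValidationError(f"{name} table must be normalized")
    overlap = set(cases.subjects.index) & set(controls.subjects.index)
    if overlap:
        raise ValidationError(f"case/control subject sets overlap: {sorted(overlap)[:5]}")

    def _moments(table: MorphometryTable, prefix: str) -> pd.DataFrame:
        g = table.data.groupby(KEY, sort=True)["value"]
        out = g.agg(["count", "mean", "var"])
        out.columns = [f"{prefix}_{c}" for c in out.columns]
        return out

    joined = _moments(cases, "case").join(_moments(controls, "control"), how="outer")

    stats_out: list[RegionStat] = []
    n1 = joined["case_count"].fillna(0).to_numpy(int)
    n2 = joined["control_count"].fillna(0).to_numpy(int)
    usable = (n1 >= 2) & (n2 >= 2)
    for key in joined.index[~usable]:
        logger.warning("compare_groups: skipping %s (fewer than 2 subjects per group)", key)

    sub = joined[usable]
    n1 = sub["case_count"].to_numpy(int)
    n2 = sub["control_count"].to_numpy(int)
    m1 = sub["case_mean"].to_numpy(float)
    m2 = sub["control_mean"].to_numpy(float)
    v1 = sub["case_var"].to_numpy(float)
    v2 = sub["control_var"].to_numpy(float)
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = np.where(se2 > 0, se2**2 /
                      ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1) + (se2 == 0)), 1.0)
        t = np.where(se2 > 0, (m1 - m2) / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
    else:
        df = (n1 + n2 - 2).astype(float)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        denom = np.sqrt(np.where(sp2 > 0, sp2, 1.0) * (1.0 / n1 + 1.0 / n2))
        t = np.where(sp2 > 0, (m1 - m2) / denom, 0.0)
    p = np.minimum(2.0 * sps.t.sf(np.abs(t), df), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (m2 - m1) / m2

    for i, (region, hemisphere, metric) in enumerate(sub.index):
        stats_out.append(
            RegionStat(
                region=region,
                hemisphere=hemisphere,
                metric=metric,
                case_mean=float(m1[i]),
                control_mean=float(m2[i]),
                percent_change=float(pct[i]),
                t_statistic=float(t[i]),
                p_value=float(p[i]),
                n_case=int(n1[i]),
                n_control=int(n2[i]),
            )
        )
    return stats_out


def region_stats_frame(stats: list[RegionStat]) -> pd.DataFrame:
    """Tabulate RegionStats (one row per hemisphere test)."""
    return pd.DataFrame(
        [
            {
                "region": s.region,
                "hemisphere": s.hemisphere,
                "metric": s.metric,
                "case_mean": s.case_mean,
                "control_mean": s.control_mean,
                "percent_change": s.percent_change,
                "t_statistic": s.t_statistic,
                "p_value": s.p_value,
                "n_case": s.n_case,
                "n_control": s.n_control,
            }
            for s in stats
        ]
    )


@dataclass(frozen=True)
class FingerprintEntry:
    """One (region, metric) pair passing the bilateral filter.

    ``left``/``right`` hold the per-hemisphere statistics; midline regions
    carry their single test in ``left`` with ``right`` None.
    """

    region: str
    metric: str
    direction: str
    left: RegionStat
    right: RegionStat | None = None

    @property
    def hemispheric(self) -> bool:
        return self.right is not None

    def stats(self) -> list[RegionStat]:
        return [s for s in (self.left, self.right) if s is not None]


@dataclass
class Fingerprint:
    """The bilateral-significance disease fingerprint."""

    entries: list[FingerprintEntry]
    alpha: float
    n_tests: int = 0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self) -> list[tuple[str, str]]:
        return [(e.region, e.metric) for e in self.entries]

    def region_count(self) -> int:
        """Distinct regions (thickness and volume of a region count once)."""
        return len({e.region for e in self.entries})

    def entry_count(self) -> int:
        """Region x metric entries (thickness and volume count separately)."""
        return len(self.entries)

    def expected_false_positives(self) -> float:
        """Expected significant tests under the global null (no correction)."""
        return self.alpha * self.n_tests

    def summary(self, registry: reg.RegionRegistry | None = None) -> dict:
        out = {
            "alpha": self.alpha,
            "entry_count": self.entry_count(),
            "region_count": self.region_count(),
            "n_tests": self.n_tests,
            "expected_false_positive_tests": self.expected_false_positives(),
            "atrophy_entries": sum(1 for e in self.entries if e.direction == ATROPHY),
            "dilation_entries": sum(1 for e in self.entries if e.direction == DILATION),
        }
        if registry is not None:
            by_cat: dict[str, set] = {c: set() for c in reg.CATEGORIES}
            for e in self.entries:
                by_cat[registry.lookup(e.region).category].add(e.region)
            out["regions_by_category"] = {c: len(v) for c, v in by_cat.items()}
        return out

    # -- flat-file round trip ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for e in self.entries:
            for s in e.stats():
                rows.append(
                    {
                        "region": e.region,
                        "metric": e.metric,
                        "direction": e.direction,
                        "hemisphere": s.hemisphere,
                        "case_mean": repr(s.case_mean),
                        "control_mean": repr(s.control_mean),
                        "percent_change": repr(s.percent_change),
                        "t_statistic": repr(s.t_statistic),
                        "p_value": repr(s.p_value),
                        "n_case": s.n_case,
                        "n_control": s.n_control,
                    }
                )
        frame = pd.DataFrame(
            rows,
            columns=[
                "region", "metric", "direction", "hemisphere", "case_mean",
                "control_mean", "percent_change", "t_statistic", "p_value",
                "n_case", "n_control",
            ],
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# morphprint fingerprint v1 alpha={self.alpha!r} n_tests={self.n_tests}\n")
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Fingerprint":
        alpha, n_tests = None, 0
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                for token in first.split():
                    if token.startswith("alpha="):
                        alpha = float(token.split("=", 1)[1])
                    if token.startswith("n_tests="):
                        n_tests = int(token.split("=", 1)[1])
            frame = pd.read_csv(fh, sep="\t")
        if alpha is None:
            raise ParseError("fingerprint file lacks alpha header", str(path), 1)
        entries = []
        for (region, metric, direction), grp in frame.groupby(
            ["region", "metric", "direction"], sort=False
        ):
            stats = {}
            for row in grp.itertuples(index=False):
                stats[row.hemisphere] = RegionStat(
                    region=region,
                    hemisphere=row.hemisphere,
                    metric=metric,
                    case_mean=float(row.case_mean),
                    control_mean=float(row.control_mean),
                    percent_change=float(row.percent_change),
                    t_statistic=float(row.t_statistic),
                    p_value=float(row.p_value),
                    n_case=int(row.n_case),
                    n_control=int(row.n_control),
                )
            if "none" in stats:
                entries.append(FingerprintEntry(region, metric, direction, stats["none"], None))
            else:
                if set(stats) != {"left", "right"}:
                    raise ParseError(f"incomplete hemisphere pair for {region}/{metric}", str(path))
                entries.append(
                    FingerprintEntry(region, metric, direction, stats["left"], stats["right"])
                )
        return cls(entries=entries, alpha=alpha, n_tests=n_tests)


def build_fingerprint(stats: list[RegionStat], alpha: float = 0.05) -> Fingerprint:
    """Apply the bilateral-significance filter to screening statistics.

    A hemispheric (region, metric) pair enters iff p <= alpha in both
    hemispheres with the same direction; a midline key needs only its
    single significant test.  Keys with one hemisphere missing are
    excluded (the bilateral requirement cannot be verified).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    by_pair: dict[tuple[str, str], dict[str, RegionStat]] = {}
    for s in stats:
        by_pair.setdefault((s.region, s.metric), {})[s.hemisphere] = s

    entries: list[FingerprintEntry] = []
    for (region, metric), hemis in sorted(by_pair.items()):
        if "none" in hemis:
            s = hemis["none"]
            if s.p_value <= alpha and s.percent_change != 0:
                entries.append(FingerprintEntry(region, metric, s.direction, s, None))
            continue
        left, right = hemis.get("left"), hemis.get("right")
        if left is None or right is None:
            logger.warning(
                "fingerprint: %s/%s has only one hemisphere tested; excluded", region, metric
            )
            continue
        if left.p_value <= alpha and right.p_value <= alpha and left.direction == right.direction:
            entries.append(FingerprintEntry(region, metric, left.direction, left, right))
    return Fingerprint(entries=entries, alpha=alpha, n_tests=len(stats))
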