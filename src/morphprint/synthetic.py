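"""Synthetic three-cohort morphometry and neuropsychology generator.

Generates raw-scale measurement tables for a control cohort, a disease
(AD-like) cohort and an exposed (former-athlete-like) cohort with the
statistical structure the analysis pipeline assumes:

* region volumes scale with the subject's intracranial volume, so ICV
  normalization demonstrably removes head-size variance;
* values drift linearly with age (additive slope in raw units), so
  control-slope age correction removes the drift;
* hippocampal-subfield and amygdalar-nucleus values are drawn as fractions
  of the subject's simulated parent structure and multiplied back, so
  parent normalization recovers the configured fraction;
* left/right values share correlated noise (default rho = 0.8);
* group effects are multiplicative (0.73 = 27 % atrophy, 2.25 = 125 %
  dilation) on the baseline;
* an optional "spike" gives a fraction of exposed subjects strong
  disease-direction shifts in a fixed set of regions (ground truth for
  sensitivity/specificity experiments);
* exposed-cohort cognitive scores are drawn with configurable Pearson
  correlation against each subject's true affected-region count.

Every draw comes from one seeded generator, so a fixed seed reproduces the
output bit for bit.  A truth ledger records each region's configured effect
and each subject's true affected-region set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import registry as reg
from .errors import ValidationError
from .io_morphometry import DATA_COLUMNS, MorphometryTable, SubjectRecord
from .neuropsych import ANAM_SUBTESTS, NeuropsychRecord

COHORTS = ("control", "AD", "exposed")


@dataclass
class AgeDist:
    """Uniform or (truncated) normal age distribution."""

    kind: str = "uniform"
    low: float | None = None
    high: float | None = None
    mean: float | None = None
    sd: float | None = None

    def validate(self) -> None:
        if self.kind == "uniform":
            if self.low is None or self.high is None or not 0 < self.low < self.high:
                raise ValidationError(f"bad uniform age range ({self.low}, {self.high})")
        elif self.kind == "normal":
            if self.mean is None or self.sd is None or self.sd <= 0 or self.mean <= 0:
                raise ValidationError(f"bad normal age parameters ({self.mean}, {self.sd})")
        else:
            raise ValidationError(f"unknown age distribution kind {self.kind!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, n)
        low = self.low if self.low is not None else 1.0
        high = self.high if self.high is not None else self.mean + 6 * self.sd
        a, b = (low - self.mean) / self.sd, (high - self.mean) / self.sd
        u = rng.uniform(size=n)
        return sps.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass
class CohortSpec:
    n: int
    age: AgeDist
    icv_mean: float = 1.55e6
    icv_sd: float = 1.4e5

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort n must be >= 1")
        if self.icv_mean <= 0 or self.icv_sd <= 0:
            raise ValidationError("ICV mean/sd must be positive")
        self.age.validate()


@dataclass
class RegionEffectSpec:
    """Generator parameters for one (region, metric).

    ``baseline`` is the control mean at the reference age: raw mm^3 / mm
    for ICV-normalized regions and thickness, a fraction of the parent
    structure for subfields/nuclei.  ``cv`` is the multiplicative noise SD.
    ``effects`` maps cohort -> multiplicative group effect (1 = none);
    ``slope_mult`` maps cohort -> age-slope multiplier.
    """

    baseline: float
    cv: float
    age_slope: float = 0.0
    effects: dict[str, float] = field(default_factory=dict)
    slope_mult: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.baseline <= 0:
            raise ValidationError("baseline must be positive")
        if self.cv <= 0:
            raise ValidationError("cv must be positive")
        for cohort, eff in self.effects.items():
            if cohort not in COHORTS:
                raise ValidationError(f"unknown cohort {cohort!r} in effects")
            if eff <= 0:
                raise ValidationError(f"effect for {cohort!r} must be positive")

    def effect(self, cohort: str) -> float:
        return self.effects.get(cohort, 1.0)

    def slope(self, cohort: str) -> float:
        return self.age_slope * self.slope_mult.get(cohort, 1.0)


@dataclass
class SpikeSpec:
    """Strong per-subject disease-direction shifts in the exposed cohort."""

    prevalence: float = 0.0
    n_regions: int = 8
    magnitude_sd: float = 3.0
    regions: tuple = ()

    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError("spike prevalence must lie in [0, 1]")
        if self.prevalence > 0:
            if self.n_regions < 1 or self.n_regions > len(self.regions):
                raise ValidationError("spike n_regions must be in [1, len(regions)]")
            if self.magnitude_sd <= 0:
                raise ValidationError("spike magnitude must be positive")


@dataclass
class CognitionSpec:
    """Links exposed-cohort cognitive scores to true atrophy burden."""

    subtest_r: dict[str, float] = field(default_factory=dict)
    anam_offset: float = 0.0
    wrat_mean: float = 0.0
    wrat_sd: float = 1.0

    def validate(self) -> None:
        for subtest, r in self.subtest_r.items():
            if subtest not in ANAM_SUBTESTS:
                raise ValidationError(f"unknown ANAM subtest {subtest!r}")
            if not -1.0 < r < 1.0:
                raise ValidationError(f"target r for {subtest} must lie in (-1, 1)")
        if self.wrat_sd <= 0:
            raise ValidationError("wrat_sd must be positive")


@dataclass
class CohortSimConfig:
    """Full parameterization of the three-cohort generator."""

    seed: int = 0
    cohorts: dict[str, CohortSpec] = field(default_factory=dict)
    region_effects: dict[tuple[str, str], RegionEffectSpec] = field(default_factory=dict)
    hemisphere_rho: float = 0.8
    reference_age: float = 41.4
    missingness: dict[str, float] = field(default_factory=dict)
    spike: SpikeSpec | None = None
    cognition: CognitionSpec | None = None
    cohort_tag_offsets: dict[str, float] = field(default_factory=dict)

    def validate(self, registry: reg.RegionRegistry | None = None) -> None:
        registry = registry or reg.build_default_registry()
        if not self.cohorts:
            raise ValidationError("config needs at least one cohort")
        for name, spec in self.cohorts.items():
            if name not in COHORTS:
                raise ValidationError(f"unknown cohort {name!r}")
            spec.validate()
        if not 0.0 <= self.hemisphere_rho <= 1.0:
            raise ValidationError("hemisphere_rho must lie in [0, 1]")
        if self.reference_age <= 0:
            raise ValidationError("reference_age must be positive")
        for (region, metric), spec in self.region_effects.items():
            desc = registry.lookup(region)
            if metric not in desc.metrics:
                raise ValidationError(f"{region!r} has no metric {metric!r}")
            spec.validate()
        for category, rate in self.missingness.items():
            if category not in reg.CATEGORIES:
                raise ValidationError(f"unknown region category {category!r}")
            if not 0.0 <= rate < 1.0:
                raise ValidationError("missingness rate must lie in [0, 1)")
        if self.spike is not None:
            self.spike.validate()
            for region, metric in self.spike.regions:
                if (region, metric) not in self.region_effects:
                    raise ValidationError(f"spike region {(region, metric)} not configured")
        if self.cognition is not None:
            self.cognition.validate()


@dataclass
class TruthLedger:
    """Ground truth of a simulation run.

    ``regions``: one row per (region, metric, cohort) with the configured
    effect and its direction.  ``subjects``: one row per subject with the
    spiked-region set and true burden count.
    """

    regions: pd.DataFrame
    subjects: pd.DataFrame

    def true_burden(self) -> pd.Series:
        return self.subjects.set_index("subject_id")["true_burden"]


@dataclass
class SimResult:
    table: MorphometryTable
    anam: pd.DataFrame      # subject_id, subtest, z  (exposed cohort)
    wrat: pd.DataFrame      # subject_id, wrat_z
    truth: TruthLedger

    def neuropsych_records(self) -> list[NeuropsychRecord]:
        wrat = dict(zip(self.wrat["subject_id"], self.wrat["wrat_z"]))
        records = []
        for sid, grp in self.anam.groupby("subject_id", sort=True):
            records.append(
                NeuropsychRecord(
                    subject_id=sid,
                    anam_z=dict(zip(grp["subtest"], grp["z"])),
                    wrat_z=wrat.get(sid),
                )
            )
        return records


def _sorted_keys(config: CohortSimConfig, registry: reg.RegionRegistry):
    """Deterministic key order with parent structures generated first."""
    keys = sorted(config.region_effects)
    parents = {reg.WHOLE_HIPPOCAMPUS, reg.WHOLE_AMYGDALA}
    first = [k for k in keys if k[0] in parents]
    rest = [k for k in keys if k[0] not in parents]
    return first + rest


def simulate_cohorts(
    config: CohortSimConfig,
    seed: int | None = None,
    cohorts: tuple[str, ...] | None = None,
    registry: reg.RegionRegistry | None = None,
) -> SimResult:
    """Run the generator and return (table, cognition tables, truth ledger).

    ``seed`` overrides ``config.seed``; ``cohorts`` restricts generation to
    a subset (in fixed order control, AD, exposed).
    """
    registry = registry or reg.build_default_registry()
    config.validate(registry)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    which = [c for c in COHORTS if c in config.cohorts]
    if cohorts is not None:
        unknown = set(cohorts) - set(which)
        if unknown:
            raise ValidationError(f"requested cohorts not configured: {sorted(unknown)}")
        which = [c for c in which if c in cohorts]

    keys = _sorted_keys(config, registry)
    rho = config.hemisphere_rho
    rho_tail = np.sqrt(max(1.0 - rho * rho, 0.0))

    subjects: list[SubjectRecord] = []
    frames: list[pd.DataFrame] = []
    truth_subject_rows: list[dict] = []
    truth_region_rows: list[dict] = []
    anam_rows: list[dict] = []
    wrat_rows: list[dict] = []

    for cohort in which:
        spec = config.cohorts[cohort]
        n = spec.n
        ids = [f"{cohort}{i + 1:03d}" for i in range(n)]
        ages = spec.age.sample(n, rng)
        icv = np.clip(
            rng.normal(spec.icv_mean, spec.icv_sd, n),
            spec.icv_mean - 4 * spec.icv_sd,
            spec.icv_mean + 4 * spec.icv_sd,
        )
        icv = np.maximum(icv, 0.2 * spec.icv_mean)
        sexes = np.where(rng.uniform(size=n) < 0.5, "male", "female")
        tag = cohort
        offset = config.cohort_tag_offsets.get(tag, 1.0)

        # -- spike assignment (exposed cohort only) -------------------------
        spiked_sets: list[frozenset] = [frozenset()] * n
        spike = config.spike
        if cohort == "exposed" and spike is not None and spike.prevalence > 0:
            affected = rng.uniform(size=n) < spike.prevalence
            region_pool = list(spike.regions)
            sets = []
            for i in range(n):
                if affected[i]:
                    pick = rng.choice(len(region_pool), size=spike.n_regions, replace=False)
                    sets.append(frozenset(region_pool[j] for j in sorted(pick)))
                else:
                    sets.append(frozenset())
            spiked_sets = sets

        # -- measurements ---------------------------------------------------
        parent_raw: dict[tuple[str, str], np.ndarray] = {}  # (region, 'left'/'right') -> values
        cohort_rows: list[pd.DataFrame] = []
        for region, metric in keys:
            espec = config.region_effects[(region, metric)]
            desc = registry.lookup(region)
            eff = espec.effect(cohort)
            slope = espec.slope(cohort)
            drift = slope * (ages - config.reference_age)
            fractional = metric == reg.VOLUME and desc.norm_parent in (
                reg.NORM_WHOLE_HIPPOCAMPUS,
                reg.NORM_WHOLE_AMYGDALA,
            )
            scale = (
                icv / spec.icv_mean
                if metric == reg.VOLUME and not fractional
                else np.ones(n)
            )
            if desc.hemispheric:
                z = rng.standard_normal((n, 2))
                eps = np.column_stack([z[:, 0], rho * z[:, 0] + rho_tail * z[:, 1]]) * espec.cv
            else:
                eps = rng.normal(0.0, espec.cv, size=(n, 1))
            hemis = ("left", "right") if desc.hemispheric else ("none",)
            for h_idx, hemi in enumerate(hemis):
                base = espec.baseline * eff * (1.0 + eps[:, h_idx])
                if fractional:
                    parent_region = (
                        reg.WHOLE_HIPPOCAMPUS
                        if desc.norm_parent == reg.NORM_WHOLE_HIPPOCAMPUS
                        else reg.WHOLE_AMYGDALA
                    )
                    parent = parent_raw.get((parent_region, hemi))
                    if parent is None:
                        raise ValidationError(
                            f"{region!r} needs {parent_region!r} configured in region_effects"
                        )
                    fraction = base + drift
                    values = parent * fraction
                    spike_delta = spike.magnitude_sd * espec.cv * espec.baseline * parent \
                        if (cohort == "exposed" and spike is not None) else None
                else:
                    values = scale * base + drift
                    spike_delta = spike.magnitude_sd * espec.cv * espec.baseline * scale \
                        if (cohort == "exposed" and spike is not None) else None
                if spike_delta is not None:
                    hit = np.array([(region, metric) in s for s in spiked_sets])
                    if hit.any():
                        ad_eff = espec.effect("AD")
                        sign = -1.0 if ad_eff <= 1.0 else 1.0
                        values = values + np.where(hit, sign * spike_delta, 0.0)
                values = values * offset
                values = np.maximum(values, 1e-9 * espec.baseline)
                if desc.name == reg.WHOLE_HIPPOCAMPUS or desc.name == reg.WHOLE_AMYGDALA:
                    parent_raw[(desc.name, hemi)] = values
                cohort_rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": ids,
                            "region": desc.name,
                            "hemisphere": hemi,
                            "metric": metric,
                            "value": values,
                        }
                    )
                )
            truth_region_rows.append(
                {
                    "region": desc.name,
                    "metric": metric,
                    "cohort": cohort,
                    "effect": eff,
                    "direction": "dilation" if eff > 1.0 else ("none" if eff == 1.0 else "atrophy"),
                }
            )

        cohort_frame = pd.concat(cohort_rows, ignore_index=True)

        # -- missingness per region family ----------------------------------
        for category in reg.CATEGORIES:
            rate = config.missingness.get(category, 0.0)
            if rate <= 0:
                continue
            missing = rng.uniform(size=n) < rate
            drop_ids = {ids[i] for i in range(n) if missing[i]}
            if not drop_ids:
                continue
            cat_regions = {d.name for d in registry if d.category == category}
            drop = cohort_frame["subject_id"].isin(drop_ids) & cohort_frame["region"].isin(
                cat_regions
            )
            cohort_frame = cohort_frame[~drop]
        frames.append(cohort_frame)

        for i, sid in enumerate(ids):
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=cohort,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    cohort_tag=tag,
                    icv=float(icv[i]),
                )
            )
            truth_subject_rows.append(
                {
                    "subject_id": sid,
                    "cohort": cohort,
                    "affected": bool(spiked_sets[i]),
                    "true_burden": len(spiked_sets[i]),
                    "spiked_regions": ";".join(
                        f"{r}|{m}" for r, m in sorted(spiked_sets[i])
                    ),
                }
            )

        # -- cognition (exposed cohort) -------------------------------------
        if cohort == "exposed" and config.cognition is not None:
            cog = config.cognition
            burden = np.array([len(s) for s in spiked_sets], float)
            if burden.std() > 0:
                x_std = (burden - burden.mean()) / burden.std()
            else:
                x_std = np.zeros(n)
            for subtest in ANAM_SUBTESTS:
                r = cog.subtest_r.get(subtest, 0.0)
                noise = rng.normal(size=n)
                z = cog.anam_offset + r * x_std + np.sqrt(1.0 - r * r) * noise
                anam_rows += [
                    {"subject_id": sid, "subtest": subtest, "z": float(z[i])}
                    for i, sid in enumerate(ids)
                ]
            wrat = rng.normal(cog.wrat_mean, cog.wrat_sd, size=n)
            wrat_rows += [
                {"subject_id": sid, "wrat_z": float(wrat[i])} for i, sid in enumerate(ids)
            ]

    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=DATA_COLUMNS)
    )
    table = MorphometryTable.from_records(subjects, data)
    truth = TruthLedger(
        regions=pd.DataFrame(
            truth_region_rows, columns=["region", "metric", "cohort", "effect", "direction"]
        ),
        subjects=pd.DataFrame(
            truth_subject_rows,
            columns=["subject_id", "cohort", "affected", "true_burden", "spiked_regions"],
        ),
    )
    return SimResult(
        table=table,
        anam=pd.DataFrame(anam_rows, columns=["subject_id", "subtest", "z"]),
        wrat=pd.DataFrame(wrat_rows, columns=["subject_id", "wrat_z"]),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Default configuration: effect sizes and demographics transcribed from the
# literature-reported cohort-level effect magnitudes this pipeline models.
# ---------------------------------------------------------------------------

def _atrophy(pct: float) -> float:
    return 1.0 - pct / 100.0


def _dilation(pct: float) -> float:
    return 1.0 + pct / 100.0


# cortical (thickness %, volume %) case effects; None = no configured effect
_AD_CORTICAL = {
    "Entorhinal": (19.1, 27.0),
    "Parahippocampal": (10.9, 8.5),
    "Fusiform": (5.1, 14.5),
    "Middle temporal": (7.8, 13.0),
    "Inferior temporal": (5.3, 15.8),
    "Superior temporal": (6.0, 14.5),
    "Temporal pole": (6.7, 11.9),
    "Supramarginal": (3.6, 11.8),
    "Superior parietal": (3.6, 9.0),
    "Pre-cuneus": (3.9, 10.0),
    "Inferior parietal": (4.8, 9.9),
    "Lateral orbitofrontal": (None, 10.0),
    "Caudal middle frontal": (3.0, 7.7),
    "Superior frontal": (None, 7.6),
    "Lateral occipital": (None, 10.0),
}

_EXPOSED_CORTICAL = {
    "Entorhinal": (14.55, 15.7),
    "Parahippocampal": (9.15, 8.55),
    "Fusiform": (7.5, 10.4),
    "Inferior temporal": (5.7, None),
    "Isthmus cingulate": (7.5, None),
    "Lateral occipital": (None, 12.6),
    "Cuneus": (None, 10.2),
}

# subcortical volume effects as multiplicative factors (>1 = dilation)
_AD_SUBCORTICAL = {
    "Amygdala": _atrophy(26.8),
    "Accumbens area": _atrophy(20.0),
    "Hippocampus": _atrophy(12.5),
    "Cerebral white matter": _atrophy(8.0),
    "Inf-Lat-Vent": _dilation(124.7),
    "Lateral-ventricle": _dilation(32.5),
    "Putamen": _dilation(15.3),
}

_EXPOSED_SUBCORTICAL = {
    "Cerebellum cortex": _atrophy(14.85),
    "Amygdala": _atrophy(14.75),
    "Hippocampus": _atrophy(11.3),
    "Inf-Lat-Vent": _dilation(28.95),
    "Lateral-ventricle": _dilation(14.2),
}

# hippocampal-subfield fraction effects
_AD_SUBFIELDS = {
    "Fimbria": _atrophy(23.7),
    "Whole hippocampus": _atrophy(21.1),
    "Hippocampal fissure": _dilation(11.2),
    "Presubiculum head": _atrophy(8.0),
    "Subiculum body": _atrophy(8.0),
}

_EXPOSED_SUBFIELDS = {
    "Fimbria": _atrophy(18.5),
    "HATA": _atrophy(8.9),
    "Whole hippocampus": _atrophy(7.25),
    "Hippocampal fissure": _dilation(17.3),
}

_AD_NUCLEI = {
    "Whole amygdala": _atrophy(24.0),
    "Accessory basal nucleus": _atrophy(10.0),
    "Central nucleus": _atrophy(10.0),
}

_EXPOSED_NUCLEI = {
    "Anterior amygdaloid area": _atrophy(6.55),
    "Whole amygdala": _atrophy(6.85),
}

_SUBCORTICAL_BASELINES = {
    "Lateral-ventricle": (8000.0, 0.30, 120.0),
    "Inf-Lat-Vent": (400.0, 0.35, 6.0),
    "Cerebellum white matter": (14000.0, 0.10, -20.0),
    "Cerebellum cortex": (52000.0, 0.10, -80.0),
    "Caudate": (3600.0, 0.10, -8.0),
    "Putamen": (5000.0, 0.10, -12.0),
    "Pallidum": (1800.0, 0.10, -4.0),
    "Hippocampus": (4100.0, 0.10, -12.0),
    "Amygdala": (1700.0, 0.10, -4.0),
    "Accumbens area": (600.0, 0.12, -2.0),
    "Cortex": (230000.0, 0.08, -600.0),
    "Cerebral white matter": (240000.0, 0.08, -400.0),
    "Corpus callosum posterior": (950.0, 0.12, -1.5),
    "Corpus callosum midposterior": (450.0, 0.12, -0.8),
    "Corpus callosum central": (480.0, 0.12, -0.8),
    "Corpus callosum midanterior": (470.0, 0.12, -0.8),
    "Corpus callosum anterior": (850.0, 0.12, -1.2),
    "Third ventricle": (1000.0, 0.25, 15.0),
    "Fourth ventricle": (1700.0, 0.25, 8.0),
    "CSF": (900.0, 0.20, 6.0),
    "Brainstem": (21000.0, 0.08, -25.0),
    "Brain Seg Vol": (1150000.0, 0.08, -1800.0),
    "Total Gray Vol": (620000.0, 0.08, -1400.0),
}

_SUBFIELD_FRACTIONS = {
    "Hippocampal tail": 0.16,
    "Subiculum body": 0.07,
    "CA-1 body": 0.05,
    "Subiculum head": 0.06,
    "Hippocampal fissure": 0.045,
    "Presubiculum head": 0.04,
    "CA-1 head": 0.15,
    "Pre-subiculum body": 0.03,
    "Parasubiculum": 0.02,
    "Molecular layer HP head": 0.10,
    "Molecular layer HP body": 0.07,
    "GC-ML-DG-head": 0.09,
    "CA-3 body": 0.03,
    "GC-ML-DG body": 0.05,
    "CA-4 head": 0.04,
    "CA-4 body": 0.03,
    "Fimbria": 0.025,
    "CA-3 head": 0.03,
    "HATA": 0.02,
    "Whole hippocampal body": 0.40,
    "Whole hippocampal head": 0.45,
}

_NUCLEUS_FRACTIONS = {
    "Lateral nucleus": 0.40,
    "Basal nucleus": 0.26,
    "Accessory basal nucleus": 0.16,
    "Anterior amygdaloid area": 0.035,
    "Central nucleus": 0.03,
    "Medial nucleus": 0.012,
    "Cortical nucleus": 0.015,
    "Cortical amygdaloid transition": 0.11,
    "Paralaminar nucleus": 0.03,
}

# the eight strongest disease-direction regions: spiking targets with
# near-certain fingerprint membership at the default sample sizes
DEFAULT_SPIKE_REGIONS = (
    ("Entorhinal", reg.VOLUME),
    ("Amygdala", reg.VOLUME),
    ("Accumbens area", reg.VOLUME),
    ("Hippocampus", reg.VOLUME),
    ("Inf-Lat-Vent", reg.VOLUME),
    ("Lateral-ventricle", reg.VOLUME),
    ("Inferior temporal", reg.VOLUME),
    ("Fusiform", reg.VOLUME),
)

# Table-2-style target correlations between subtest scores and burden
DEFAULT_SUBTEST_R = {
    "CDD": -0.26,
    "CDS": -0.31,
    "M2S": -0.35,
    "MTH": -0.11,
    "PRO": -0.11,
    "SPD": -0.13,
    "SR2": -0.23,
    "SRT": -0.12,
    "ST6": -0.18,
}


def default_cohort_config(
    n_control: int = 114,
    n_ad: int = 58,
    n_exposed: int = 46,
    seed: int = 0,
    exposed_model: str = "mixture",
) -> CohortSimConfig:
    """The shipped cohort configuration.

    Demographics: controls uniform over ages 18-81 (pooled mean ~41.4); the
    disease cohort normal(75.5, 6.6); the exposed cohort normal(48.4, 12.2)
    truncated to 29-75.  Disease-cohort effects carry literature-reported
    percent-change magnitudes for every region where one is printed;
    regions reported as significant without a magnitude get a modest
    default, all others 1.0.

    The exposed cohort is modelled two ways.  ``exposed_model='mixture'``
    (default): a 41 % sub-population receives strong disease-direction
    shifts (3 SD in 8 fingerprint regions) while the rest stay normal —
    the mixture's group means then approximate the reported exposed-group
    percent changes, and per-subject burden varies so at-risk rates and
    cognition correlations are meaningful.  ``exposed_model='uniform'``:
    every exposed subject gets the reported group-mean effects
    multiplicatively and no spikes (useful for group-mean calibration
    checks, but every subject then deviates identically).
    """
    if exposed_model not in ("mixture", "uniform"):
        raise ValidationError(f"unknown exposed_model {exposed_model!r}")
    uniform_exposed = exposed_model == "uniform"
    registry = reg.build_default_registry()
    effects: dict[tuple[str, str], RegionEffectSpec] = {}
    for desc in registry:
        if desc.category == reg.CORTICAL:
            ad_t, ad_v = _AD_CORTICAL.get(desc.name, (None, None))
            ex_t, ex_v = (
                _EXPOSED_CORTICAL.get(desc.name, (None, None))
                if uniform_exposed
                else (None, None)
            )
            effects[(desc.name, reg.THICKNESS)] = RegionEffectSpec(
                baseline=2.5,
                cv=0.05,
                age_slope=-0.004,
                effects={
                    **({"AD": _atrophy(ad_t)} if ad_t is not None else {}),
                    **({"exposed": _atrophy(ex_t)} if ex_t is not None else {}),
                },
            )
            effects[(desc.name, reg.VOLUME)] = RegionEffectSpec(
                baseline=6500.0,
                cv=0.10,
                age_slope=-13.0,
                effects={
                    **({"AD": _atrophy(ad_v)} if ad_v is not None else {}),
                    **({"exposed": _atrophy(ex_v)} if ex_v is not None else {}),
                },
            )
        elif desc.category == reg.SUBCORTICAL:
            baseline, cv, slope = _SUBCORTICAL_BASELINES[desc.name]
            eff = {}
            if desc.name in _AD_SUBCORTICAL:
                eff["AD"] = _AD_SUBCORTICAL[desc.name]
            if uniform_exposed and desc.name in _EXPOSED_SUBCORTICAL:
                eff["exposed"] = _EXPOSED_SUBCORTICAL[desc.name]
            slope_mult = {"exposed": 2.0} if desc.name == "Inf-Lat-Vent" else {}
            effects[(desc.name, reg.VOLUME)] = RegionEffectSpec(
                baseline=baseline, cv=cv, age_slope=slope, effects=eff, slope_mult=slope_mult
            )
        elif desc.category == reg.HIPPOCAMPAL_SUBFIELD:
            if desc.name == reg.WHOLE_HIPPOCAMPUS:
                effects[(desc.name, reg.VOLUME)] = RegionEffectSpec(
                    baseline=3400.0,
                    cv=0.10,
                    age_slope=-10.0,
                    effects={
                        "AD": _AD_SUBFIELDS["Whole hippocampus"],
                        **(
                            {"exposed": _EXPOSED_SUBFIELDS["Whole hippocampus"]}
                            if uniform_exposed
                            else {}
                        ),
                    },
                )
            else:
                eff = {}
                if desc.name in _AD_SUBFIELDS:
                    eff["AD"] = _AD_SUBFIELDS[desc.name]
                if uniform_exposed and desc.name in _EXPOSED_SUBFIELDS:
                    eff["exposed"] = _EXPOSED_SUBFIELDS[desc.name]
                effects[(desc.name, reg.VOLUME)] = RegionEffectSpec(
                    baseline=_SUBFIELD_FRACTIONS[desc.name], cv=0.12, effects=eff
                )
        else:  # amygdalar nucleus
            if desc.name == reg.WHOLE_AMYGDALA:
                effects[(desc.name, reg.VOLUME)] = RegionEffectSpec(
                    baseline=1700.0,
                    cv=0.10,
                    age_slope=-4.0,
                    effects={
                        "AD": _AD_NUCLEI["Whole amygdala"],
                        **(
                            {"exposed": _EXPOSED_NUCLEI["Whole amygdala"]}
                            if uniform_exposed
                            else {}
                        ),
                    },
                )
            else:
                eff = {}
                if desc.name in _AD_NUCLEI:
                    eff["AD"] = _AD_NUCLEI[desc.name]
                if uniform_exposed and desc.name in _EXPOSED_NUCLEI:
                    eff["exposed"] = _EXPOSED_NUCLEI[desc.name]
                effects[(desc.name, reg.VOLUME)] = RegionEffectSpec(
                    baseline=_NUCLEUS_FRACTIONS[desc.name], cv=0.12, effects=eff
                )

    return CohortSimConfig(
        seed=seed,
        cohorts={
            "control": CohortSpec(n=n_control, age=AgeDist(kind="uniform", low=18.0, high=81.0)),
            "AD": CohortSpec(n=n_ad, age=AgeDist(kind="normal", mean=75.5, sd=6.6, low=55.0)),
            "exposed": CohortSpec(
                n=n_exposed, age=AgeDist(kind="normal", mean=48.4, sd=12.2, low=29.0, high=75.0)
            ),
        },
        region_effects=effects,
        hemisphere_rho=0.8,
        # anchor the age drift at the control age-distribution mean so the
        # fitted model's reference age matches the generator's in expectation
        # (a mismatch adds a constant offset that biases percent changes)
        reference_age=49.5,
        spike=(
            SpikeSpec(prevalence=0.0)
            if uniform_exposed
            else SpikeSpec(
                prevalence=0.41,
                n_regions=8,
                magnitude_sd=3.0,
                regions=DEFAULT_SPIKE_REGIONS,
            )
        ),
        cognition=CognitionSpec(subtest_r=dict(DEFAULT_SUBTEST_R), anam_offset=-0.14),
    )


def null_config(n_per_cohort: int = 50, seed: int = 0) -> CohortSimConfig:
    """Fully exchangeable cohorts: calibration input for the null case.

    All group effects are 1.0, all age slopes 0, and every cohort shares the
    control age distribution — so any significant finding is a false
    positive.  (Merely zeroing the effects is not enough: cohorts at
    different ages share the control slope-fit error as a common shift,
    which inflates the group test's size.)
    """
    config = default_cohort_config(
        n_control=n_per_cohort, n_ad=n_per_cohort, n_exposed=n_per_cohort, seed=seed
    )
    for spec in config.region_effects.values():
        spec.effects = {}
        spec.slope_mult = {}
        spec.age_slope = 0.0
    for cohort in config.cohorts.values():
        cohort.age = AgeDist(kind="uniform", low=18.0, high=81.0)
    config.spike = None
    return config


# ---------------------------------------------------------------------------
# Config file round trip (YAML)
# ---------------------------------------------------------------------------


def config_to_yaml(config: CohortSimConfig, path: str | Path | None = None) -> str:
    """Serialize a config; region/metric keys become 'Region|metric' paths."""
    payload = {
        "seed": config.seed,
        "hemisphere_rho": config.hemisphere_rho,
        "reference_age": config.reference_age,
        "cohorts": {name: asdict(spec) for name, spec in config.cohorts.items()},
        "region_effects": {
            f"{region}|{metric}": asdict(spec)
            for (region, metric), spec in config.region_effects.items()
        },
        "missingness": dict(config.missingness),
        "spike": (
            {**asdict(config.spike), "regions": [f"{r}|{m}" for r, m in config.spike.regions]}
            if config.spike is not None
            else None
        ),
        "cognition": asdict(config.cognition) if config.cognition is not None else None,
        "cohort_tag_offsets": dict(config.cohort_tag_offsets),
    }
    text = yaml.safe_dump(payload, sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def config_from_yaml(source: str | Path) -> CohortSimConfig:
    """Load a config from a YAML file path or a YAML string."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    payload = yaml.safe_load(io.StringIO(text))
    cohorts = {
        name: CohortSpec(
            n=spec["n"],
            age=AgeDist(**spec["age"]),
            icv_mean=spec.get("icv_mean", 1.55e6),
            icv_sd=spec.get("icv_sd", 1.4e5),
        )
        for name, spec in payload.get("cohorts", {}).items()
    }
    region_effects = {}
    for key, spec in payload.get("region_effects", {}).items():
        region, metric = key.rsplit("|", 1)
        region_effects[(region, metric)] = RegionEffectSpec(**spec)
    spike = None
    if payload.get("spike") is not None:
        raw = dict(payload["spike"])
        raw["regions"] = tuple(tuple(t.rsplit("|", 1)) for t in raw.get("regions", []))
        spike = SpikeSpec(**raw)
    cognition = (
        CognitionSpec(**payload["cognition"]) if payload.get("cognition") is not None else None
    )
    return CohortSimConfig(
        seed=payload.get("seed", 0),
        cohorts=cohorts,
        region_effects=region_effects,
        hemisphere_rho=payload.get("hemisphere_rho", 0.8),
        reference_age=payload.get("reference_age", 41.4),
        missingness=payload.get("missingness", {}) or {},
        spike=spike,
        cognition=cognition,
        cohort_tag_offsets=payload.get("cohort_tag_offsets", {}) or {},
    )
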