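"""Age correction and volume normalization.

The pipeline order is fixed: measurements are first age-corrected with
per-key regression slopes fitted on the control cohort, then volumes are
normalized — by the subject's intracranial volume, or for hippocampal
subfields and amygdalar nuclei by the subject's same-hemisphere
age-corrected whole-hippocampus / whole-amygdala volume.  Thickness is
age-corrected but never normalized.

Age correction residualizes to the control mean age::

    value' = value - slope * (age - reference_age)

which leaves control means on the raw scale, so downstream percent
differences stay interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry as reg
from .errors import MissingDataError, ProvenanceError, ValidationError
from .io_morphometry import (
    PROV_AGE_CORRECTED,
    PROV_NORMALIZED,
    MorphometryTable,
)

logger = logging.getLogger(__name__)

KEY = ["region", "hemisphere", "metric"]


@dataclass
class AgeModel:
    """Per-key OLS slope/intercept of control values on age.

    ``params`` is indexed by (region, hemisphere, metric) with columns
    slope, intercept, n.  Keys fitted on fewer than ``min_n`` controls get
    slope 0 (value passed through unchanged) with a logged warning.
    """

    params: pd.DataFrame
    reference_age: float

    def __post_init__(self):
        if not self.reference_age > 0:
            raise ValidationError("reference_age must be > 0")
        self.params = self.params[["slope", "intercept", "n"]]

    def to_tsv(self, path: str | Path) -> None:
        out = self.params.reset_index()
        out["reference_age"] = self.reference_age
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AgeModel":
        frame = pd.read_csv(path, sep="\t")
        reference_age = float(frame["reference_age"].iloc[0])
        params = frame.set_index(KEY)[["slope", "intercept", "n"]]
        return cls(params=params, reference_age=reference_age)


def fit_age_model(controls: MorphometryTable, min_n: int = 3) -> AgeModel:
    """Fit per-key OLS of value on age over the control cohort.

    Uses pairwise-complete controls per key; reference age is the mean age
    of the control subjects supplied.
    """
    if controls.n_subjects() == 0:
        raise ValidationError("cannot fit an age model on an empty control table")
    if not controls.is_raw:
        raise ProvenanceError("age model must be fitted on raw values")
    bad_group = set(controls.subjects["group"]) - {"control"}
    if bad_group:
        raise ValidationError(f"age model requires control subjects only, found {bad_group}")

    merged = controls.merged()
    grouped = merged.groupby(KEY, sort=True)

    def _ols(frame: pd.DataFrame) -> pd.Series:
        age = frame["age"].to_numpy(float)
        value = frame["value"].to_numpy(float)
        n = len(frame)
        if n < min_n or np.ptp(age) == 0:
            return pd.Series({"slope": 0.0, "intercept": float(value.mean()), "n": n})
        am = age.mean()
        vm = value.mean()
        slope = float(((age - am) * (value - vm)).sum() / ((age - am) ** 2).sum())
        return pd.Series({"slope": slope, "intercept": vm - slope * am, "n": n})

    params = grouped.apply(_ols, include_groups=False)
    params["n"] = params["n"].astype(int)
    few = params.index[params["n"] < min_n]
    for key in few:
        logger.warning("age model: only %d controls for %s; slope forced to 0",
                       int(params.loc[key, "n"]), key)
    return AgeModel(params=params, reference_age=float(controls.subjects["age"].mean()))


def age_correct(table: MorphometryTable, model: AgeModel) -> MorphometryTable:
    """Residualize every measurement to the model's reference age.

    Applies the control-derived slopes to any cohort.  Raises
    :class:`MissingDataError` listing keys present in the table but absent
    from the model.
    """
    if not table.is_raw:
        raise ProvenanceError("age_correct expects a raw table")
    data = table.data.copy()
    keys = pd.MultiIndex.from_frame(data[KEY])
    missing = keys.difference(model.params.index)
    if len(missing):
        raise MissingDataError(
            f"{len(missing)} keys missing from age model, e.g. {list(missing[:3])}"
        )
    slope = model.params["slope"].reindex(keys).to_numpy(float)
    age = table.subjects["age"].reindex(data["subject_id"]).to_numpy(float)
    data["value"] = data["value"].to_numpy(float) - slope * (age - model.reference_age)
    return table.with_data(data, frozenset({PROV_AGE_CORRECTED}))


def normalize(
    table: MorphometryTable, registry: reg.RegionRegistry | None = None
) -> MorphometryTable:
    """Normalize age-corrected volumes by ICV or parent-structure volume.

    Volumes with norm_parent ICV divide by the subject's intracranial
    volume; hippocampal subfields divide by the subject's same-hemisphere
    age-corrected whole-hippocampus volume, amygdalar nuclei by the whole
    amygdala.  Thickness passes through unchanged.
    """
    if PROV_AGE_CORRECTED not in table.provenance:
        raise ProvenanceError("normalize requires an age_corrected table")
    if PROV_NORMALIZED in table.provenance:
        raise ProvenanceError("table is already normalized")
    registry = registry or reg.build_default_registry()

    data = table.data.copy()
    parents = {d.name: d.norm_parent for d in registry}
    norm_parent = data["region"].map(parents)
    unknown = data.loc[norm_parent.isna(), "region"].unique()
    if len(unknown):
        raise ValidationError(f"regions not in registry: {list(unknown[:5])}")

    is_volume = data["metric"] == reg.VOLUME
    denom = np.ones(len(data))

    icv_mask = is_volume & (norm_parent == reg.NORM_ICV)
    denom[icv_mask] = table.subjects["icv"].reindex(data.loc[icv_mask, "subject_id"]).to_numpy(float)

    for parent_kind, parent_region in (
        (reg.NORM_WHOLE_HIPPOCAMPUS, reg.WHOLE_HIPPOCAMPUS),
        (reg.NORM_WHOLE_AMYGDALA, reg.WHOLE_AMYGDALA),
    ):
        mask = is_volume & (norm_parent == parent_kind)
        if not mask.any():
            continue
        parent_rows = data[(data["region"] == parent_region) & (data["metric"] == reg.VOLUME)]
        parent_map = parent_rows.set_index(["subject_id", "hemisphere"])["value"]
        if parent_map.index.duplicated().any():
            raise ValidationError(f"duplicate {parent_region} rows")
        idx = pd.MultiIndex.from_frame(data.loc[mask, ["subject_id", "hemisphere"]])
        values = parent_map.reindex(idx).to_numpy(float)
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            offenders = sorted(set(idx[bad].get_level_values(0)))
            raise MissingDataError(
                f"missing or non-positive {parent_region} denominator for subjects "
                f"{offenders[:5]}"
            )
        denom[mask] = values

    if (denom <= 0).any():
        bad_ids = sorted(set(data.loc[denom <= 0, "subject_id"]))
        raise MissingDataError(f"non-positive normalization denominator for {bad_ids[:5]}")

    data["value"] = data["value"].to_numpy(float) / denom
    return table.with_data(data, table.provenance | {PROV_NORMALIZED})


def preprocess_pipeline(
    table: MorphometryTable,
    model: AgeModel,
    registry: reg.RegionRegistry | None = None,
) -> MorphometryTable:
    """Convenience: age-correct then normalize in the fixed order."""
    return normalize(age_correct(table, model), registry)
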