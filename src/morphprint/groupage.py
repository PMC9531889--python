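"""Age x group interaction regression on regional volumes.

Fits ordinary least squares with the fixed design
``[1, age, group, age * group]`` (group coded 0 = control, 1 = case) and
reports per-coefficient t-based inference plus the overall ANOVA F.

Inputs are typically ICV-normalized but NOT age-corrected volumes: age is a
regressor here, and feeding age-residualized values would null the age
coefficient by construction.  Raw volumes are also accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import registry as reg
from .errors import DegenerateStatisticsError, ValidationError
from .io_morphometry import MorphometryTable

COEF_NAMES = ("intercept", "age", "group", "age_group")


@dataclass
class InteractionFit:
    """OLS fit of value ~ 1 + age + group + age:group."""

    region: str
    metric: str
    coef: dict[str, float]
    se: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    n: int
    r_squared: float
    f_statistic: float
    f_pvalue: float
    group_coding: str = "0=control, 1=case"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": list(COEF_NAMES),
                "estimate": [self.coef[c] for c in COEF_NAMES],
                "se": [self.se[c] for c in COEF_NAMES],
                "t": [self.t_values[c] for c in COEF_NAMES],
                "p": [self.p_values[c] for c in COEF_NAMES],
            }
        )


def fit_interaction(
    values,
    ages,
    groups,
    region: str = "",
    metric: str = reg.VOLUME,
) -> InteractionFit:
    """Fit the four-column interaction design by OLS.

    ``groups`` holds 0/1 indicators (or booleans); both levels must be
    present, ages must vary, and at least 5 subjects are required.
    """
    y = np.asarray(values, float)
    age = np.asarray(ages, float)
    group = np.asarray(groups, float)
    if not (len(y) == len(age) == len(group)):
        raise ValidationError("values, ages and groups must have equal length")
    if len(y) < 5:
        raise ValidationError("need >= 5 subjects for the interaction fit")
    if not set(np.unique(group)) <= {0.0, 1.0}:
        raise ValidationError("groups must be coded 0 (control) / 1 (case)")
    if len(np.unique(group)) < 2:
        raise DegenerateStatisticsError("both groups must be present")
    if np.ptp(age) == 0:
        raise DegenerateStatisticsError("constant age: design is rank-deficient")

    X = np.column_stack([np.ones_like(age), age, group, age * group])
    if np.linalg.matrix_rank(X) < 4:
        raise DegenerateStatisticsError("rank-deficient interaction design")
    fit = sm.OLS(y, X).fit()

    def _named(values_) -> dict[str, float]:
        return {name: float(v) for name, v in zip(COEF_NAMES, values_)}

    return InteractionFit(
        region=region,
        metric=metric,
        coef=_named(fit.params),
        se=_named(fit.bse),
        t_values=_named(fit.tvalues),
        p_values=_named(fit.pvalues),
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
    )


def fit_interaction_from_table(
    table: MorphometryTable,
    region: str,
    hemisphere: str,
    case_group: str,
    control_group: str = "control",
    metric: str = reg.VOLUME,
    icv_normalize: bool = True,
    registry: reg.RegionRegistry | None = None,
) -> InteractionFit:
    """Extract one region's values from a (raw) table and fit the interaction.

    Volumes are divided by each subject's ICV when ``icv_normalize`` is on
    (the default); the table is deliberately NOT age-corrected first.
    """
    registry = registry or reg.build_default_registry()
    desc = registry.lookup(region)
    if metric not in desc.metrics:
        raise ValidationError(f"{desc.name!r} has no {metric} metric")
    rows = table.data[
        (table.data["region"] == desc.name)
        & (table.data["hemisphere"] == hemisphere)
        & (table.data["metric"] == metric)
    ]
    if rows.empty:
        raise ValidationError(f"no measurements for {desc.name}/{hemisphere}/{metric}")
    demo = table.subjects.reindex(rows["subject_id"])
    keep = demo["group"].isin([case_group, control_group]).to_numpy()
    rows, demo = rows[keep], demo[keep]
    values = rows["value"].to_numpy(float)
    if icv_normalize and metric == reg.VOLUME:
        values = values / demo["icv"].to_numpy(float)
    return fit_interaction(
        values,
        demo["age"].to_numpy(float),
        (demo["group"] == case_group).to_numpy(float),
        region=desc.name,
        metric=metric,
    )
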