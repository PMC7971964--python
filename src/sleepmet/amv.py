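"""The observational arm: adjusted multivariable regression per cohort.

Each cohort contributes, for every (sleep exposure, metabolite) pair, the
ordinary-least-squares coefficient of the metabolite on the exposure
adjusted for age, sex and BMI. Metabolites are log-transformed and
standardized within cohort beforehand, so coefficients are in SD units of
log concentration per exposure unit (binary exposures coded 1 = index
category, duration in hours). Cohort results are then pooled by fixed-
and random-effects inverse-variance meta-analysis; the fixed-effect
result is the headline observational estimate.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import ValidationError
from .meta import MetaEstimate, fixed_effect_meta, random_effect_meta

__all__ = [
    "CohortAssoc",
    "prepare_metabolites",
    "fit_cohort",
    "meta_cohorts",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "BMI")


@dataclasses.dataclass
class CohortAssoc:
    """One cohort's adjusted regression coefficient for one pair."""

    cohort: str
    exposure: str
    metabolite: str
    beta: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError("cohort association SE must be positive")


def prepare_metabolites(
    table: pd.DataFrame,
    columns: Sequence[str],
    *,
    log: bool = True,
    standardize: bool = True,
) -> pd.DataFrame:
    """Log-transform and z-score metabolite columns within a cohort.

    Raises if a column to be logged is not strictly positive or has zero
    variance after transformation.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(float)
        if log:
            if np.any(x <= 0):
                raise ValidationError(f"{col}: non-positive values cannot be logged")
            x = np.log(x)
        if standardize:
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"{col}: zero variance, cannot standardize")
            x = (x - x.mean()) / sd
        out[col] = x
    return out


def fit_cohort(
    table: pd.DataFrame,
    exposure: str,
    metabolite: str,
    *,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cohort: str = "",
) -> CohortAssoc:
    """OLS of metabolite on exposure + covariates; returns the exposure term.

    Missing values are handled by listwise deletion. Passing an empty
    ``covariates`` sequence gives the unadjusted (crude) association.
    """
    cols = [metabolite, exposure, *covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table lacks column(s): {', '.join(missing)}")
    data = table[cols].dropna()
    n = len(data)
    n_params = 2 + len(covariates)  # intercept + exposure + covariates
    if n < n_params + 1:
        raise ValidationError(
            f"n = {n} below parameter count + 1 ({n_params + 1}) for {metabolite}"
        )
    x_exp = data[exposure].to_numpy(float)
    if np.ptp(x_exp) == 0:
        raise ValidationError(f"no contrast: exposure {exposure!r} constant in cohort")
    design = sm.add_constant(data[[exposure, *covariates]].astype(float))
    fit = sm.OLS(data[metabolite].astype(float), design).fit()
    return CohortAssoc(
        cohort=cohort,
        exposure=exposure,
        metabolite=metabolite,
        beta=float(fit.params[exposure]),
        se=float(fit.bse[exposure]),
        n=n,
    )


def meta_cohorts(
    assocs: Sequence[CohortAssoc],
) -> tuple[MetaEstimate, MetaEstimate | None]:
    """Pool per-cohort associations: (fixed-effect, random-effects).

    All inputs must refer to the same exposure and metabolite. The random-
    effects result is None when only one cohort is available.
    """
    if not assocs:
        raise ValidationError("no cohort associations to pool")
    labels = {(a.exposure, a.metabolite) for a in assocs}
    if len(labels) != 1:
        raise ValidationError(f"mixed exposure/metabolite labels in pooling: {labels}")
    pairs = [(a.beta, a.se) for a in assocs]
    fixed = fixed_effect_meta(pairs)
    random = random_effect_meta(pairs) if len(pairs) >= 2 else None
    return fixed, random


def assocs_to_frame(assocs: Sequence[CohortAssoc]) -> pd.DataFrame:
    cols = ["cohort", "exposure", "metabolite", "beta", "se", "n"]
    return pd.DataFrame([{c: getattr(a, c) for c in cols} for a in assocs], columns=cols)
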