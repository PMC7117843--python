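"""External 10-year fracture-probability ingestion and risk-factor imputation.

The FRAX algorithm itself is a proprietary external tool: per-subject
10-year MOF and hip probabilities arrive as input columns and are only
summarized here.  What *is* implemented is the upstream preparation step —
filling in missing clinical risk factors from their conditional association
with the observed ones — and the mean-predicted-versus-observed comparison.

Glucocorticoid use and rheumatoid arthritis are pinned to "no": they were
exclusion criteria of the trial population this pipeline models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .cohort import CohortTable

__all__ = ["RiskFactorProfile", "ImputationError", "impute_missing", "frax_summary"]

_CONTINUOUS = ("age_years", "bmi", "femoral_neck_tscore")
_BINARY = ("prior_fracture", "parental_hip_fracture", "alcohol_3_units", "current_smoker")
MIN_COMPLETE_CASES = 20


class ImputationError(ValueError):
    pass


@dataclass
class RiskFactorProfile:
    """Clinical risk factors of one subject as a FRAX-style questionnaire.

    ``None`` marks a missing value.  ``glucocorticoid_use`` and
    ``rheumatoid_arthritis`` are always ``False`` (trial exclusion criteria)
    and may not be set otherwise.
    """

    age_years: Optional[float] = None
    bmi: Optional[float] = None
    femoral_neck_tscore: Optional[float] = None
    prior_fracture: Optional[bool] = None
    parental_hip_fracture: Optional[bool] = None
    alcohol_3_units: Optional[bool] = None
    current_smoker: Optional[bool] = None
    glucocorticoid_use: bool = False
    rheumatoid_arthritis: bool = False

    def __post_init__(self):
        if self.glucocorticoid_use or self.rheumatoid_arthritis:
            raise ValueError(
                "glucocorticoid_use and rheumatoid_arthritis are exclusion "
                "criteria and must remain False"
            )


def _field_array(profiles: list[RiskFactorProfile], name: str) -> np.ndarray:
    return np.array(
        [np.nan if getattr(p, name) is None else float(getattr(p, name)) for p in profiles]
    )


def impute_missing(profiles: list[RiskFactorProfile], seed: int) -> list[RiskFactorProfile]:
    """Fill missing risk factors by conditional models fitted on complete cases.

    Continuous fields are imputed first, each from the other two continuous
    fields by OLS plus a Gaussian residual draw; binary fields are then drawn
    from logistic models with the (now complete) continuous fields as
    predictors.  Deterministic given ``seed``; observed values are never
    altered.  Requires ≥ 20 complete cases per imputed field.
    """
    rng = np.random.default_rng(seed)
    values = {name: _field_array(profiles, name) for name in _CONTINUOUS + _BINARY}

    # continuous fields from the other continuous fields
    for name in _CONTINUOUS:
        miss = np.isnan(values[name])
        if not miss.any():
            continue
        others = [o for o in _CONTINUOUS if o != name]
        pred = np.column_stack([values[o] for o in others])
        complete = ~np.isnan(values[name]) & ~np.isnan(pred).any(axis=1)
        if complete.sum() < MIN_COMPLETE_CASES:
            raise ImputationError(
                f"field {name!r}: only {int(complete.sum())} complete cases "
                f"(need ≥ {MIN_COMPLETE_CASES})"
            )
        X = sm.add_constant(pred[complete])
        fit = sm.OLS(values[name][complete], X).fit()
        target = miss & ~np.isnan(pred).any(axis=1)
        if (miss & ~target).any():
            raise ImputationError(
                f"field {name!r}: cannot impute rows missing the other continuous fields"
            )
        mean = sm.add_constant(pred[target], has_constant="add") @ fit.params
        sd = float(np.sqrt(fit.scale))
        values[name] = values[name].copy()
        values[name][target] = mean + rng.normal(0, sd, size=target.sum())

    # binary fields from the continuous fields
    cont = np.column_stack([values[o] for o in _CONTINUOUS])
    for name in _BINARY:
        miss = np.isnan(values[name])
        if not miss.any():
            continue
        complete = ~miss
        if complete.sum() < MIN_COMPLETE_CASES:
            raise ImputationError(
                f"field {name!r}: only {int(complete.sum())} complete cases "
                f"(need ≥ {MIN_COMPLETE_CASES})"
            )
        X = sm.add_constant(cont[complete])
        y = values[name][complete]
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        p = fit.predict(sm.add_constant(cont[miss], has_constant="add"))
        values[name] = values[name].copy()
        values[name][miss] = (rng.random(miss.sum()) < p).astype(float)

    out = []
    for i, p in enumerate(profiles):
        out.append(
            RiskFactorProfile(
                age_years=float(values["age_years"][i]),
                bmi=float(values["bmi"][i]),
                femoral_neck_tscore=float(values["femoral_neck_tscore"][i]),
                prior_fracture=bool(values["prior_fracture"][i])
                if not np.isnan(values["prior_fracture"][i]) else None,
                parental_hip_fracture=bool(values["parental_hip_fracture"][i])
                if not np.isnan(values["parental_hip_fracture"][i]) else None,
                alcohol_3_units=bool(values["alcohol_3_units"][i])
                if not np.isnan(values["alcohol_3_units"][i]) else None,
                current_smoker=bool(values["current_smoker"][i])
                if not np.isnan(values["current_smoker"][i]) else None,
            )
        )
    return out


def frax_summary(cohort: CohortTable, endpoint: str) -> tuple[float, tuple[float, float]]:
    """Mean externally predicted 10-year probability with a normal 95% CI.

    ``endpoint`` is ``"mof"`` or ``"hip"``; the CI is
    ``mean ± 1.96 · SD/√n`` over subjects with a non-missing probability.
    """
    if endpoint == "mof":
        vals = [s.frax_mof_prob for s in cohort.subjects]
    elif endpoint == "hip":
        vals = [s.frax_hip_prob for s in cohort.subjects]
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected 'mof' or 'hip'")
    x = np.array([v for v in vals if v is not None], dtype=float)
    if len(x) == 0:
        raise ValueError(f"no subject has a non-missing {endpoint} probability")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    half = 1.959963984540054 * sd / np.sqrt(len(x))
    return mean, (mean - half, mean + half)
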