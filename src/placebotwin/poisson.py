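"""Poisson regression of core-period fracture counts with person-time offset.

This is the engine behind the virtual-twin counterfactual: a log-linear
model for the number of MOF events a subject accrues while untreated,

    log E[count_i] = beta · x_i + log(t_i),

fitted by Newton/IRLS on the placebo (crossover) arm's core-period data.
The response is the event *count* (recurrent events included), not a
first-event indicator.  Predictors: age, BMI, prior vertebral and prior
nonvertebral fracture indicators, total-hip T-score (switchable to
femoral-neck), ever-smoker.

No overdispersion adjustment is applied; a quasi-Poisson Pearson scale
factor is reported as a diagnostic only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .cohort import CohortArrays, CohortTable, event_count_arrays

__all__ = [
    "PredictorVector",
    "PoissonFit",
    "PoissonFitError",
    "fit_placebo_poisson",
    "fit_poisson_counts",
    "expected_count",
]

PREDICTOR_NAMES = (
    "intercept",
    "age_years",
    "bmi",
    "prior_vertebral_fx",
    "prior_nonvertebral_fx",
    "total_hip_tscore",
    "ever_smoker",
)

GRADIENT_TOL = 1e-8
MAX_ITER = 100


class PoissonFitError(RuntimeError):
    """Raised for rank-deficient designs or non-converged fits."""


@dataclass
class PredictorVector:
    """Covariate vector of one (real or virtual) subject at a period baseline."""

    age_years: float
    bmi: float
    prior_vertebral_fx: int
    prior_nonvertebral_fx: int
    total_hip_tscore: float
    ever_smoker: int

    def __post_init__(self):
        for name in ("prior_vertebral_fx", "prior_nonvertebral_fx", "ever_smoker"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v!r}")
        for name in ("age_years", "bmi", "total_hip_tscore"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_design_row(self) -> np.ndarray:
        return np.array(
            [1.0, self.age_years, self.bmi, self.prior_vertebral_fx,
             self.prior_nonvertebral_fx, self.total_hip_tscore, self.ever_smoker]
        )


@dataclass
class PoissonFit:
    """A fitted log-linear rate model (MLE, observed-information covariance)."""

    coefficients: np.ndarray
    covariance: np.ndarray
    predictor_names: tuple
    n_subjects: int
    total_events: float
    total_person_years: float
    converged: bool
    n_iter: int = 0
    pearson_scale: float = float("nan")

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "covariance": self.covariance.tolist(),
                "predictor_names": list(self.predictor_names),
                "n_subjects": self.n_subjects,
                "total_events": self.total_events,
                "total_person_years": self.total_person_years,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "pearson_scale": self.pearson_scale,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PoissonFit":
        d = json.loads(text)
        return cls(
            coefficients=np.array(d["coefficients"]),
            covariance=np.array(d["covariance"]),
            predictor_names=tuple(d["predictor_names"]),
            n_subjects=int(d["n_subjects"]),
            total_events=float(d["total_events"]),
            total_person_years=float(d["total_person_years"]),
            converged=bool(d["converged"]),
            n_iter=int(d.get("n_iter", 0)),
            pearson_scale=float(d.get("pearson_scale", float("nan"))),
        )


def _check_rank(X: np.ndarray, names: Iterable[str]) -> None:
    # name the collinear columns via the QR diagonal
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = [n for n, d in zip(names, diag) if d < 1e-10 * scale]
    if bad:
        raise PoissonFitError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_poisson_counts(
    X: np.ndarray,
    counts: np.ndarray,
    exposure: np.ndarray,
    names: tuple = PREDICTOR_NAMES,
) -> PoissonFit:
    """Newton/IRLS maximum likelihood for counts with a log-exposure offset.

    Iterates to max-norm of the score below 1e-8 (or 100 iterations, after
    which the fit is flagged non-converged and downstream consumers refuse
    it).  Covariance is the inverse observed information X' diag(mu) X.
    """
    X = np.asarray(X, dtype=float)
    counts = np.asarray(counts, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if np.any(exposure <= 0):
        raise ValueError("all exposures must be positive")
    _check_rank(X, names)
    offset = np.log(exposure)

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(counts.sum(), 0.5) / exposure.sum())
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta + offset
        mu = np.exp(eta)
        score = X.T @ (counts - mu)
        if np.max(np.abs(score)) < GRADIENT_TOL:
            converged = True
            break
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise PoissonFitError(f"singular information matrix at iteration {it}") from exc
        # dampen huge steps (rare: near-degenerate data)
        nstep = np.max(np.abs(step))
        if nstep > 10:
            step *= 10 / nstep
        beta = beta + step

    mu = np.exp(X @ beta + offset)
    H = (X * mu[:, None]).T @ X
    cov = np.linalg.inv(H)
    resid_pearson = (counts - mu) / np.sqrt(mu)
    dof = max(len(counts) - X.shape[1], 1)
    return PoissonFit(
        coefficients=beta,
        covariance=cov,
        predictor_names=tuple(names),
        n_subjects=len(counts),
        total_events=float(counts.sum()),
        total_person_years=float(exposure.sum()),
        converged=converged,
        n_iter=it,
        pearson_scale=float(np.sum(resid_pearson ** 2) / dof),
    )


def design_matrix(arrays: CohortArrays, tscore: np.ndarray,
                  composite_prior: bool = False) -> np.ndarray:
    """Design matrix in :data:`PREDICTOR_NAMES` order for given T-scores."""
    if composite_prior:
        either = np.maximum(arrays.prior_vert, arrays.prior_nonvert)
        cols = [np.ones(len(arrays)), arrays.age, arrays.bmi, either,
                np.zeros(len(arrays)), tscore, arrays.smoker]
        return np.column_stack(cols)
    return np.column_stack([
        np.ones(len(arrays)), arrays.age, arrays.bmi, arrays.prior_vert,
        arrays.prior_nonvert, tscore, arrays.smoker,
    ])


def fit_placebo_poisson(
    cohort: CohortTable,
    event_set: Iterable[str],
    tscore_predictor: str = "total_hip",
    composite_prior: bool = False,
    counts: Optional[np.ndarray] = None,
    arrays: Optional[CohortArrays] = None,
) -> PoissonFit:
    """Fit the untreated fracture-rate model on the crossover arm's core data.

    ``count_i`` is the number of ``event_set`` events during subject *i*'s
    core follow-up and the offset is ``log(core follow-up years)``.
    ``tscore_predictor`` selects ``"total_hip"`` (default) or
    ``"femoral_neck"`` as the bone-density predictor.
    """
    if arrays is None:
        arrays = CohortArrays.from_cohort(cohort)
    if counts is None:
        counts = event_count_arrays(cohort, event_set)["core_count"]
    mask = arrays.is_crossover & (arrays.core_fu > 0)
    if not np.any(mask):
        raise PoissonFitError("no placebo (crossover) subjects with positive core follow-up")
    sub = arrays.take(np.nonzero(mask)[0])
    if tscore_predictor == "total_hip":
        tsc = sub.thip_base
    elif tscore_predictor == "femoral_neck":
        tsc = sub.fn_tscore
    else:
        raise ValueError(f"unknown tscore_predictor {tscore_predictor!r}")
    X = design_matrix(sub, tsc, composite_prior=composite_prior)
    names = PREDICTOR_NAMES
    if composite_prior:
        # the empty second history slot would be collinear; drop it
        keep = [0, 1, 2, 3, 5, 6]
        X = X[:, keep]
        names = tuple(PREDICTOR_NAMES[i] for i in keep)
        names = tuple(n if n != "prior_vertebral_fx" else "prior_any_fx" for n in names)
    fit = fit_poisson_counts(X, np.asarray(counts)[mask], sub.core_fu, names=names)
    if not fit.converged:
        raise PoissonFitError("Poisson fit did not converge; refusing downstream use")
    return fit


def expected_count(fit: PoissonFit, x: "PredictorVector | np.ndarray",
                   person_years: float) -> float:
    """Model-expected event count ``exp(beta · x) × person_years``."""
    if person_years < 0:
        raise ValueError("person_years must be non-negative")
    if not fit.converged:
        raise PoissonFitError("refusing prediction from a non-converged fit")
    row = x.to_design_row() if isinstance(x, PredictorVector) else np.asarray(x, dtype=float)
    return float(np.exp(row @ fit.coefficients) * person_years)
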