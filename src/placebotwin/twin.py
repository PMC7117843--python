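"""Virtual-twin construction: counterfactual placebo outcomes for treated
subjects.

For each 10-year completer of the long-term active arm, a *virtual twin* is
built: an untreated duplicate with identical baseline covariates whose
fracture experience is predicted from models calibrated on the crossover
(placebo-in-core) arm:

1. core-period expected MOF count from the placebo-calibrated Poisson rate
   model evaluated at baseline covariates over 3 person-years;
2. a stochastic fracture-history update at extension baseline — a Bernoulli
   draw with probability ``1 − exp(−μ_core)``, assigned to the vertebral or
   nonvertebral history slot with the placebo arm's empirical vertebral
   share of core events (an expectation-weighting variant is available);
3. an end-of-core total-hip T-score simulated from a linear model
   (age, baseline T-score, BMI) fitted on the crossover arm, plus Gaussian
   residual noise;
4. extension-period expected count from the same Poisson model at the
   updated covariates (age + 3, carried-forward BMI and smoking, updated
   history, simulated T-score) over 7 person-years;
5. the two expected counts are summed as a cumulative hazard and converted
   to a 10-year incidence by ``1 − exp(−Λ)`` (a count-scale alternative is
   available for sensitivity analysis).

A low-event guard refuses the whole analysis when the placebo arm's
core-period event count is too small for a stable rate model — mirroring
the refusal of hip-specific estimates in sparse trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .cohort import (
    CORE_YEARS,
    EXTENSION_YEARS,
    CohortArrays,
    CohortTable,
    SubjectRecord,
    event_count_arrays,
)
from .poisson import PoissonFit, PoissonFitError, expected_count

__all__ = [
    "TScoreFit",
    "TwinRecord",
    "GuardResult",
    "fit_tscore_model",
    "vertebral_event_split",
    "make_virtual_twin",
    "twin_cohort_incidence",
    "low_event_guard",
]

TSCORE_PREDICTORS = ("intercept", "age_years", "total_hip_tscore_baseline", "bmi")


@dataclass
class TScoreFit:
    """OLS model of end-of-core total-hip T-score on baseline covariates."""

    coefficients: np.ndarray  # intercept, age, baseline T-score, BMI
    residual_sd: float
    n: int

    def predict_mean(self, age: np.ndarray, thip_base: np.ndarray, bmi: np.ndarray) -> np.ndarray:
        b = self.coefficients
        return b[0] + b[1] * np.asarray(age) + b[2] * np.asarray(thip_base) + b[3] * np.asarray(bmi)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "predictor_names": list(TSCORE_PREDICTORS),
                "residual_sd": self.residual_sd,
                "n": self.n,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TScoreFit":
        d = json.loads(text)
        return cls(
            coefficients=np.array(d["coefficients"]),
            residual_sd=float(d["residual_sd"]),
            n=int(d["n"]),
        )


@dataclass
class TwinRecord:
    """The counterfactual placebo twin of one long-term completer."""

    subject_id: str
    core_expected_count: float
    core_predicted_fx_vertebral: int
    core_predicted_fx_nonvertebral: int
    ext_tscore_simulated: float
    ext_expected_count: float
    ten_year_incidence: float
    tscore_z: float  # the standard-normal draw behind the simulated T-score


@dataclass
class GuardResult:
    """Typed pass/refuse outcome of the low-event guard."""

    passed: bool
    n_events: int
    min_events: int
    overridden: bool
    message: str


class TwinEngineError(RuntimeError):
    pass


def fit_tscore_model(cohort: CohortTable, arrays: Optional[CohortArrays] = None) -> TScoreFit:
    """Fit the end-of-core T-score model on crossover subjects.

    Uses crossover-arm subjects with a recorded end-of-core total-hip
    T-score.  A perfect (zero-residual) fit is rejected as degenerate: the
    twin's T-score must carry sampling noise.
    """
    if arrays is None:
        arrays = CohortArrays.from_cohort(cohort)
    mask = arrays.is_crossover & np.isfinite(arrays.thip_end_core)
    idx = np.nonzero(mask)[0]
    if len(idx) < 5:
        raise TwinEngineError(
            f"need ≥ 5 crossover subjects with end-of-core T-score, found {len(idx)}"
        )
    return _fit_tscore_arrays(
        arrays.age[idx], arrays.thip_base[idx], arrays.bmi[idx], arrays.thip_end_core[idx]
    )


def _fit_tscore_arrays(age, thip_base, bmi, y) -> TScoreFit:
    X = np.column_stack([np.ones(len(age)), age, thip_base, bmi])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise TwinEngineError("collinear T-score design matrix")
    resid = y - X @ coef
    dof = len(y) - 4
    if dof <= 0:
        raise TwinEngineError("too few subjects for a 4-parameter T-score model")
    residual_sd = float(np.sqrt(resid @ resid / dof))
    if residual_sd < 1e-10:
        raise TwinEngineError(
            "degenerate (perfect) T-score fit: residual SD is zero, so simulated "
            "twin T-scores would carry no noise"
        )
    return TScoreFit(coefficients=coef, residual_sd=residual_sd, n=len(y))


def vertebral_event_split(cohort: CohortTable, event_set: Iterable[str],
                          counts: Optional[dict] = None,
                          arrays: Optional[CohortArrays] = None) -> float:
    """Placebo-arm empirical share of core-period events that are vertebral.

    Used to assign a twin's predicted core fracture to the vertebral versus
    nonvertebral history slot.  Falls back to 0.5 when the placebo arm had
    no core events at all.
    """
    if counts is None:
        counts = event_count_arrays(cohort, event_set)
    if arrays is None:
        arrays = CohortArrays.from_cohort(cohort)
    m = arrays.is_crossover
    vert = counts["core_vert"][m].sum()
    nonvert = counts["core_nonvert"][m].sum()
    total = vert + nonvert
    return float(vert / total) if total > 0 else 0.5


def _twin_incidences_arrays(
    age: np.ndarray,
    bmi: np.ndarray,
    prior_vert: np.ndarray,
    prior_nonvert: np.ndarray,
    thip_base: np.ndarray,
    smoker: np.ndarray,
    pfit: PoissonFit,
    tfit: TScoreFit,
    rng: np.random.Generator,
    split_vertebral: float,
    history_mode: str = "draw",
    composition: str = "hazard",
) -> dict:
    """Vectorized twin construction; returns per-twin arrays."""
    if not pfit.converged:
        raise PoissonFitError("refusing twins from a non-converged Poisson fit")
    n = len(age)
    beta = pfit.coefficients
    Xc = np.column_stack([np.ones(n), age, bmi, prior_vert, prior_nonvert, thip_base, smoker])
    mu_core = np.exp(Xc @ beta) * CORE_YEARS
    p_event = -np.expm1(-mu_core)

    if history_mode == "draw":
        hit = rng.random(n) < p_event
        is_vert = rng.random(n) < split_vertebral
        new_vert = (hit & is_vert).astype(float)
        new_nonvert = (hit & ~is_vert).astype(float)
        pv_ext = np.maximum(prior_vert, new_vert)
        pnv_ext = np.maximum(prior_nonvert, new_nonvert)
    elif history_mode == "expectation":
        new_vert = p_event * split_vertebral
        new_nonvert = p_event * (1 - split_vertebral)
        pv_ext = prior_vert + (1 - prior_vert) * new_vert
        pnv_ext = prior_nonvert + (1 - prior_nonvert) * new_nonvert
    else:
        raise ValueError(f"unknown history_mode {history_mode!r}")

    z = rng.standard_normal(n)
    t_sim = tfit.predict_mean(age, thip_base, bmi) + z * tfit.residual_sd

    Xe = np.column_stack([np.ones(n), age + CORE_YEARS, bmi, pv_ext, pnv_ext, t_sim, smoker])
    mu_ext = np.exp(Xe @ beta) * EXTENSION_YEARS

    lam = mu_core + mu_ext
    if composition == "hazard":
        inc = -np.expm1(-lam)
    elif composition == "count":
        inc = lam  # uncapped expected count, sensitivity analysis only
    else:
        raise ValueError(f"unknown composition {composition!r}")
    return {
        "mu_core": mu_core,
        "new_vert": new_vert,
        "new_nonvert": new_nonvert,
        "t_sim": t_sim,
        "z": z,
        "mu_ext": mu_ext,
        "incidence": inc,
    }


def make_virtual_twin(
    subject: SubjectRecord,
    pfit: PoissonFit,
    tfit: TScoreFit,
    rng: np.random.Generator,
    split_vertebral: float = 0.5,
    history_mode: str = "draw",
    composition: str = "hazard",
) -> TwinRecord:
    """Build the virtual placebo twin of one long-term 10-year completer."""
    if subject.arm != "denosumab_longterm" or not subject.is_ten_year_completer:
        raise TwinEngineError(
            f"subject {subject.subject_id}: twins are built only for 10-year "
            "completers of the long-term active arm"
        )
    out = _twin_incidences_arrays(
        np.array([subject.age_years]),
        np.array([subject.bmi]),
        np.array([float(subject.prior_vertebral_fx)]),
        np.array([float(subject.prior_nonvertebral_fx)]),
        np.array([subject.total_hip_tscore_baseline]),
        np.array([float(subject.ever_smoker)]),
        pfit, tfit, rng, split_vertebral, history_mode, composition,
    )
    return TwinRecord(
        subject_id=subject.subject_id,
        core_expected_count=float(out["mu_core"][0]),
        core_predicted_fx_vertebral=int(round(float(out["new_vert"][0]))),
        core_predicted_fx_nonvertebral=int(round(float(out["new_nonvert"][0]))),
        ext_tscore_simulated=float(out["t_sim"][0]),
        ext_expected_count=float(out["mu_ext"][0]),
        ten_year_incidence=float(out["incidence"][0]),
        tscore_z=float(out["z"][0]),
    )


def twin_cohort_incidence(
    cohort: CohortTable,
    pfit: PoissonFit,
    tfit: TScoreFit,
    rng: np.random.Generator,
    split_vertebral: Optional[float] = None,
    event_set: Iterable[str] = None,
    history_mode: str = "draw",
    composition: str = "hazard",
    arrays: Optional[CohortArrays] = None,
) -> float:
    """Mean twin 10-year incidence over all long-term 10-year completers."""
    from .cohort import MOF_EVENTS

    if event_set is None:
        event_set = MOF_EVENTS
    if arrays is None:
        arrays = CohortArrays.from_cohort(cohort)
    if split_vertebral is None:
        split_vertebral = vertebral_event_split(cohort, event_set, arrays=arrays)
    mask = ~arrays.is_crossover & arrays.completer
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise TwinEngineError("no long-term 10-year completers in the cohort")
    out = _twin_incidences_arrays(
        arrays.age[idx], arrays.bmi[idx], arrays.prior_vert[idx],
        arrays.prior_nonvert[idx], arrays.thip_base[idx], arrays.smoker[idx],
        pfit, tfit, rng, split_vertebral, history_mode, composition,
    )
    return float(np.mean(out["incidence"]))


def low_event_guard(
    cohort: CohortTable,
    event_set: Iterable[str],
    min_events: int = 20,
    override: bool = False,
    counts: Optional[dict] = None,
    arrays: Optional[CohortArrays] = None,
) -> GuardResult:
    """Refuse the twin analysis when placebo-arm core events are too sparse.

    Returns a typed outcome, never raises: refusal carries an explanatory
    message; an explicit override passes with a recorded warning.
    """
    if counts is None:
        counts = event_count_arrays(cohort, event_set)
    if arrays is None:
        arrays = CohortArrays.from_cohort(cohort)
    n_events = int(counts["core_count"][arrays.is_crossover].sum())
    if n_events >= min_events:
        return GuardResult(True, n_events, min_events, False,
                           f"{n_events} placebo-arm core events (≥ {min_events}): ok")
    if override:
        return GuardResult(
            True, n_events, min_events, True,
            f"WARNING: only {n_events} placebo-arm core events (< {min_events}); "
            "estimates may be unreliable — guard overridden",
        )
    return GuardResult(
        False, n_events, min_events, False,
        f"refused: only {n_events} placebo-arm core-period events of the requested "
        f"types (< {min_events}); the rate model would be unreliable. "
        "Pass an explicit override to proceed anyway.",
    )
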