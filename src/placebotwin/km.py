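"""Product-limit (Kaplan–Meier) cumulative fracture incidence.

Implements the standard product-limit estimator on per-subject
time-to-first-event data with Greenwood variance and 95% confidence
intervals on the complementary log-log scale (so intervals stay inside
[0, 1]).  The curve is a right-continuous step function; the horizon
read-out is its value at the requested horizon.

Ties between an event and a censoring at the same timestamp are resolved
events-first (the standard convention).  The estimator is kept in plain
numpy because it runs inside the bootstrap hot loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .cohort import CohortTable, first_event_time

__all__ = ["KMEstimate", "ComparisonRow", "km_fit", "km_fit_arrays", "km_compare_report"]

_Z = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class KMEstimate:
    """A fitted product-limit curve with a horizon read-out.

    ``event_times`` are the distinct observed event times; ``survival`` and
    ``cumulative_incidence`` are the step values just after each;
    ``greenwood_variance`` is the variance of the survival estimate.
    ``horizon_readout`` is ``(incidence, ci_low, ci_high)`` at the horizon.
    """

    event_times: np.ndarray
    survival: np.ndarray
    cumulative_incidence: np.ndarray
    greenwood_variance: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    horizon: float
    horizon_readout: tuple[float, float, float]
    n_subjects: int

    def incidence_at(self, t: float) -> float:
        """Right-continuous step-function value of cumulative incidence at t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumulative_incidence[idx])


@dataclass
class ComparisonRow:
    """Observed-versus-reference incidence comparison used by the report."""

    observed: float
    observed_ci: tuple[float, float]
    reference: float
    reference_ci: Optional[tuple[float, float]]
    difference: float


def km_fit_arrays(times: np.ndarray, observed: np.ndarray, horizon: float,
                  ci_transform: str = "cloglog") -> KMEstimate:
    """Product-limit fit on raw (time, event-indicator) arrays."""
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    n = len(times)
    if n == 0:
        raise ValueError("no subjects at risk at time 0")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if np.any(times < 0):
        raise ValueError("negative follow-up time")

    order = np.lexsort((~observed, times))  # events precede censorings at ties
    t_sorted = times[order]
    e_sorted = observed[order]

    ev_times = t_sorted[e_sorted]
    uniq, first_idx = np.unique(ev_times, return_index=True)
    d = np.diff(np.append(first_idx, len(ev_times)))  # events per distinct time
    # subjects at risk just before each distinct event time
    n_risk = n - np.searchsorted(t_sorted, uniq, side="left")

    frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.cumsum(d / (n_risk * (n_risk - d)))
        greenwood = surv ** 2 * gw_terms  # 0·inf -> nan only where S = 0

    incidence = 1.0 - surv
    idx = np.searchsorted(uniq, horizon, side="right") - 1
    if idx < 0:  # no events by horizon
        inc_h, ci = 0.0, (0.0, _zero_event_upper(n))
    else:
        s = surv[idx]
        if s <= 0.0:
            inc_h, ci = 1.0, (float(1.0 - _zero_event_upper(n)), 1.0)
        else:
            inc_h = float(1.0 - s)
            ci = _horizon_ci(s, gw_terms[idx], ci_transform)
    return KMEstimate(
        event_times=uniq,
        survival=surv,
        cumulative_incidence=incidence,
        greenwood_variance=greenwood,
        n_at_risk=n_risk.astype(int),
        n_events=d.astype(int),
        horizon=float(horizon),
        horizon_readout=(inc_h, ci[0], ci[1]),
        n_subjects=n,
    )


def _zero_event_upper(n: int) -> float:
    # one-sided exact binomial bound: largest p with P(0 events | p) ≥ 0.025
    return float(1.0 - 0.025 ** (1.0 / n))


def _horizon_ci(s: float, gw_sum: float, transform: str) -> tuple[float, float]:
    se_s = s * np.sqrt(gw_sum)
    if transform == "cloglog":
        if s >= 1.0 - 1e-15:
            return (0.0, 0.0)
        # theta = log(-log S); CI back-transformed as S^exp(±z·se_theta)
        se_theta = np.sqrt(gw_sum) / abs(np.log(s))
        lo_s = s ** np.exp(_Z * se_theta)   # lower survival → upper incidence
        hi_s = s ** np.exp(-_Z * se_theta)
        return (float(1.0 - hi_s), float(1.0 - lo_s))
    if transform == "linear":
        inc = 1.0 - s
        return (float(max(0.0, inc - _Z * se_s)), float(min(1.0, inc + _Z * se_s)))
    raise ValueError(f"unknown ci_transform {transform!r}")


def km_fit(cohort: CohortTable, event_set: Iterable[str], horizon: float,
           ci_transform: str = "cloglog") -> KMEstimate:
    """Fit the product-limit curve of time to first event in ``event_set``.

    Subjects without a matching event are censored at their total follow-up.
    """
    pairs = [first_event_time(s, event_set) for s in cohort.subjects]
    times = np.array([p[0] for p in pairs])
    observed = np.array([p[1] for p in pairs])
    return km_fit_arrays(times, observed, horizon, ci_transform=ci_transform)


def km_compare_report(
    km: KMEstimate,
    reference_incidence: float,
    reference_ci: Optional[tuple[float, float]] = None,
) -> ComparisonRow:
    """One observed-vs-reference row for the final comparison report."""
    if not 0 <= reference_incidence <= 1:
        raise ValueError("reference_incidence must lie in [0, 1]")
    inc, lo, hi = km.horizon_readout
    return ComparisonRow(
        observed=inc,
        observed_ci=(lo, hi),
        reference=float(reference_incidence),
        reference_ci=reference_ci,
        difference=float(inc - reference_incidence),
    )
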