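"""Subject-level percentile bootstrap, rate ratio, and the comparison report.

The headline uncertainty statements come from resampling *subjects* with
replacement, stratified by arm, and re-running the entire estimation
pipeline inside every resample: the Poisson rate model and the T-score
model are refitted on the resampled crossover subjects, fresh virtual twins
(new history and T-score draws) are built for the resampled long-term
completers, and the observed incidence, twin incidence and their ratio are
recomputed.  95% CIs are the 2.5th/97.5th percentiles of the draws.

The treated-versus-counterfactual rate ratio is defined on the cumulative-
hazard scale, ``−log(1 − observed incidence) / −log(1 − twin incidence)``:
this is the Poisson-consistent reading of a "rate ratio" between cumulative
incidences (the raw incidence quotient is reported alongside).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np

from .cohort import (
    CohortArrays,
    CohortTable,
    HIP_EVENTS,
    MOF_EVENTS,
    event_count_arrays,
)
from .km import KMEstimate, km_fit_arrays
from .poisson import PoissonFitError, design_matrix, fit_poisson_counts
from .twin import (
    GuardResult,
    TwinEngineError,
    _fit_tscore_arrays,
    _twin_incidences_arrays,
    low_event_guard,
)

__all__ = [
    "BootstrapResult",
    "PipelineEstimates",
    "ComparisonReport",
    "bootstrap_statistic",
    "bootstrap_twin_pipeline",
    "rate_ratio",
    "build_report",
    "run_full_pipeline",
]

MAX_FAILED_FRACTION = 0.01


@dataclass
class BootstrapResult:
    """Point estimate with percentile CI and (optionally) the raw draws."""

    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    draws: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    def to_dict(self) -> dict:
        return {
            "point_estimate": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _percentile_result(point: float, draws: np.ndarray, seed: int,
                       retain_draws: bool) -> BootstrapResult:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return BootstrapResult(
        point_estimate=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=len(draws),
        seed=seed,
        draws=draws if retain_draws else None,
    )


# ---------------------------------------------------------------------------
# Generic subject-level bootstrap


def bootstrap_statistic(
    cohort: CohortTable,
    statistic: Callable[[CohortTable, np.random.Generator], float],
    n_boot: int,
    seed: int,
    stratify_by_arm: bool = True,
    retain_draws: bool = True,
) -> BootstrapResult:
    """Percentile bootstrap of an arbitrary cohort statistic.

    Subjects are resampled with replacement, within each arm when
    ``stratify_by_arm`` (so per-arm sample sizes are preserved exactly).
    ``statistic`` receives the resampled cohort and a dedicated RNG stream.
    Failing draws are recorded; more than 1% failures is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be ≥ 1")
    ss = np.random.SeedSequence(seed)
    point_rng, boot_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    point = float(statistic(cohort, point_rng))

    subjects = cohort.subjects
    if stratify_by_arm:
        strata = [
            [i for i, s in enumerate(subjects) if s.arm == arm]
            for arm in ("placebo_crossover", "denosumab_longterm")
        ]
        strata = [np.array(g) for g in strata if g]
    else:
        strata = [np.arange(len(subjects))]

    draws = np.full(n_boot, np.nan)
    n_failed = 0
    for b in range(n_boot):
        idx = np.concatenate([g[boot_rng.integers(0, len(g), size=len(g))] for g in strata])
        resampled = [
            dataclasses.replace(subjects[i], subject_id=f"{subjects[i].subject_id}#b{k}")
            for k, i in enumerate(idx)
        ]
        boot_cohort = CohortTable(resampled, provenance=f"bootstrap draw {b}")
        try:
            draws[b] = statistic(boot_cohort, boot_rng)
        except Exception:
            n_failed += 1
    if n_failed > MAX_FAILED_FRACTION * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap draws failed")
    ok = draws[np.isfinite(draws)]
    return _percentile_result(point, ok, seed, retain_draws)


# ---------------------------------------------------------------------------
# The full twin pipeline bootstrap (array-level, fast)


@dataclass
class PipelineEstimates:
    """Joint bootstrap of the observed KM incidence, the twin incidence and
    their hazard-scale rate ratio over the same resamples."""

    observed_km: KMEstimate
    observed: BootstrapResult
    twin: BootstrapResult
    ratio: BootstrapResult
    ratio_raw_quotient: float
    vertebral_split: float
    n_failed: int
    n_completers: int
    n_crossover: int


def _hazard_ratio(obs_inc: float, twin_inc: float) -> float:
    return float(np.log1p(-obs_inc) / np.log1p(-twin_inc))


def bootstrap_twin_pipeline(
    cohort: CohortTable,
    event_set: Iterable[str] = MOF_EVENTS,
    n_boot: int = 5000,
    seed: int = 0,
    horizon: float = 10.0,
    history_mode: str = "draw",
    composition: str = "hazard",
    tscore_predictor: str = "total_hip",
    retain_draws: bool = False,
) -> PipelineEstimates:
    """Run the whole observed-versus-twin estimation with a joint bootstrap.

    Every draw resamples crossover and long-term-completer subjects
    independently with replacement (arm-stratified), refits both calibration
    models on the resampled crossover data, rebuilds twins with fresh
    stochastic draws, and recomputes all three statistics.  Deterministic
    given ``seed``.
    """
    event_set = frozenset(event_set)
    arrays = CohortArrays.from_cohort(cohort)
    counts = event_count_arrays(cohort, event_set)

    x_idx = np.nonzero(arrays.is_crossover & (arrays.core_fu > 0))[0]
    c_idx = np.nonzero(~arrays.is_crossover & arrays.completer)[0]
    if len(x_idx) == 0:
        raise PoissonFitError("no crossover subjects with core follow-up")
    if len(c_idx) == 0:
        raise TwinEngineError("no long-term 10-year completers")

    xa = arrays.take(x_idx)
    ca = arrays.take(c_idx)
    x_counts = counts["core_count"][x_idx]
    x_vert = counts["core_vert"][x_idx]
    x_nonvert = counts["core_nonvert"][x_idx]
    x_tmask = np.isfinite(xa.thip_end_core)
    c_first = counts["first_time"][c_idx]
    c_obs = counts["observed"][c_idx] & (c_first <= horizon)

    tsc_col = xa.thip_base if tscore_predictor == "total_hip" else xa.fn_tscore
    Xfull = design_matrix(xa, tsc_col)

    ss = np.random.SeedSequence(seed)
    twin_rng, boot_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    def fit_and_twin(xsel: np.ndarray, csel: np.ndarray, rng: np.random.Generator):
        pfit = fit_poisson_counts(Xfull[xsel], x_counts[xsel], xa.core_fu[xsel])
        if not pfit.converged:
            raise PoissonFitError("non-converged resample fit")
        tm = xsel[x_tmask[xsel]]
        if len(tm) < 5:
            raise TwinEngineError("too few end-of-core T-scores in resample")
        tfit = _fit_tscore_arrays(xa.age[tm], xa.thip_base[tm], xa.bmi[tm],
                                  xa.thip_end_core[tm])
        vt, nvt = x_vert[xsel].sum(), x_nonvert[xsel].sum()
        split = float(vt / (vt + nvt)) if vt + nvt > 0 else 0.5
        out = _twin_incidences_arrays(
            ca.age[csel], ca.bmi[csel], ca.prior_vert[csel], ca.prior_nonvert[csel],
            ca.thip_base[csel], ca.smoker[csel], pfit, tfit, rng, split,
            history_mode, composition,
        )
        twin_inc = float(np.mean(out["incidence"]))
        obs_inc = float(np.mean(c_obs[csel]))
        return obs_inc, twin_inc, split

    # point estimates on the original data
    all_x = np.arange(len(x_idx))
    all_c = np.arange(len(c_idx))
    obs_point, twin_point, split_point = fit_and_twin(all_x, all_c, twin_rng)
    observed_km = km_fit_arrays(c_first, c_obs, horizon)

    obs_draws = np.full(n_boot, np.nan)
    twin_draws = np.full(n_boot, np.nan)
    ratio_draws = np.full(n_boot, np.nan)
    n_failed = 0
    for b in range(n_boot):
        xsel = boot_rng.integers(0, len(x_idx), size=len(x_idx))
        csel = boot_rng.integers(0, len(c_idx), size=len(c_idx))
        try:
            o, t, _ = fit_and_twin(xsel, csel, boot_rng)
        except (PoissonFitError, TwinEngineError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        obs_draws[b], twin_draws[b] = o, t
        if t > 0:
            ratio_draws[b] = _hazard_ratio(o, t)
    if n_failed > MAX_FAILED_FRACTION * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap draws failed")

    fin = np.isfinite
    if twin_point <= 0:
        raise TwinEngineError("twin incidence is zero; rate ratio refused")
    return PipelineEstimates(
        observed_km=observed_km,
        observed=_percentile_result(obs_point, obs_draws[fin(obs_draws)], seed, retain_draws),
        twin=_percentile_result(twin_point, twin_draws[fin(twin_draws)], seed, retain_draws),
        ratio=_percentile_result(
            _hazard_ratio(obs_point, twin_point), ratio_draws[fin(ratio_draws)], seed, retain_draws
        ),
        ratio_raw_quotient=float(obs_point / twin_point),
        vertebral_split=split_point,
        n_failed=n_failed,
        n_completers=len(c_idx),
        n_crossover=len(x_idx),
    )


def rate_ratio(observed_km: KMEstimate, twin_incidence: float,
               boot: Optional[BootstrapResult] = None) -> BootstrapResult:
    """Hazard-scale rate ratio of observed versus twin 10-year incidence.

    Point estimate ``−log(1 − observed) / −log(1 − twin)``; the CI comes
    from paired bootstrap ratio draws when supplied (``boot`` holding the
    per-draw ratios), else degenerate at the point.
    """
    if twin_incidence <= 0:
        raise TwinEngineError("twin incidence must be positive for a rate ratio")
    obs = observed_km.horizon_readout[0]
    point = _hazard_ratio(obs, twin_incidence)
    if boot is None:
        return BootstrapResult(point, point, point, 0, 0)
    return BootstrapResult(point, boot.ci_low, boot.ci_high, boot.n_boot,
                           boot.seed, draws=boot.draws)


# ---------------------------------------------------------------------------
# Comparison report


@dataclass
class ComparisonReport:
    """Final observed / external-prediction / twin comparison (per endpoint).

    Every row is a plain serializable dict; refused analyses appear as a
    ``{"refused": message}`` marker, never as zeros.
    """

    rows: dict
    rate_ratio: dict
    metadata: dict

    def to_json(self) -> str:
        return json.dumps(
            {"rows": self.rows, "rate_ratio": self.rate_ratio, "metadata": self.metadata},
            sort_keys=True, indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        return cls(rows=d["rows"], rate_ratio=d["rate_ratio"], metadata=d["metadata"])

    def render_table(self) -> str:
        lines = [f"{'endpoint':10s} {'source':10s} {'estimate':>10s} {'95% CI':>20s}"]
        for endpoint, sources in sorted(self.rows.items()):
            for source, row in sorted(sources.items()):
                if "refused" in row:
                    lines.append(f"{endpoint:10s} {source:10s} {'refused':>10s}  ({row['refused'][:40]}…)")
                    continue
                ci = row.get("ci")
                ci_s = f"[{ci[0]:.4f}, {ci[1]:.4f}]" if ci else ""
                lines.append(f"{endpoint:10s} {source:10s} {row['estimate']:10.4f} {ci_s:>20s}")
        rr = self.rate_ratio
        if "refused" in rr:
            lines.append(f"rate ratio: refused ({rr['refused']})")
        else:
            lines.append(
                f"MOF rate ratio (observed vs twin): {rr['point_estimate']:.3f} "
                f"[{rr['ci_low']:.3f}, {rr['ci_high']:.3f}]"
            )
        return "\n".join(lines)

    def plot(self, path) -> None:
        """Grouped-bar comparison figure (one group per endpoint)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        sources = ["observed", "frax", "twin"]
        labels = {"observed": "Observed (KM)", "frax": "External 10-y probability",
                  "twin": "Virtual twin"}
        endpoints = sorted(self.rows)
        fig, axes = plt.subplots(1, len(endpoints), figsize=(5 * len(endpoints), 4))
        if len(endpoints) == 1:
            axes = [axes]
        for ax, ep in zip(axes, endpoints):
            xs, hs, errs, ticklabels = [], [], [], []
            for k, src in enumerate(sources):
                row = self.rows[ep].get(src)
                if row is None or "refused" in row:
                    continue
                xs.append(k)
                hs.append(100 * row["estimate"])
                ci = row.get("ci")
                errs.append(
                    [[100 * (row["estimate"] - ci[0])], [100 * (ci[1] - row["estimate"])]]
                    if ci else [[0], [0]]
                )
                ticklabels.append(labels[src])
            for x, h, e in zip(xs, hs, errs):
                ax.bar([x], [h], yerr=np.array(e), capsize=4)
            ax.set_xticks(xs)
            ax.set_xticklabels(ticklabels, rotation=15)
            ax.set_ylabel("10-year incidence (%)")
            ax.set_title(ep.upper())
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_report(
    km_mof: Optional[KMEstimate],
    km_hip: Optional[KMEstimate],
    frax_summary: Optional[dict],
    twin_result: Optional[PipelineEstimates],
    rr: Optional[BootstrapResult],
    guards: dict[str, GuardResult],
    metadata: Optional[dict] = None,
) -> ComparisonReport:
    """Assemble the serializable comparison report.

    ``frax_summary`` maps endpoint → ``(mean, (lo, hi))``; guard refusals
    propagate into the corresponding rows as refusal markers.
    """
    if km_mof is None and km_hip is None:
        raise ValueError("at least the observed KM rows must be present")

    def km_row(km: KMEstimate) -> dict:
        inc, lo, hi = km.horizon_readout
        return {"estimate": inc, "ci": [lo, hi], "n": km.n_subjects}

    rows: dict = {}
    for endpoint, km in (("mof", km_mof), ("hip", km_hip)):
        if km is None:
            continue
        rows[endpoint] = {"observed": km_row(km)}
        if frax_summary and endpoint in frax_summary:
            mean, ci = frax_summary[endpoint]
            rows[endpoint]["frax"] = {"estimate": mean, "ci": list(ci)}
        guard = guards.get(endpoint)
        if guard is not None and not guard.passed:
            rows[endpoint]["twin"] = {"refused": guard.message}
        elif endpoint == "mof" and twin_result is not None:
            tw = twin_result.twin
            rows[endpoint]["twin"] = {
                "estimate": tw.point_estimate,
                "ci": [tw.ci_low, tw.ci_high],
                "n_boot": tw.n_boot,
            }
            if guard is not None and guard.overridden:
                rows[endpoint]["twin"]["warning"] = guard.message

    rr_dict: dict
    if rr is None:
        guard = guards.get("mof")
        rr_dict = {"refused": guard.message if guard and not guard.passed
                   else "rate ratio unavailable"}
    else:
        rr_dict = rr.to_dict()
        if twin_result is not None:
            rr_dict["raw_incidence_quotient"] = twin_result.ratio_raw_quotient

    meta = dict(metadata or {})
    meta.setdefault("guards", {k: dataclasses.asdict(g) for k, g in guards.items()})
    return ComparisonReport(rows=rows, rate_ratio=rr_dict, metadata=meta)


def run_full_pipeline(
    cohort: CohortTable,
    n_boot: int = 5000,
    seed: int = 0,
    horizon: float = 10.0,
    min_events: int = 20,
    override_hip_guard: bool = False,
    history_mode: str = "draw",
) -> ComparisonReport:
    """Observed KM + external probabilities + virtual twin, end to end.

    The analysis set for the observed and twin estimates is the long-term
    arm's 10-year completers; the calibration set is the crossover arm's
    core-period data.  The hip twin analysis is guarded off when the
    placebo arm has too few core hip events (as is typical), while the
    composite-MOF analysis proceeds.
    """
    from .frax import frax_summary as _frax_summary

    arrays = CohortArrays.from_cohort(cohort)
    guards = {
        "mof": low_event_guard(cohort, MOF_EVENTS, min_events, arrays=arrays),
        "hip": low_event_guard(cohort, HIP_EVENTS, min_events,
                               override=override_hip_guard, arrays=arrays),
    }

    comp_idx = np.nonzero(~arrays.is_crossover & arrays.completer)[0]
    completers = cohort.subset(
        [cohort.subjects[i] for i in comp_idx], note="long-term 10-year completers"
    )
    from .km import km_fit

    km_mof = km_fit(completers, MOF_EVENTS, horizon)
    km_hip = km_fit(completers, HIP_EVENTS, horizon)

    frax = {}
    for endpoint in ("mof", "hip"):
        try:
            frax[endpoint] = _frax_summary(completers, endpoint)
        except ValueError:
            pass

    twin_result = None
    rr = None
    if guards["mof"].passed:
        twin_result = bootstrap_twin_pipeline(
            cohort, MOF_EVENTS, n_boot=n_boot, seed=seed, horizon=horizon,
            history_mode=history_mode,
        )
        rr = rate_ratio(twin_result.observed_km, twin_result.twin.point_estimate,
                        twin_result.ratio)

    metadata = {
        "seed": seed,
        "n_boot": n_boot,
        "horizon": horizon,
        "cohort_hash": cohort.content_hash(),
        "n_completers": len(completers),
        "provenance": cohort.provenance,
    }
    if twin_result is not None:
        metadata["vertebral_split"] = twin_result.vertebral_split
        metadata["n_failed_draws"] = twin_result.n_failed
    return build_report(km_mof, km_hip, frax, twin_result, rr, guards, metadata)
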