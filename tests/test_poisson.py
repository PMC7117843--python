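"""Poisson offset model: closed forms, brute-force likelihood, recovery."""

import numpy as np
import pytest

from placebotwin import (
    MOF_EVENTS,
    PoissonFit,
    PoissonFitError,
    PredictorVector,
    SimulationConfig,
    expected_count,
    fit_placebo_poisson,
    generate_cohort,
)
from placebotwin.poisson import PREDICTOR_NAMES, fit_poisson_counts
from placebotwin.cohort import CohortArrays, event_count_arrays


def test_intercept_only_closed_form():
    """Intercept-only MLE is log(total events / total person-years)."""
    counts = np.array([0, 1, 2, 0, 3.0])
    expo = np.array([1.0, 2.0, 3.0, 1.5, 2.5])
    fit = fit_poisson_counts(np.ones((5, 1)), counts, expo, names=("intercept",))
    assert fit.coefficients[0] == pytest.approx(np.log(counts.sum() / expo.sum()), abs=1e-10)


def test_toy_mle_matches_likelihood_grid():
    """6-subject toy with one binary predictor: MLE vs brute-force grid."""
    x = np.array([0, 0, 0, 1, 1, 1.0])
    X = np.column_stack([np.ones(6), x])
    counts = np.array([0, 1, 0, 2, 1, 3.0])
    expo = np.array([2.0, 3.0, 2.5, 3.0, 2.0, 3.0])

    def loglik(b0, b1):
        mu = np.exp(b0 + b1 * x) * expo
        return np.sum(counts * np.log(mu) - mu, axis=-1)

    b0g = np.linspace(-3, 1, 801)
    b1g = np.linspace(-2, 3, 1001)
    ll = loglik(b0g[:, None, None], b1g[None, :, None])
    i, j = np.unravel_index(np.argmax(ll), ll.shape)

    fit = fit_poisson_counts(X, counts, expo, names=("intercept", "x"))
    assert fit.converged
    assert fit.coefficients[0] == pytest.approx(b0g[i], abs=6e-3)
    assert fit.coefficients[1] == pytest.approx(b1g[j], abs=6e-3)
    # beyond grid resolution: the analytic MLE of this saturated-in-x
    # model is log(events/time) per group
    g0 = np.log(counts[x == 0].sum() / expo[x == 0].sum())
    g1 = np.log(counts[x == 1].sum() / expo[x == 1].sum())
    assert fit.coefficients[0] == pytest.approx(g0, abs=1e-8)
    assert (fit.coefficients[0] + fit.coefficients[1]) == pytest.approx(g1, abs=1e-8)


def test_score_equations_zero_at_mle(default_cohort):
    cohort, _ = default_cohort
    fit = fit_placebo_poisson(cohort, MOF_EVENTS)
    arr = CohortArrays.from_cohort(cohort)
    counts = event_count_arrays(cohort, MOF_EVENTS)["core_count"]
    m = arr.is_crossover & (arr.core_fu > 0)
    sub = arr.take(np.nonzero(m)[0])
    X = np.column_stack([np.ones(len(sub)), sub.age, sub.bmi, sub.prior_vert,
                         sub.prior_nonvert, sub.thip_base, sub.smoker])
    mu = np.exp(X @ fit.coefficients + np.log(sub.core_fu))
    score = X.T @ (counts[m] - mu)
    assert np.max(np.abs(score)) < 1e-6


def test_age_shift_invariance(small_cohort):
    """Shifting age changes only intercept; fitted means are unchanged."""
    cohort, _ = small_cohort
    fit = fit_placebo_poisson(cohort, MOF_EVENTS)
    shifted = CohortArrays.from_cohort(cohort)
    counts = event_count_arrays(cohort, MOF_EVENTS)["core_count"]
    m = shifted.is_crossover & (shifted.core_fu > 0)
    sub = shifted.take(np.nonzero(m)[0])
    X = np.column_stack([np.ones(len(sub)), sub.age, sub.bmi, sub.prior_vert,
                         sub.prior_nonvert, sub.thip_base, sub.smoker])
    X2 = X.copy()
    X2[:, 1] += 5.0
    fit2 = fit_poisson_counts(X2, counts[m], sub.core_fu)
    mu1 = np.exp(X @ fit.coefficients)
    mu2 = np.exp(X2 @ fit2.coefficients)
    assert np.allclose(mu1, mu2, atol=1e-8)
    assert fit2.coefficients[1] == pytest.approx(fit.coefficients[1], abs=1e-6)


def test_matches_statsmodels_glm(default_cohort):
    """Independent cross-check against statsmodels' Poisson GLM.

    Uses the full-size cohort so every predictor level carries events (a
    tiny arm can put the smoker coefficient's MLE at -infinity, where
    solver stopping points are not comparable).
    """
    import statsmodels.api as sm

    cohort, _ = default_cohort
    fit = fit_placebo_poisson(cohort, MOF_EVENTS)
    arr = CohortArrays.from_cohort(cohort)
    counts = event_count_arrays(cohort, MOF_EVENTS)["core_count"]
    m = arr.is_crossover & (arr.core_fu > 0)
    sub = arr.take(np.nonzero(m)[0])
    X = np.column_stack([np.ones(len(sub)), sub.age, sub.bmi, sub.prior_vert,
                         sub.prior_nonvert, sub.thip_base, sub.smoker])
    ref = sm.GLM(counts[m], X, family=sm.families.Poisson(),
                 offset=np.log(sub.core_fu)).fit()
    assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
    assert np.allclose(fit.standard_errors, ref.bse, rtol=1e-4)


def test_parameter_recovery_single_large_arm():
    """Known coefficients recovered within 3 SE on a 5000-subject arm."""
    cfg = SimulationConfig(n_per_arm=5000)
    cohort, _ = generate_cohort(cfg, seed=2024)
    fit = fit_placebo_poisson(cohort, MOF_EVENTS)
    beta_true = np.asarray(cfg.rate_coefficients)
    z = (fit.coefficients - beta_true) / fit.standard_errors
    assert np.all(np.abs(z) < 3)


def test_standard_errors_match_finite_difference_hessian():
    rng = np.random.default_rng(5)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n).astype(float)])
    beta = np.array([-1.5, 0.3, 0.5])
    expo = rng.uniform(0.5, 3.0, n)
    counts = rng.poisson(np.exp(X @ beta) * expo)
    fit = fit_poisson_counts(X, counts, expo, names=("intercept", "z", "b"))

    def loglik(b):
        mu = np.exp(X @ b) * expo
        return np.sum(counts * np.log(mu) - mu)

    h = 1e-5
    p = len(beta)
    H = np.zeros((p, p))
    b0 = fit.coefficients
    for i in range(p):
        for j in range(p):
            bpp, bpm, bmp, bmm = (b0.copy() for _ in range(4))
            bpp[i] += h; bpp[j] += h
            bpm[i] += h; bpm[j] -= h
            bmp[i] -= h; bmp[j] += h
            bmm[i] -= h; bmm[j] -= h
            H[i, j] = (loglik(bpp) - loglik(bpm) - loglik(bmp) + loglik(bmm)) / (4 * h * h)
    se_fd = np.sqrt(np.diag(np.linalg.inv(-H)))
    assert np.allclose(fit.standard_errors, se_fd, rtol=0.01)


def test_rank_deficient_design_names_columns():
    X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
    with pytest.raises(PoissonFitError, match="collinear"):
        fit_poisson_counts(X, np.zeros(10), np.ones(10), names=("intercept", "a", "b"))


def test_expected_count_closed_forms():
    fit = PoissonFit(
        coefficients=np.zeros(7), covariance=np.eye(7),
        predictor_names=PREDICTOR_NAMES, n_subjects=1, total_events=0,
        total_person_years=1, converged=True,
    )
    x = PredictorVector(age_years=0, bmi=0, prior_vertebral_fx=0,
                        prior_nonvertebral_fx=0, total_hip_tscore=0, ever_smoker=0)
    assert expected_count(fit, x, 1.0) == pytest.approx(1.0)
    fit.coefficients[0] = np.log(0.02)
    assert expected_count(fit, x, 3.0) == pytest.approx(0.06)
    # arbitrary fit/x: independent dot-product recomputation
    rng = np.random.default_rng(1)
    fit.coefficients = rng.normal(scale=0.1, size=7)
    x2 = PredictorVector(70.0, 25.0, 1, 0, -2.2, 1)
    row = np.array([1, 70.0, 25.0, 1, 0, -2.2, 1])
    assert expected_count(fit, x2, 4.5) == pytest.approx(
        np.exp(row @ fit.coefficients) * 4.5, abs=1e-12
    )


def test_predictor_vector_validates_indicators():
    with pytest.raises(ValueError):
        PredictorVector(70, 25, 2, 0, -2, 0)


def test_quasi_poisson_scale_reported(default_cohort):
    cohort, _ = default_cohort
    fit = fit_placebo_poisson(cohort, MOF_EVENTS)
    assert np.isfinite(fit.pearson_scale) and fit.pearson_scale > 0


def test_fit_json_round_trip(small_cohort):
    cohort, _ = small_cohort
    fit = fit_placebo_poisson(cohort, MOF_EVENTS)
    back = PoissonFit.from_json(fit.to_json())
    assert np.allclose(back.coefficients, fit.coefficients)
    assert np.allclose(back.covariance, fit.covariance)
    assert back.predictor_names == fit.predictor_names
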