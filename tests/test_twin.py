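"""Twin engine: T-score model oracles, twin composition, low-event guard."""

import numpy as np
import pytest

from placebotwin import (
    CohortTable,
    HIP_EVENTS,
    MOF_EVENTS,
    PoissonFit,
    SimulationConfig,
    TScoreFit,
    TwinEngineError,
    fit_tscore_model,
    generate_cohort,
    low_event_guard,
    make_virtual_twin,
    twin_cohort_incidence,
    vertebral_event_split,
)
from placebotwin.poisson import PREDICTOR_NAMES
from placebotwin.twin import _fit_tscore_arrays

from conftest import make_subject


def _pfit(coefficients):
    return PoissonFit(
        coefficients=np.asarray(coefficients, dtype=float),
        covariance=np.eye(7) * 1e-4,
        predictor_names=PREDICTOR_NAMES,
        n_subjects=100, total_events=10, total_person_years=300, converged=True,
    )


def _tfit(coefficients=(-0.1, 0.0, 1.0, 0.0), residual_sd=0.25):
    return TScoreFit(coefficients=np.asarray(coefficients, dtype=float),
                     residual_sd=residual_sd, n=100)


# ---------------------------------------------------------------------------
# T-score model


def test_tscore_normal_equations_oracle():
    rng = np.random.default_rng(3)
    n = 6
    age = rng.uniform(60, 80, n)
    thip = rng.uniform(-3, -1, n)
    bmi = rng.uniform(20, 30, n)
    y = -0.2 + 0.01 * age + 0.9 * thip - 0.005 * bmi + rng.normal(0, 0.3, n)
    fit = _fit_tscore_arrays(age, thip, bmi, y)
    X = np.column_stack([np.ones(n), age, thip, bmi])
    beta_ref = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.coefficients, beta_ref, atol=1e-10)
    resid = y - X @ beta_ref
    assert fit.residual_sd == pytest.approx(np.sqrt(resid @ resid / (n - 4)))


def test_tscore_perfect_fit_rejected_as_degenerate():
    rng = np.random.default_rng(4)
    n = 20
    age = rng.uniform(60, 80, n)
    thip = rng.uniform(-3, -1, n)
    bmi = rng.uniform(20, 30, n)
    with pytest.raises(TwinEngineError, match="degenerate"):
        _fit_tscore_arrays(age, thip, bmi, thip.copy())  # end == baseline exactly


def test_tscore_requires_five_crossover_subjects():
    subjects = [make_subject(f"S{i}", arm="placebo_crossover") for i in range(3)]
    subjects.append(make_subject("L1"))
    with pytest.raises(TwinEngineError, match="≥ 5"):
        fit_tscore_model(CohortTable(subjects))


def test_tscore_drift_recovery():
    """Fitted on the crossover arm, the model recovers the placebo drift."""
    import statsmodels.api as sm
    from placebotwin.cohort import CohortArrays

    cfg = SimulationConfig(n_per_arm=4000)
    cohort, _ = generate_cohort(cfg, seed=31)
    fit = fit_tscore_model(cohort)
    # true model: T_end = drift + 1.0 * T_base + noise
    arr = CohortArrays.from_cohort(cohort)
    m = arr.is_crossover & np.isfinite(arr.thip_end_core)
    X = sm.add_constant(np.column_stack([arr.age[m], arr.thip_base[m], arr.bmi[m]]))
    ref = sm.OLS(arr.thip_end_core[m], X).fit()
    for k, true_val in [(0, cfg.tscore_drift_placebo), (1, 0.0), (2, 1.0), (3, 0.0)]:
        assert abs(fit.coefficients[k] - true_val) < 3 * ref.bse[k]
    assert fit.residual_sd == pytest.approx(cfg.tscore_noise_sd, rel=0.1)


# ---------------------------------------------------------------------------
# make_virtual_twin


def test_twin_requires_longterm_completer():
    pfit, tfit = _pfit([-20, 0, 0, 0, 0, 0, 0]), _tfit()
    rng = np.random.default_rng(0)
    with pytest.raises(TwinEngineError, match="completer"):
        make_virtual_twin(make_subject(arm="placebo_crossover"), pfit, tfit, rng)
    with pytest.raises(TwinEngineError, match="completer"):
        make_virtual_twin(make_subject(ext_fu=5.0), pfit, tfit, rng)


def test_twin_degenerate_rate():
    """Near-zero rate: incidence ~0 and fracture history never updated."""
    pfit, tfit = _pfit([-20, 0, 0, 0, 0, 0, 0]), _tfit()
    rng = np.random.default_rng(0)
    twin = make_virtual_twin(make_subject(), pfit, tfit, rng)
    assert twin.ten_year_incidence < 1e-6
    assert twin.core_predicted_fx_vertebral == 0
    assert twin.core_predicted_fx_nonvertebral == 0


def test_twin_age_advances_three_years():
    """Only the age slope nonzero: ext/core expected counts expose age + 3."""
    b_age = 0.05
    pfit = _pfit([-5.0, b_age, 0, 0, 0, 0, 0])
    tfit = _tfit()
    rng = np.random.default_rng(1)
    twin = make_virtual_twin(make_subject(age=70.8), pfit, tfit, rng)
    assert twin.core_expected_count == pytest.approx(np.exp(-5 + b_age * 70.8) * 3)
    assert twin.ext_expected_count / twin.core_expected_count == pytest.approx(
        (7 / 3) * np.exp(3 * b_age)  # extension-baseline age is 73.8
    )


def test_twin_tscore_reproducible_from_recorded_draw():
    """The simulated T-score is the fit mean plus the recorded z times SD,
    and the whole record is reproducible from the seed."""
    pfit, tfit = _pfit([-4.0, 0, 0, 0.4, 0.3, -0.2, 0]), _tfit()
    s = make_subject()
    twin = make_virtual_twin(s, pfit, tfit, np.random.default_rng(99))
    mean = tfit.predict_mean(np.array([s.age_years]),
                             np.array([s.total_hip_tscore_baseline]),
                             np.array([s.bmi]))[0]
    assert twin.ext_tscore_simulated == pytest.approx(
        mean + twin.tscore_z * tfit.residual_sd, abs=1e-12
    )
    twin2 = make_virtual_twin(s, pfit, tfit, np.random.default_rng(99))
    assert twin2 == twin


def test_twin_composition_bound():
    """ten_year_incidence ≤ core + extension expected counts (1-e^-x ≤ x)."""
    rng = np.random.default_rng(10)
    tfit = _tfit()
    for _ in range(50):
        pfit = _pfit(np.concatenate([[rng.uniform(-7, -3)], rng.normal(0, 0.1, 6)]))
        twin = make_virtual_twin(make_subject(), pfit, tfit, rng)
        assert twin.ten_year_incidence <= twin.core_expected_count + twin.ext_expected_count
        assert twin.ten_year_incidence == pytest.approx(
            1 - np.exp(-(twin.core_expected_count + twin.ext_expected_count))
        )


def test_single_subject_cohort_incidence_equals_twin(default_cohort):
    from placebotwin import fit_placebo_poisson

    cohort, _ = default_cohort
    pfit = fit_placebo_poisson(cohort, MOF_EVENTS)
    tfit = fit_tscore_model(cohort)
    completer = next(
        s for s in cohort.subjects
        if s.arm == "denosumab_longterm" and s.is_ten_year_completer
    )
    one = cohort.subset([completer])
    split = vertebral_event_split(cohort, MOF_EVENTS)
    inc = twin_cohort_incidence(one, pfit, tfit, np.random.default_rng(5),
                                split_vertebral=split)
    twin = make_virtual_twin(completer, pfit, tfit, np.random.default_rng(5),
                             split_vertebral=split)
    assert inc == pytest.approx(twin.ten_year_incidence)


def test_homogeneous_cohort_closed_form_limit():
    """Constant true rate 0.024/yr, well-specified fits, intercept-only
    structure: the twin estimate approaches 1 - e^-0.24."""
    lam = 0.024
    pfit = _pfit([np.log(lam), 0, 0, 0, 0, 0, 0])
    tfit = _tfit((0.0, 0.0, 1.0, 0.0), residual_sd=0.2)
    subjects = [make_subject(f"S{i}") for i in range(4000)]
    cohort = CohortTable(subjects[:1] + subjects[1:])
    inc = twin_cohort_incidence(cohort, pfit, tfit, np.random.default_rng(8),
                                split_vertebral=0.3)
    assert abs(inc - (1 - np.exp(-0.24))) < 0.01


def test_twin_monotone_in_data_generating_rate():
    """Raising every subject's true rate never lowers the twin estimate,
    in expectation (paired seeds)."""
    from placebotwin import bootstrap_twin_pipeline
    import dataclasses

    diffs = []
    for seed in range(6):
        base = SimulationConfig(n_per_arm=800)
        coeffs = list(base.rate_coefficients)
        coeffs[0] += 0.5
        high = dataclasses.replace(base, rate_coefficients=tuple(coeffs))
        c0, _ = generate_cohort(base, seed=500 + seed)
        c1, _ = generate_cohort(high, seed=500 + seed)
        r0 = bootstrap_twin_pipeline(c0, n_boot=1, seed=seed)
        r1 = bootstrap_twin_pipeline(c1, n_boot=1, seed=seed)
        diffs.append(r1.twin.point_estimate - r0.twin.point_estimate)
    assert np.mean(diffs) > 0


# ---------------------------------------------------------------------------
# low-event guard


def test_guard_refuses_sparse_hip_events(default_cohort):
    cohort, _ = default_cohort
    guard = low_event_guard(cohort, HIP_EVENTS, min_events=20)
    assert not guard.passed
    assert guard.n_events < 20
    assert "refused" in guard.message


def test_guard_passes_mof(default_cohort):
    cohort, _ = default_cohort
    guard = low_event_guard(cohort, MOF_EVENTS, min_events=20)
    assert guard.passed and guard.n_events >= 20 and not guard.overridden


def test_guard_override_passes_with_warning(default_cohort):
    cohort, _ = default_cohort
    guard = low_event_guard(cohort, HIP_EVENTS, min_events=20, override=True)
    assert guard.passed and guard.overridden
    assert "WARNING" in guard.message


def test_expectation_history_mode_close_to_draw_mode(default_cohort):
    from placebotwin import fit_placebo_poisson

    cohort, _ = default_cohort
    pfit = fit_placebo_poisson(cohort, MOF_EVENTS)
    tfit = fit_tscore_model(cohort)
    kw = dict(split_vertebral=0.3)
    inc_draw = np.mean([
        twin_cohort_incidence(cohort, pfit, tfit, np.random.default_rng(k),
                              history_mode="draw", **kw)
        for k in range(10)
    ])
    inc_exp = twin_cohort_incidence(cohort, pfit, tfit, np.random.default_rng(0),
                                    history_mode="expectation", **kw)
    assert abs(inc_draw - inc_exp) < 0.01
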