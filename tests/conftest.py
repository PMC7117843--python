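import pytest

from placebotwin import CohortTable, FractureEvent, SimulationConfig, SubjectRecord, generate_cohort


def make_subject(
    subject_id="S1",
    arm="denosumab_longterm",
    age=70.0,
    bmi=26.0,
    fn=-2.1,
    thip=-2.0,
    thip_end=-2.1,
    prior_vert=False,
    prior_nonvert=True,
    smoker=False,
    core_fu=3.0,
    ext_fu=7.0,
    events=(),
    frax_mof=None,
    frax_hip=None,
):
    return SubjectRecord(
        subject_id=subject_id,
        arm=arm,
        age_years=age,
        bmi=bmi,
        femoral_neck_tscore=fn,
        total_hip_tscore_baseline=thip,
        total_hip_tscore_end_core=thip_end,
        prior_vertebral_fx=prior_vert,
        prior_nonvertebral_fx=prior_nonvert,
        ever_smoker=smoker,
        core_followup_years=core_fu,
        extension_followup_years=ext_fu,
        events=[FractureEvent(t, y) for t, y in events],
        frax_mof_prob=frax_mof,
        frax_hip_prob=frax_hip,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (n = 1278 per arm) shared across tests."""
    return generate_cohort(SimulationConfig(n_per_arm=1278), seed=20260921)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimulationConfig(n_per_arm=300), seed=77)


@pytest.fixture
def toy_km_cohort():
    """4 subjects: events at t=1 and t=3, censorings at t=2 and t=4."""
    subjects = [
        make_subject("A", core_fu=3.0, ext_fu=7.0, events=[("hip", 1.0)]),
        make_subject("B", core_fu=2.0, ext_fu=0.0),
        make_subject("C", core_fu=3.0, ext_fu=7.0, events=[("forearm", 3.0)]),
        make_subject("D", core_fu=3.0, ext_fu=1.0),
    ]
    return CohortTable(subjects, provenance="toy")
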