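"""Subject-level trial data model and CSV round-tripping.

The analysis cohort is a two-arm osteoporosis trial with a 3-year
placebo-controlled core study followed by a 7-year open-label extension in
which every participant receives active treatment.  All times are fractional
years since core-study baseline: the core period is the half-open interval
[0, 3), the extension [3, 10).

Fracture events are restricted to the four components of a major
osteoporotic fracture (MOF): clinical vertebral, hip, forearm, humerus.
Recurrent events are stored — the count model downstream uses them — while
time-to-first-event analyses pick the first matching event per subject.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "MOF_EVENTS",
    "HIP_EVENTS",
    "ARMS",
    "FractureEvent",
    "SubjectRecord",
    "CohortTable",
    "CohortValidationError",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "first_event_time",
]

#: The four MOF component fracture types, in canonical order.
EVENT_TYPES = ("clinical_vertebral", "hip", "forearm", "humerus")
MOF_EVENTS = frozenset(EVENT_TYPES)
HIP_EVENTS = frozenset({"hip"})
NONVERTEBRAL_EVENTS = frozenset({"hip", "forearm", "humerus"})

ARMS = ("placebo_crossover", "denosumab_longterm")

CORE_YEARS = 3.0
EXTENSION_YEARS = 7.0
TOTAL_YEARS = CORE_YEARS + EXTENSION_YEARS

_TIME_TOL = 1e-9

SUBJECT_COLUMNS = [
    "subject_id",
    "arm",
    "age_years",
    "bmi",
    "femoral_neck_tscore",
    "total_hip_tscore_baseline",
    "total_hip_tscore_end_core",
    "prior_vertebral_fx",
    "prior_nonvertebral_fx",
    "ever_smoker",
    "core_followup_years",
    "extension_followup_years",
    "frax_mof_prob",
    "frax_hip_prob",
]
EVENT_COLUMNS = ["subject_id", "event_type", "time_years"]

_BOOL_COLUMNS = ("prior_vertebral_fx", "prior_nonvertebral_fx", "ever_smoker")
_OPTIONAL_COLUMNS = ("total_hip_tscore_end_core", "frax_mof_prob", "frax_hip_prob")


class CohortValidationError(ValueError):
    """A cohort violates a structural invariant (duplicate ids, bad times...)."""


class CohortSchemaError(ValueError):
    """A CSV file does not conform to the documented schema."""


@dataclass(frozen=True)
class FractureEvent:
    """A single clinical fracture: one of the four MOF components.

    ``time_years`` is measured from core-study baseline and must lie within
    the subject's observed follow-up.
    """

    event_type: str
    time_years: float

    def __post_init__(self):
        if self.event_type not in MOF_EVENTS:
            raise CohortValidationError(
                f"unknown event_type {self.event_type!r}; expected one of {EVENT_TYPES}"
            )
        if not np.isfinite(self.time_years) or self.time_years < 0:
            raise CohortValidationError(
                f"event time must be a finite non-negative number of years, got {self.time_years!r}"
            )


@dataclass
class SubjectRecord:
    """One trial participant: baseline covariates, arm, follow-up and events.

    ``arm`` is ``placebo_crossover`` (placebo in the core study, active drug
    in the extension) or ``denosumab_longterm`` (active drug throughout).
    ``total_hip_tscore_end_core`` and the FRAX probability fields may be
    ``None`` (missing); missing values are serialized as empty CSV cells.
    """

    subject_id: str
    arm: str
    age_years: float
    bmi: float
    femoral_neck_tscore: float
    total_hip_tscore_baseline: float
    total_hip_tscore_end_core: Optional[float]
    prior_vertebral_fx: bool
    prior_nonvertebral_fx: bool
    ever_smoker: bool
    core_followup_years: float
    extension_followup_years: float
    events: list[FractureEvent] = field(default_factory=list)
    frax_mof_prob: Optional[float] = None
    frax_hip_prob: Optional[float] = None

    @property
    def total_followup_years(self) -> float:
        return self.core_followup_years + self.extension_followup_years

    @property
    def is_core_completer(self) -> bool:
        return abs(self.core_followup_years - CORE_YEARS) <= _TIME_TOL

    @property
    def is_ten_year_completer(self) -> bool:
        return (
            self.is_core_completer
            and abs(self.extension_followup_years - EXTENSION_YEARS) <= _TIME_TOL
        )

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown arm {self.arm!r}; expected one of {ARMS}"
            )
        if not (self.age_years > 0 and self.bmi > 0):
            raise CohortValidationError(
                f"subject {self.subject_id}: age_years and bmi must be positive"
            )
        if not (0 < self.core_followup_years <= CORE_YEARS + _TIME_TOL):
            raise CohortValidationError(
                f"subject {self.subject_id}: core_followup_years must lie in (0, {CORE_YEARS}]"
            )
        if not (0 <= self.extension_followup_years <= EXTENSION_YEARS + _TIME_TOL):
            raise CohortValidationError(
                f"subject {self.subject_id}: extension_followup_years must lie in [0, {EXTENSION_YEARS}]"
            )
        if self.extension_followup_years > 0 and not self.is_core_completer:
            raise CohortValidationError(
                f"subject {self.subject_id}: extension follow-up requires completing the core study"
            )
        for p in (self.frax_mof_prob, self.frax_hip_prob):
            if p is not None and not (0 <= p <= 1):
                raise CohortValidationError(
                    f"subject {self.subject_id}: FRAX probabilities must lie in [0, 1]"
                )
        total = self.total_followup_years
        times = [ev.time_years for ev in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise CohortValidationError(
                f"subject {self.subject_id}: events must be sorted by time"
            )
        for ev in self.events:
            if ev.time_years > total + _TIME_TOL:
                raise CohortValidationError(
                    f"subject {self.subject_id}: event at {ev.time_years} years exceeds "
                    f"follow-up of {total} years"
                )


@dataclass
class CohortTable:
    """A validated collection of subjects plus free-text provenance."""

    subjects: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.subjects:
            raise CohortValidationError("cohort must contain at least one subject")
        seen: set[str] = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise CohortValidationError(f"duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)
            s.validate()

    def __len__(self) -> int:
        return len(self.subjects)

    def arm_subjects(self, arm: str) -> list[SubjectRecord]:
        if arm not in ARMS:
            raise CohortValidationError(f"unknown arm {arm!r}")
        return [s for s in self.subjects if s.arm == arm]

    def subset(self, subjects: Sequence[SubjectRecord], note: str = "") -> "CohortTable":
        prov = self.provenance + (f" | {note}" if note else "")
        return CohortTable(subjects=list(subjects), provenance=prov)

    # -- tabular views -----------------------------------------------------

    def subjects_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "arm": s.arm,
                    "age_years": s.age_years,
                    "bmi": s.bmi,
                    "femoral_neck_tscore": s.femoral_neck_tscore,
                    "total_hip_tscore_baseline": s.total_hip_tscore_baseline,
                    "total_hip_tscore_end_core": s.total_hip_tscore_end_core,
                    "prior_vertebral_fx": s.prior_vertebral_fx,
                    "prior_nonvertebral_fx": s.prior_nonvertebral_fx,
                    "ever_smoker": s.ever_smoker,
                    "core_followup_years": s.core_followup_years,
                    "extension_followup_years": s.extension_followup_years,
                    "frax_mof_prob": s.frax_mof_prob,
                    "frax_hip_prob": s.frax_hip_prob,
                }
            )
        return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": s.subject_id, "event_type": ev.event_type, "time_years": ev.time_years}
            for s in self.subjects
            for ev in s.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def content_hash(self) -> str:
        """Stable hash of the cohort's data content (excludes provenance)."""
        h = hashlib.sha256()
        h.update(self.subjects_frame().to_csv(index=False).encode())
        h.update(self.events_frame().to_csv(index=False).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# First-event extraction


def first_event_time(
    subject: SubjectRecord, event_set: Iterable[str]
) -> tuple[float, bool]:
    """Time to first event of a type in ``event_set``, else censoring time.

    Returns ``(time, observed)``: the first matching event time with
    ``observed=True``, or ``(total follow-up, False)`` when no event of the
    requested types occurred.
    """
    event_set = frozenset(event_set)
    if not event_set:
        raise ValueError("event_set must be non-empty")
    bad = event_set - MOF_EVENTS
    if bad:
        raise ValueError(f"unknown event types in event_set: {sorted(bad)}")
    for ev in subject.events:
        if ev.event_type in event_set:
            return ev.time_years, True
    return subject.total_followup_years, False


# ---------------------------------------------------------------------------
# CSV serialization
#
# Two dialects:
#   long_events — subjects CSV + separate events CSV (one row per event);
#   wide        — single subjects CSV with an extra `events` column holding
#                 semicolon-separated "type@time" tokens.


def _format_optional(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def _subjects_to_csv_frame(cohort: CohortTable) -> pd.DataFrame:
    df = cohort.subjects_frame()
    out = df.copy()
    for col in _BOOL_COLUMNS:
        out[col] = df[col].map(lambda b: "true" if b else "false")
    # full-precision repr so the round-trip is exact
    for col in df.columns:
        if col in _BOOL_COLUMNS or col in ("subject_id", "arm"):
            continue
        out[col] = df[col].map(lambda x: "" if x is None or (isinstance(x, float) and np.isnan(x)) else repr(float(x)))
    return out


def write_cohort(cohort: CohortTable, subjects_path, events_path=None, dialect: str = "long_events") -> None:
    """Write a cohort to CSV so that :func:`read_cohort` reproduces it exactly.

    Booleans are serialized as ``"true"``/``"false"``; missing optional values
    as empty cells; floats at full precision.
    """
    sdf = _subjects_to_csv_frame(cohort)
    if dialect == "long_events":
        if events_path is None:
            raise ValueError("long_events dialect requires events_path")
        sdf.to_csv(subjects_path, index=False)
        edf = cohort.events_frame().copy()
        if len(edf):
            edf["time_years"] = edf["time_years"].map(lambda x: repr(float(x)))
        edf.to_csv(events_path, index=False)
    elif dialect == "wide":
        tokens = []
        for s in cohort.subjects:
            tokens.append(";".join(f"{ev.event_type}@{ev.time_years!r}" for ev in s.events))
        sdf = sdf.assign(events=tokens)
        sdf.to_csv(subjects_path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _parse_bool(value, col: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    v = str(value).strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise CohortSchemaError(f"column {col!r}, row {row}: cannot parse boolean from {value!r}")


def _parse_float(value, col: str, row: int, optional: bool = False) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        if optional:
            return None
        raise CohortSchemaError(f"column {col!r}, row {row}: missing required value")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortSchemaError(f"column {col!r}, row {row}: cannot parse number from {value!r}") from None


def read_cohort(subjects_path, events_path=None, dialect: str = "long_events") -> CohortTable:
    """Read a cohort written by :func:`write_cohort` (or conforming CSVs).

    Missing optional columns/cells load as missing values, never as zero.
    Raises :class:`CohortSchemaError` for malformed files and
    :class:`CohortValidationError` for invariant violations.
    """
    sdf = pd.read_csv(subjects_path, dtype=str, keep_default_na=False)
    required = [c for c in SUBJECT_COLUMNS if c not in _OPTIONAL_COLUMNS]
    missing_cols = [c for c in required if c not in sdf.columns]
    if missing_cols:
        raise CohortSchemaError(f"subjects CSV missing required columns: {missing_cols}")

    events_by_subject: dict[str, list[FractureEvent]] = {}
    if dialect == "long_events":
        if events_path is not None:
            edf = pd.read_csv(events_path, dtype=str, keep_default_na=False)
            missing_cols = [c for c in EVENT_COLUMNS if c not in edf.columns]
            if missing_cols:
                raise CohortSchemaError(f"events CSV missing required columns: {missing_cols}")
            for i, row in edf.iterrows():
                sid = row["subject_id"]
                t = _parse_float(row["time_years"], "time_years", i)
                events_by_subject.setdefault(sid, []).append(
                    FractureEvent(event_type=row["event_type"], time_years=t)
                )
    elif dialect == "wide":
        if "events" not in sdf.columns:
            raise CohortSchemaError("wide-dialect subjects CSV missing 'events' column")
        for i, row in sdf.iterrows():
            raw = str(row["events"]).strip()
            if not raw:
                continue
            evs = []
            for tok in raw.split(";"):
                try:
                    etype, tstr = tok.split("@")
                except ValueError:
                    raise CohortSchemaError(
                        f"column 'events', row {i}: malformed token {tok!r}"
                    ) from None
                evs.append(FractureEvent(event_type=etype, time_years=float(tstr)))
            events_by_subject[row["subject_id"]] = evs
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    subjects: list[SubjectRecord] = []
    for i, row in sdf.iterrows():
        sid = str(row["subject_id"])
        evs = sorted(events_by_subject.get(sid, []), key=lambda e: e.time_years)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                arm=str(row["arm"]),
                age_years=_parse_float(row["age_years"], "age_years", i),
                bmi=_parse_float(row["bmi"], "bmi", i),
                femoral_neck_tscore=_parse_float(row["femoral_neck_tscore"], "femoral_neck_tscore", i),
                total_hip_tscore_baseline=_parse_float(
                    row["total_hip_tscore_baseline"], "total_hip_tscore_baseline", i
                ),
                total_hip_tscore_end_core=_parse_float(
                    row.get("total_hip_tscore_end_core", ""), "total_hip_tscore_end_core", i, optional=True
                ),
                prior_vertebral_fx=_parse_bool(row["prior_vertebral_fx"], "prior_vertebral_fx", i),
                prior_nonvertebral_fx=_parse_bool(row["prior_nonvertebral_fx"], "prior_nonvertebral_fx", i),
                ever_smoker=_parse_bool(row["ever_smoker"], "ever_smoker", i),
                core_followup_years=_parse_float(row["core_followup_years"], "core_followup_years", i),
                extension_followup_years=_parse_float(
                    row["extension_followup_years"], "extension_followup_years", i
                ),
                events=evs,
                frax_mof_prob=_parse_float(row.get("frax_mof_prob", ""), "frax_mof_prob", i, optional=True),
                frax_hip_prob=_parse_float(row.get("frax_hip_prob", ""), "frax_hip_prob", i, optional=True),
            )
        )
    return CohortTable(subjects=subjects, provenance=str(subjects_path))


# ---------------------------------------------------------------------------
# Array view used by the estimators (one extraction, cheap resampling)


@dataclass
class CohortArrays:
    """Column-oriented view of a cohort for vectorized estimation.

    Built once per cohort; the bootstrap resamples integer row indices into
    these arrays instead of rebuilding subject objects.
    """

    subject_id: np.ndarray          # object
    is_crossover: np.ndarray        # bool
    age: np.ndarray
    bmi: np.ndarray
    fn_tscore: np.ndarray
    thip_base: np.ndarray
    thip_end_core: np.ndarray       # NaN when missing
    prior_vert: np.ndarray          # float 0/1
    prior_nonvert: np.ndarray
    smoker: np.ndarray
    core_fu: np.ndarray
    ext_fu: np.ndarray
    completer: np.ndarray           # bool, 10-year completer
    frax_mof: np.ndarray            # NaN when missing
    frax_hip: np.ndarray

    @classmethod
    def from_cohort(cls, cohort: CohortTable) -> "CohortArrays":
        n = len(cohort.subjects)
        get = lambda f: np.array([getattr(s, f) for s in cohort.subjects], dtype=float)  # noqa: E731
        opt = lambda f: np.array(  # noqa: E731
            [np.nan if getattr(s, f) is None else getattr(s, f) for s in cohort.subjects],
            dtype=float,
        )
        return cls(
            subject_id=np.array([s.subject_id for s in cohort.subjects], dtype=object),
            is_crossover=np.array([s.arm == "placebo_crossover" for s in cohort.subjects]),
            age=get("age_years"),
            bmi=get("bmi"),
            fn_tscore=get("femoral_neck_tscore"),
            thip_base=get("total_hip_tscore_baseline"),
            thip_end_core=opt("total_hip_tscore_end_core"),
            prior_vert=get("prior_vertebral_fx"),
            prior_nonvert=get("prior_nonvertebral_fx"),
            smoker=get("ever_smoker"),
            core_fu=get("core_followup_years"),
            ext_fu=get("extension_followup_years"),
            completer=np.array([s.is_ten_year_completer for s in cohort.subjects]),
            frax_mof=opt("frax_mof_prob"),
            frax_hip=opt("frax_hip_prob"),
        )

    def take(self, idx: np.ndarray) -> "CohortArrays":
        return CohortArrays(**{k: getattr(self, k)[idx] for k in self.__dataclass_fields__})

    def __len__(self) -> int:
        return len(self.age)


def event_count_arrays(cohort: CohortTable, event_set: Iterable[str]) -> dict[str, np.ndarray]:
    """Per-subject event summaries needed by the estimators.

    Returns core-period counts (total / vertebral / nonvertebral within
    ``event_set``) and the 10-year first-event time and indicator.
    """
    event_set = frozenset(event_set)
    n = len(cohort.subjects)
    core_count = np.zeros(n)
    core_vert = np.zeros(n)
    core_nonvert = np.zeros(n)
    t_first = np.empty(n)
    observed = np.zeros(n, dtype=bool)
    for i, s in enumerate(cohort.subjects):
        t, obs = first_event_time(s, event_set)
        t_first[i] = t
        observed[i] = obs
        for ev in s.events:
            if ev.event_type in event_set and ev.time_years < min(s.core_followup_years, CORE_YEARS):
                core_count[i] += 1
                if ev.event_type == "clinical_vertebral":
                    core_vert[i] += 1
                else:
                    core_nonvert[i] += 1
    return {
        "core_count": core_count,
        "core_vert": core_vert,
        "core_nonvert": core_nonvert,
        "first_time": t_first,
        "observed": observed,
    }
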