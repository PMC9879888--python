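"""Domain types, cohort I/O, and endpoint/inclusion logic.

The cohort model follows registry studies of primary hyperoxaluria type 1
(PH1): subjects are followed from PH1 diagnosis (the time origin, in decimal
years) until kidney failure -- the first of kidney transplant, initiation of
dialysis, or eGFR < 15 ml/min/1.73 m^2 -- or censoring at last follow-up.
Three biomarkers are measured sparsely and asynchronously over follow-up:
plasma oxalate (POX, umol/L), urinary oxalate excretion (UOX) and eGFR
(ml/min/1.73 m^2).  Biomarker values must be strictly positive because every
model downstream works on the natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BIOMARKERS = ("POX", "UOX", "eGFR")

SUBJECT_COLUMNS = ["subject_id", "age_at_dx", "sex", "entry_time", "event_time", "event"]
OBSERVATION_COLUMNS = ["subject_id", "biomarker", "time", "value"]


class Sex(str, Enum):
    female = "female"
    male = "male"


class EventStatus(str, Enum):
    kidney_failure = "kidney_failure"
    censored = "censored"


@dataclass(frozen=True)
class SubjectRecord:
    """Baseline covariates and the (possibly censored) kidney-failure time.

    ``entry_time`` and ``event_time`` are on the years-since-diagnosis scale;
    a subject is at risk on ``(entry_time, event_time]`` (delayed entry).
    """

    subject_id: str
    age_at_dx: float
    sex: Sex
    entry_time: float
    event_time: float
    event: EventStatus

    def __post_init__(self) -> None:
        if self.age_at_dx < 0:
            raise ValueError(f"subject {self.subject_id}: age_at_dx must be >= 0")
        if not self.entry_time < self.event_time:
            raise ValueError(
                f"subject {self.subject_id}: entry_time ({self.entry_time}) must be "
                f"strictly before event_time ({self.event_time})"
            )


@dataclass(frozen=True)
class LongitudinalObservation:
    """One biomarker value at one time for one subject.

    ``time`` may be as early as one year before diagnosis (the inclusion
    window admits pre-diagnosis eGFR measures); ``value`` must be positive so
    the log transform is defined.
    """

    subject_id: str
    biomarker: str
    time: float
    value: float

    def __post_init__(self) -> None:
        if self.biomarker not in BIOMARKERS:
            raise ValueError(f"unknown biomarker {self.biomarker!r}; expected one of {BIOMARKERS}")
        if not self.value > 0:
            raise ValueError(
                f"subject {self.subject_id}, {self.biomarker} at t={self.time}: "
                f"value must be > 0 (log transform), got {self.value}"
            )
        if self.time < -1:
            raise ValueError(
                f"subject {self.subject_id}: observation time {self.time} precedes the "
                "allowed one-year pre-diagnosis window"
            )


class EndpointKind(str, Enum):
    transplant = "transplant"
    dialysis_start = "dialysis_start"
    egfr_measure = "egfr_measure"


@dataclass(frozen=True)
class EndpointSourceRecord:
    """A raw record from which the composite kidney-failure endpoint is derived."""

    subject_id: str
    kind: EndpointKind
    time: float
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind == EndpointKind.egfr_measure:
            if self.value is None or not self.value > 0:
                raise ValueError("egfr_measure records must carry a positive eGFR value")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age_at_dx": s.age_at_dx,
                "sex": s.sex.value,
                "entry_time": s.entry_time,
                "event_time": s.event_time,
                "event": s.event.value,
            }
            for s in subjects
        ],
        columns=SUBJECT_COLUMNS,
    )


def observations_to_frame(observations: Sequence[LongitudinalObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject_id": o.subject_id, "biomarker": o.biomarker, "time": o.time, "value": o.value}
            for o in observations
        ],
        columns=OBSERVATION_COLUMNS,
    )


def write_cohort(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
    subject_table_path: str | Path,
    long_table_path: str | Path,
) -> None:
    """Serialize a cohort to the two-CSV dialect read by :func:`read_cohort`."""
    subjects_to_frame(subjects).to_csv(subject_table_path, index=False)
    observations_to_frame(observations).to_csv(long_table_path, index=False)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_cohort(
    subject_table_path: str | Path, long_table_path: str | Path
) -> tuple[list[SubjectRecord], list[LongitudinalObservation]]:
    """Read and validate the two-CSV cohort representation.

    Validation failures are hard errors naming the offending 1-based data row
    (header excluded).  Duplicate ``(subject, biomarker, time)`` observation
    rows are rejected -- registries should resolve duplicates upstream or via
    the counting-process builder's documented last-wins policy.
    """
    sdf = pd.read_csv(subject_table_path)
    _require_columns(sdf, SUBJECT_COLUMNS, subject_table_path)
    subjects: list[SubjectRecord] = []
    for i, row in enumerate(sdf.itertuples(index=False), start=1):
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    age_at_dx=float(row.age_at_dx),
                    sex=Sex(row.sex),
                    entry_time=float(row.entry_time),
                    event_time=float(row.event_time),
                    event=EventStatus(row.event),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{subject_table_path} row {i}: {exc}") from exc

    odf = pd.read_csv(long_table_path)
    _require_columns(odf, OBSERVATION_COLUMNS, long_table_path)
    observations: list[LongitudinalObservation] = []
    seen: set[tuple[str, str, float]] = set()
    for i, row in enumerate(odf.itertuples(index=False), start=1):
        try:
            obs = LongitudinalObservation(
                subject_id=str(row.subject_id),
                biomarker=str(row.biomarker),
                time=float(row.time),
                value=float(row.value),
            )
        except ValueError as exc:
            raise ValueError(f"{long_table_path} row {i}: {exc}") from exc
        key = (obs.subject_id, obs.biomarker, obs.time)
        if key in seen:
            raise ValueError(
                f"{long_table_path} row {i}: duplicate observation for subject "
                f"{obs.subject_id}, {obs.biomarker} at t={obs.time}"
            )
        seen.add(key)
        observations.append(obs)
    return subjects, observations


# ---------------------------------------------------------------------------
# Composite endpoint
# ---------------------------------------------------------------------------

EGFR_FAILURE_THRESHOLD = 15.0  # ml/min/1.73 m^2; strict `<` defines kidney failure


def derive_kidney_failure(
    records: Sequence[EndpointSourceRecord], last_followup: float | None = None
) -> tuple[float, EventStatus]:
    """Derive the composite kidney-failure endpoint for one subject.

    Kidney failure is the first occurrence of transplant, initiation of
    dialysis, or an eGFR measure below 15 ml/min/1.73 m^2.  If no record
    qualifies the subject is censored at ``last_followup``.  Co-occurring
    qualifying events at one time collapse to a single event at that time.
    Order-invariant in the input records.
    """
    qualifying = [
        r.time
        for r in records
        if r.kind in (EndpointKind.transplant, EndpointKind.dialysis_start)
        or (r.kind == EndpointKind.egfr_measure and r.value < EGFR_FAILURE_THRESHOLD)
    ]
    if qualifying:
        return (min(qualifying), EventStatus.kidney_failure)
    if last_followup is None:
        raise ValueError("no qualifying endpoint records and no last_followup provided")
    return (float(last_followup), EventStatus.censored)


# ---------------------------------------------------------------------------
# FAS eGFR
# ---------------------------------------------------------------------------

# Median serum creatinine Q (mg/dL) by completed age in years; the full age
# spectrum (FAS) equation normalizes serum creatinine by the age/sex-specific
# population median.  Ages 2-14 share one pediatric column; from 15 onward Q
# differs by sex and plateaus at the adult medians (0.90 men, 0.70 women).
_Q_PEDIATRIC = {
    2: 0.29, 3: 0.31, 4: 0.34, 5: 0.38, 6: 0.41, 7: 0.44,
    8: 0.46, 9: 0.49, 10: 0.51, 11: 0.53, 12: 0.57, 13: 0.59, 14: 0.61,
}
_Q_MALE_TEEN = {15: 0.72, 16: 0.78, 17: 0.82, 18: 0.85, 19: 0.88}
_Q_FEMALE_TEEN = {15: 0.64, 16: 0.67, 17: 0.69, 18: 0.69, 19: 0.70}
_Q_ADULT = {Sex.male: 0.90, Sex.female: 0.70}

FAS_CONSTANT = 107.3  # ml/min/1.73 m^2 at Scr == Q


def default_q_table(age: float, sex: Sex) -> float:
    """Age/sex median serum creatinine Q (mg/dL) for the FAS equation."""
    if age < 2:
        raise ValueError(f"age {age} below the supported FAS range (>= 2 years)")
    a = int(np.floor(age))
    if a <= 14:
        return _Q_PEDIATRIC[a]
    if a <= 19:
        return (_Q_MALE_TEEN if sex == Sex.male else _Q_FEMALE_TEEN)[a]
    return _Q_ADULT[sex]


def egfr_fas(serum_creatinine: float, age: float, sex: Sex, q_table=default_q_table) -> float:
    """Estimate GFR (ml/min/1.73 m^2) from serum creatinine via the full age
    spectrum equation: 107.3 / (Scr/Q), with a 0.988^(age-40) attenuation
    after age 40.  ``q_table(age, sex)`` supplies the normalizing median
    creatinine; it must raise for unsupported ages.
    """
    if not serum_creatinine > 0:
        raise ValueError("serum_creatinine must be > 0")
    q = q_table(age, sex)
    est = FAS_CONSTANT / (serum_creatinine / q)
    if age > 40:
        est *= 0.988 ** (age - 40)
    return est


# ---------------------------------------------------------------------------
# Inclusion filtering
# ---------------------------------------------------------------------------

@dataclass
class InclusionLog:
    """Per-criterion exclusion counts from :func:`apply_inclusion`."""

    n_input: int = 0
    excluded_age: int = 0
    excluded_failure_at_dx: int = 0
    excluded_no_egfr_in_window: int = 0
    n_retained: int = 0
    excluded_ids: list[str] = field(default_factory=list)

    def as_text(self) -> str:
        return (
            f"subjects in: {self.n_input}\n"
            f"excluded, age at diagnosis < 2: {self.excluded_age}\n"
            f"excluded, kidney failure at/before diagnosis: {self.excluded_failure_at_dx}\n"
            f"excluded, no eGFR in (-1, event) window: {self.excluded_no_egfr_in_window}\n"
            f"subjects retained: {self.n_retained}\n"
        )


def apply_inclusion(
    subjects: Sequence[SubjectRecord],
    observations: Sequence[LongitudinalObservation],
) -> tuple[list[SubjectRecord], list[LongitudinalObservation], InclusionLog]:
    """Apply the three cohort inclusion criteria.

    Retained subjects are (a) 2 years or older at diagnosis, (b) free of
    kidney failure at diagnosis (event strictly after time 0), and (c) have
    at least one eGFR measure in the window from one year before diagnosis to
    before kidney failure.  A subject failing several criteria is counted
    under the first failing criterion in that order.  Idempotent.
    """
    log = InclusionLog(n_input=len(subjects))
    egfr_times: dict[str, list[float]] = {}
    for o in observations:
        if o.biomarker == "eGFR":
            egfr_times.setdefault(o.subject_id, []).append(o.time)

    kept: list[SubjectRecord] = []
    for s in subjects:
        if s.age_at_dx < 2:
            log.excluded_age += 1
            log.excluded_ids.append(s.subject_id)
            continue
        if s.event == EventStatus.kidney_failure and s.event_time <= 0:
            log.excluded_failure_at_dx += 1
            log.excluded_ids.append(s.subject_id)
            continue
        times = egfr_times.get(s.subject_id, [])
        window_hi = s.event_time if s.event == EventStatus.kidney_failure else np.inf
        if not any(-1.0 <= t < window_hi for t in times):
            log.excluded_no_egfr_in_window += 1
            log.excluded_ids.append(s.subject_id)
            continue
        kept.append(s)
    log.n_retained = len(kept)
    kept_ids = {s.subject_id for s in kept}
    kept_obs = [o for o in observations if o.subject_id in kept_ids]
    return kept, kept_obs, log
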