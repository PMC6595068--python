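"""Per-patient timelines and 30-day all-cause readmission labeling.

A *timeline* is a patient's temporally ordered sequence of
hospitalization events.  An event t is labeled y_t = 1 when the next
admission occurs within 30 days of its discharge (inclusive: a gap of
exactly 30 days counts), else 0.  The final observed event is labeled
0 only when at least 30 days of observation remain after its
discharge; otherwise its outcome is censored and the event is
unlabelable.  Retained timelines are truncated at the last labelable
heart-failure (HF, CCS code 108) event, so every retained timeline
ends in an HF event — the prediction target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import HF_CODE

logger = logging.getLogger(__name__)

READMIT_WINDOW_DAYS = 30


class TimelineOrderError(ValueError):
    """Events handed to the labeler are not sorted by admission day."""


class EmptyCohortError(ValueError):
    """No timelines survive inclusion and labeling."""


@dataclass(frozen=True)
class ClaimEvent:
    """One inpatient hospitalization record."""

    patient_id: str
    admit_day: int
    discharge_day: int
    primary_dx: str
    secondary_dx: tuple = ()
    procedures: tuple = ()
    comorbidities: tuple = ()
    age_years: int = 0
    sex: str = "F"
    pay_source: str = "Medicare"

    def __post_init__(self):
        if self.discharge_day < self.admit_day:
            raise ValueError(
                f"discharge_day {self.discharge_day} precedes admit_day "
                f"{self.admit_day} for patient {self.patient_id}")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")

    @property
    def length_of_stay(self) -> int:
        return self.discharge_day - self.admit_day

    @property
    def is_hf(self) -> bool:
        return self.primary_dx == HF_CODE


@dataclass
class PatientTimeline:
    """Ordered events with per-event readmission labels, post-truncation.

    ``last_hf_index`` is the (0-based) index of the final event, which
    is always an HF event in a retained timeline.
    """

    patient_id: str
    events: list
    labels: np.ndarray
    is_hf: np.ndarray
    last_hf_index: int

    def __len__(self):
        return len(self.events)

    def __post_init__(self):
        if len(self.labels) != len(self.events):
            raise ValueError("labels and events must align")
        if not self.is_hf[self.last_hf_index]:
            raise ValueError("timeline must end in an HF event")

    @property
    def last_label(self) -> int:
        return int(self.labels[self.last_hf_index])


def sort_events(events) -> list:
    """Stable sort by (admit_day, discharge_day); preserves input order
    for full ties, the documented tie-break."""
    return sorted(events, key=lambda e: (e.admit_day, e.discharge_day))


def _check_sorted(events):
    for a, b in zip(events, events[1:]):
        if (b.admit_day, b.discharge_day) < (a.admit_day, a.discharge_day):
            raise TimelineOrderError(
                f"events for patient {a.patient_id} are not sorted by "
                f"admission day")


def include_patient(events, window_days: int = 365) -> bool:
    """Inclusion: at least one HF-primary event admitted early enough to
    allow a full 30-day lookahead (admit_day <= window_end - 30), with
    the patient aged >= 18 at that event."""
    return any(e.is_hf and e.age_years >= 18
               and e.admit_day <= window_days - READMIT_WINDOW_DAYS
               for e in events)


def label_events(events, window_days: int = 365) -> np.ndarray:
    """Raw per-event labels: 1/0, or -1 for a censored final event.

    Requires sorted events.  Labels every event (HF and non-HF) with
    the same rule; downstream losses choose which events contribute.
    """
    if not events:
        return np.zeros(0, dtype=int)
    _check_sorted(events)
    y = np.zeros(len(events), dtype=int)
    for t in range(len(events) - 1):
        gap = events[t + 1].admit_day - events[t].discharge_day
        y[t] = 1 if gap <= READMIT_WINDOW_DAYS else 0
    last = events[-1]
    if window_days - last.discharge_day < READMIT_WINDOW_DAYS:
        y[-1] = -1                      # censored: unlabelable
    return y


def label_timeline(events, window_days: int = 365):
    """Label, then truncate at the last labelable HF event.

    Returns a :class:`PatientTimeline`, or ``None`` when the patient
    has no labelable HF event.  Events after the truncation point are
    dropped; their effect on earlier labels is already baked in because
    labels are computed on the full sequence first.
    """
    y = label_events(events, window_days)
    keep = None
    for t in range(len(events) - 1, -1, -1):
        if events[t].is_hf and y[t] >= 0:
            keep = t
            break
    if keep is None:
        return None
    events = list(events[:keep + 1])
    labels = y[:keep + 1].astype(int)
    is_hf = np.array([e.is_hf for e in events], dtype=bool)
    return PatientTimeline(patient_id=events[0].patient_id, events=events,
                           labels=labels, is_hf=is_hf, last_hf_index=keep)


def events_from_claims(claims: pd.DataFrame) -> dict:
    """Group a claims table into per-patient sorted event lists."""
    out = {}
    for pid, grp in claims.groupby("patient_id", sort=True):
        events = [ClaimEvent(patient_id=row.patient_id,
                             admit_day=int(row.admit_day),
                             discharge_day=int(row.discharge_day),
                             primary_dx=str(row.primary_dx),
                             secondary_dx=tuple(row.secondary_dx),
                             procedures=tuple(row.procedures),
                             comorbidities=tuple(row.comorbidities),
                             age_years=int(row.age_years),
                             sex=str(row.sex),
                             pay_source=str(row.pay_source))
                  for row in grp.itertuples(index=False)]
        out[pid] = sort_events(events)
    return out


def build_timelines(claims: pd.DataFrame, window_days: int = 365) -> list:
    """Claims table -> list of labeled, truncated PatientTimelines.

    Applies inclusion (an adult HF index admission inside the
    labelable part of the window) before labeling; patients with no
    labelable HF event are dropped.
    """
    timelines = []
    for pid, events in events_from_claims(claims).items():
        if not include_patient(events, window_days):
            continue
        tl = label_timeline(events, window_days)
        if tl is not None:
            timelines.append(tl)
    return timelines


def cohort_summary(timelines) -> pd.Series:
    """Descriptive cohort statistics analogous to a Table-1 overview."""
    if not timelines:
        raise EmptyCohortError("cannot summarise an empty cohort")
    n = len(timelines)
    lengths = np.array([len(tl) for tl in timelines], dtype=float)
    ages = np.array([tl.events[tl.last_hf_index].age_years
                     for tl in timelines], dtype=float)
    female = np.mean([tl.events[0].sex == "F" for tl in timelines])
    hf_labels, n_events = [], 0
    pay = {}
    for tl in timelines:
        n_events += len(tl)
        hf_labels.extend(tl.labels[tl.is_hf])
        for e in tl.events:
            pay[e.pay_source] = pay.get(e.pay_source, 0) + 1
    hf_labels = np.asarray(hf_labels, dtype=float)
    out = {
        "n_patients": n,
        "n_events": n_events,
        "pct_female": 100.0 * float(female),
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=1)) if n > 1 else 0.0,
        "hf_event_share": float(len(hf_labels)) / n_events,
        "hf_readmission_rate": float(hf_labels.mean()),
        "last_hf_readmission_rate": float(np.mean(
            [tl.last_label for tl in timelines])),
        "timeline_length_mean": float(lengths.mean()),
        "timeline_length_sd": float(lengths.std(ddof=1)) if n > 1 else 0.0,
    }
    total = sum(pay.values())
    for src, cnt in sorted(pay.items()):
        out[f"pay_{src}"] = cnt / total
    return pd.Series(out)


# -- JSONL export ------------------------------------------------------


def timeline_to_record(tl: PatientTimeline) -> dict:
    return {
        "patient_id": tl.patient_id,
        "labels": [int(v) for v in tl.labels],
        "last_hf_index": int(tl.last_hf_index),
        "events": [{
            "admit_day": e.admit_day, "discharge_day": e.discharge_day,
            "primary_dx": e.primary_dx,
            "secondary_dx": list(e.secondary_dx),
            "procedures": list(e.procedures),
            "comorbidities": list(e.comorbidities),
            "age_years": e.age_years, "sex": e.sex,
            "pay_source": e.pay_source} for e in tl.events],
    }


def timeline_from_record(rec: dict) -> PatientTimeline:
    events = [ClaimEvent(patient_id=rec["patient_id"],
                         admit_day=ev["admit_day"],
                         discharge_day=ev["discharge_day"],
                         primary_dx=ev["primary_dx"],
                         secondary_dx=tuple(ev["secondary_dx"]),
                         procedures=tuple(ev["procedures"]),
                         comorbidities=tuple(ev["comorbidities"]),
                         age_years=ev["age_years"], sex=ev["sex"],
                         pay_source=ev["pay_source"])
              for ev in rec["events"]]
    labels = np.asarray(rec["labels"], dtype=int)
    is_hf = np.array([e.is_hf for e in events], dtype=bool)
    return PatientTimeline(patient_id=rec["patient_id"], events=events,
                           labels=labels, is_hf=is_hf,
                           last_hf_index=rec["last_hf_index"])
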