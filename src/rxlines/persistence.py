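"""Gap-method persistence: discontinuation, switching, censoring, retreatment.

Persistence is measured per treatment episode as the time, in consecutive
days, from the episode's first dispensing to the first of:

* **switch** — the start of a later episode with a different antipsychotic
  class (the persistence clock runs through add-on progressions, which keep
  the same anchor class);
* **discontinuation** — the last antipsychotic dispensing (of any class)
  that is followed by at least ``gap_days`` (default 183, ~6 months) with no
  antipsychotic dispensing; the event is dated at that last dispensing;
* **censoring** — the last antipsychotic dispensing when the remaining
  observation time (to ``window_end``) is too short to reveal a qualifying
  gap.

Time to retreatment runs from a discontinuation date to the next
antipsychotic dispensing, censored administratively at ``window_end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Sequence

import pandas as pd

from .claims_io import DrugClass
from .episodes import EndReason, TreatmentEpisode

__all__ = [
    "PersistenceEvent",
    "PersistenceRecord",
    "compute_persistence",
    "time_to_retreatment",
    "persistence_to_frame",
]


class PersistenceEvent(str, Enum):
    DISCONTINUED = "DISCONTINUED"
    SWITCHED = "SWITCHED"
    CENSORED = "CENSORED"


@dataclass(frozen=True)
class PersistenceRecord:
    patient_id: str
    line_number: int
    drug_class: DrugClass
    start_date: date
    event: PersistenceEvent
    event_date: date
    duration_days: int
    discontinuation_date: date | None = None  # set iff event is DISCONTINUED
    switch_to_class: DrugClass | None = None  # set iff event is SWITCHED


def _first_gap(
    dates: list[date], gap_days: int, window_end: date
) -> tuple[date | None, bool]:
    """First dispensing followed by a >= gap_days antipsychotic-free period.

    Returns (discontinuation_date, censored).  ``censored`` is True when no
    qualifying gap exists and the tail to window_end is too short to show
    one.
    """
    for cur, nxt in zip(dates[:-1], dates[1:]):
        if (nxt - cur).days >= gap_days:
            return cur, False
    last = dates[-1]
    if (window_end - last).days >= gap_days:
        return last, False
    return None, True


def compute_persistence(
    episodes: Sequence[TreatmentEpisode],
    claims: pd.DataFrame,
    window_end: date,
    gap_days: int = 183,
) -> list[PersistenceRecord]:
    """One persistence record per episode; resolves open episode end reasons.

    ``claims`` is the cohort claims frame (used for gap scanning over
    antipsychotic dispensings of any class).  Episodes whose ``end_reason``
    is still unresolved (final lines) are updated in place to DISCONTINUED
    or CENSORED according to their own record.
    """
    if gap_days <= 0:
        raise ValueError("gap_days must be positive")
    ap = claims[claims["is_antipsychotic"]]
    ap_dates: dict[str, list[date]] = {
        pid: sorted(set(g["dispense_date"]))
        for pid, g in ap.groupby("patient_id", sort=False)
    }
    by_patient: dict[str, list[TreatmentEpisode]] = {}
    for e in episodes:
        by_patient.setdefault(e.patient_id, []).append(e)

    records: list[PersistenceRecord] = []
    for pid, eps in by_patient.items():
        eps = sorted(eps, key=lambda e: e.line_number)
        dates_all = ap_dates.get(pid, [])
        for i, e in enumerate(eps):
            # Switch candidate: first later episode of a different class.
            switch_date: date | None = None
            switch_to: DrugClass | None = None
            for later in eps[i + 1 :]:
                if later.drug_class != e.drug_class:
                    switch_date = later.start_date
                    switch_to = later.drug_class
                    break
            # Gap candidate over this patient's antipsychotic claims.  An
            # add-on line opened by a late adjunct dispensing may have no
            # antipsychotic claim on/after its start; the gap then begins
            # at the line start itself.
            dates = [d for d in dates_all if d >= e.start_date]
            if dates:
                disc_date, censored = _first_gap(dates, gap_days, window_end)
            else:
                if (window_end - e.start_date).days >= gap_days:
                    disc_date, censored = e.start_date, False
                else:
                    disc_date, censored = None, True
                dates = [e.start_date]

            if switch_date is not None and (
                disc_date is None or switch_date <= disc_date
            ):
                event = PersistenceEvent.SWITCHED
                event_date = switch_date
            elif disc_date is not None:
                event = PersistenceEvent.DISCONTINUED
                event_date = disc_date
            else:
                event = PersistenceEvent.CENSORED
                event_date = dates[-1]
            records.append(
                PersistenceRecord(
                    patient_id=pid,
                    line_number=e.line_number,
                    drug_class=e.drug_class,
                    start_date=e.start_date,
                    event=event,
                    event_date=event_date,
                    duration_days=(event_date - e.start_date).days,
                    discontinuation_date=(
                        event_date if event is PersistenceEvent.DISCONTINUED else None
                    ),
                    switch_to_class=(
                        switch_to if event is PersistenceEvent.SWITCHED else None
                    ),
                )
            )
            if e.end_reason is None:
                e.end_reason = (
                    EndReason.DISCONTINUED
                    if event is PersistenceEvent.DISCONTINUED
                    else EndReason.CENSORED
                )
    return records


def persistence_to_frame(records: Sequence[PersistenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "line_number": [r.line_number for r in records],
            "drug_class": [r.drug_class for r in records],
            "start_date": [r.start_date for r in records],
            "duration_days": [r.duration_days for r in records],
            "event": [r.event.value for r in records],
            "discontinuation_date": [r.discontinuation_date for r in records],
            "switch_to_class": [r.switch_to_class for r in records],
        }
    )


def time_to_retreatment(
    records: Sequence[PersistenceRecord],
    claims: pd.DataFrame,
    window_end: date,
    per_patient: bool = True,
) -> pd.DataFrame:
    """Durations from discontinuation to the next antipsychotic dispensing.

    One row per discontinuation (by default the first per patient) with
    columns: patient_id, prior_class, discontinuation_date, duration_days,
    restarted (bool; False rows are censored at ``window_end``) and
    next_class.  Callers wanting restarters only filter on ``restarted``.
    """
    ap = claims[claims["is_antipsychotic"]]
    grouped = {
        pid: g.sort_values("dispense_date")
        for pid, g in ap.groupby("patient_id", sort=False)
    }
    disc = [r for r in records if r.event is PersistenceEvent.DISCONTINUED]
    if per_patient:
        first: dict[str, PersistenceRecord] = {}
        for r in sorted(disc, key=lambda r: (r.patient_id, r.discontinuation_date, r.line_number)):
            first.setdefault(r.patient_id, r)
        disc = list(first.values())

    rows = []
    for r in disc:
        g = grouped.get(r.patient_id)
        nxt = g[g["dispense_date"] > r.discontinuation_date] if g is not None else None
        if nxt is not None and len(nxt):
            nxt_row = nxt.iloc[0]
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "prior_class": r.drug_class,
                    "discontinuation_date": r.discontinuation_date,
                    "duration_days": (nxt_row["dispense_date"] - r.discontinuation_date).days,
                    "restarted": True,
                    "next_class": nxt_row["drug_class"],
                }
            )
        else:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "prior_class": r.drug_class,
                    "discontinuation_date": r.discontinuation_date,
                    "duration_days": (window_end - r.discontinuation_date).days,
                    "restarted": False,
                    "next_class": None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "prior_class",
            "discontinuation_date",
            "duration_days",
            "restarted",
            "next_class",
        ],
    )
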