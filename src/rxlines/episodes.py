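"""Line-of-therapy construction, polypharmacy detection, regimen census.

A patient's first in-window antipsychotic dispensing opens line 1.  The line
number advances when the patient

* **switches** — a dispensing of a different antipsychotic class appears and
  the current anchor class is not promptly re-dispensed afterwards (the
  anchor stops); or
* **adds on** — a first adjunct dispensing (antidepressant, lithium,
  antiepileptic) occurs strictly after the line start, or a second
  antipsychotic class appears while the anchor class continues to be
  dispensed (concurrent therapy).  The next line keeps the same anchor class
  and records the add-on.

Distinguishing a concurrent add-on from a switch hinges on whether the
anchor class continues: a new class dispensed while the anchor's next refill
arrives within its usual refill interval (plus a small grace for cadence
jitter) is concurrent; a new class after which the anchor never promptly
refills is a switch.  Gaps in dispensing never advance the line — they
produce discontinuation events, handled by the persistence module.

Same-day ties are broken deterministically: when two antipsychotic classes
first appear on the same date, the class earlier in the reporting order
(oral atypical, typical LAT, oral typical, atypical LAT, clozapine) anchors
the line and the other is treated as a concurrent add-on starting a new
line the same day.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import Sequence

import pandas as pd

from .claims_io import (
    ADJUNCT_CLASSES,
    ANTIPSYCHOTIC_CLASSES,
    CLASS_PRIORITY,
    DrugClass,
)

__all__ = [
    "EndReason",
    "TreatmentEpisode",
    "PolypharmacyFlag",
    "build_lines",
    "build_lines_cohort",
    "detect_polypharmacy",
    "classify_regimen",
    "episodes_to_frame",
]

# Grace added to the anchor's days supply when deciding whether it
# "continues" past a new class's first dispensing (absorbs refill jitter).
CONCURRENCY_GRACE_DAYS = 14


class EndReason(str, Enum):
    SWITCH = "SWITCH"
    ADDON_PROGRESSION = "ADDON_PROGRESSION"
    DISCONTINUED = "DISCONTINUED"
    CENSORED = "CENSORED"


@dataclass
class TreatmentEpisode:
    """Contiguous exposure to one antipsychotic class at one line number."""

    patient_id: str
    line_number: int
    drug_class: DrugClass
    start_date: date
    last_supply_end: date
    end_reason: EndReason | None  # None until persistence resolves final lines
    addon_classes: frozenset[DrugClass] = field(default_factory=frozenset)


def _sorted_patient_claims(patient_claims: pd.DataFrame) -> pd.DataFrame:
    order = patient_claims["drug_class"].map(CLASS_PRIORITY)
    return (
        patient_claims.assign(_prio=order)
        .sort_values(["dispense_date", "_prio", "molecule"], kind="mergesort")
        .drop(columns="_prio")
    )


def build_lines(
    patient_claims: pd.DataFrame,
    concurrency_grace_days: int = CONCURRENCY_GRACE_DAYS,
) -> list[TreatmentEpisode]:
    """Build ordered treatment episodes for one patient's classified claims.

    ``patient_claims`` must contain a single patient's claims (columns
    patient_id, dispense_date, molecule, drug_class, days_supply).  Adjunct
    claims dated on or before the first antipsychotic dispensing are
    baseline add-ons and do not advance the line.  Returns [] when the
    patient has no antipsychotic claims.
    """
    rows = _sorted_patient_claims(patient_claims)
    ap_mask = rows["drug_class"].map(lambda c: c in ANTIPSYCHOTIC_CLASSES)
    ap_rows = rows[ap_mask]
    if ap_rows.empty:
        return []
    pid = str(rows["patient_id"].iloc[0])

    # Per-class dispensing dates for the continuation look-ahead.
    class_dates: dict[DrugClass, list[date]] = {}
    class_supply: dict[DrugClass, int] = {}
    for cls, g in ap_rows.groupby("drug_class", observed=True):
        class_dates[cls] = sorted(g["dispense_date"].tolist())
        class_supply[cls] = int(g["days_supply"].iloc[0])

    def anchor_continues(anchor: DrugClass, d: date) -> bool:
        """Does the anchor class have a prompt dispensing on/after *d*?"""
        dates = class_dates[anchor]
        i = bisect_left(dates, d)
        if i == len(dates):
            return False
        return (dates[i] - d).days <= class_supply[anchor] + concurrency_grace_days

    episodes: list[TreatmentEpisode] = []
    anchor: DrugClass | None = None
    line_no = 0
    line_start: date | None = None
    addons: set[DrugClass] = set()
    supply_end: date | None = None
    adjuncts_seen: set[DrugClass] = set()
    first_line_start: date | None = None

    def close(reason: EndReason | None) -> None:
        episodes.append(
            TreatmentEpisode(
                patient_id=pid,
                line_number=line_no,
                drug_class=anchor,
                start_date=line_start,
                last_supply_end=supply_end,
                end_reason=reason,
                addon_classes=frozenset(addons),
            )
        )

    def extend_supply(d: date, days: int) -> None:
        nonlocal supply_end
        end = d + timedelta(days=int(days))
        if supply_end is None or end > supply_end:
            supply_end = end

    for row in rows.itertuples(index=False):
        cls: DrugClass = row.drug_class
        d: date = row.dispense_date
        if cls in ADJUNCT_CLASSES:
            if anchor is None or d <= first_line_start:
                # Baseline adjunct: present at (or before) index.
                adjuncts_seen.add(cls)
                if anchor is not None:
                    addons.add(cls)
                continue
            if cls in adjuncts_seen:
                addons.add(cls)
                continue
            adjuncts_seen.add(cls)
            close(EndReason.ADDON_PROGRESSION)
            line_no += 1
            line_start = d
            addons = set(addons) | {cls}
            continue
        # Antipsychotic claim.
        if anchor is None:
            anchor = cls
            line_no = 1
            line_start = d
            first_line_start = d
            addons = set()
            extend_supply(d, row.days_supply)
            continue
        if cls == anchor or cls in addons:
            extend_supply(d, row.days_supply)
            continue
        if anchor_continues(anchor, d):
            # Concurrent second antipsychotic class: add-on progression.
            close(EndReason.ADDON_PROGRESSION)
            line_no += 1
            line_start = d
            addons = set(addons) | {cls}
            extend_supply(d, row.days_supply)
        else:
            close(EndReason.SWITCH)
            anchor = cls
            line_no += 1
            line_start = d
            addons = set()
            supply_end = None
            extend_supply(d, row.days_supply)
    close(None)  # final line; persistence resolves DISCONTINUED vs CENSORED
    return episodes


def build_lines_cohort(
    claims: pd.DataFrame,
    cohort: pd.DataFrame,
    concurrency_grace_days: int = CONCURRENCY_GRACE_DAYS,
) -> list[TreatmentEpisode]:
    """Build lines for every cohort member from their on/post-index claims."""
    index_dates = cohort.set_index("patient_id")["index_date"]
    episodes: list[TreatmentEpisode] = []
    for pid, g in claims.groupby("patient_id", sort=True):
        if pid not in index_dates.index:
            continue
        g = g[g["dispense_date"] >= index_dates.loc[pid]]
        episodes.extend(build_lines(g, concurrency_grace_days))
    return episodes


def episodes_to_frame(episodes: Sequence[TreatmentEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "line_number": [e.line_number for e in episodes],
            "drug_class": [e.drug_class for e in episodes],
            "start_date": [e.start_date for e in episodes],
            "last_supply_end": [e.last_supply_end for e in episodes],
            "end_reason": [
                e.end_reason.value if e.end_reason else "" for e in episodes
            ],
            "addon_classes": [
                "|".join(sorted(c.value for c in e.addon_classes)) for e in episodes
            ],
        }
    )


@dataclass(frozen=True)
class PolypharmacyFlag:
    patient_id: str
    classes_involved: frozenset[DrugClass]
    concurrent_days: int
    flagged: bool


def _merged_intervals(starts: list[int], length: int) -> list[tuple[int, int]]:
    """Merge [s, s+length) intervals given sorted integer start days."""
    merged: list[tuple[int, int]] = []
    for s in starts:
        e = s + length
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def detect_polypharmacy(
    patient_claims: pd.DataFrame, threshold_days: int = 90
) -> PolypharmacyFlag:
    """Count days of concurrent exposure to >=2 qualifying drug classes.

    Each dispensing projects exposure over [dispense_date, dispense_date +
    days_supply).  A day is concurrent when at least two classes are active
    and at least one of them is an antipsychotic (two antipsychotics, or an
    antipsychotic plus an adjunct).  The patient is flagged when the total
    reaches ``threshold_days`` (default 90).
    """
    if threshold_days < 1:
        raise ValueError("threshold_days must be >= 1")
    pid = (
        str(patient_claims["patient_id"].iloc[0]) if len(patient_claims) else ""
    )
    per_class: dict[DrugClass, list[tuple[int, int]]] = {}
    for cls, g in patient_claims.groupby("drug_class", observed=True):
        starts = sorted(d.toordinal() for d in g["dispense_date"])
        length = int(g["days_supply"].iloc[0])
        per_class[cls] = _merged_intervals(starts, length)
    if len(per_class) < 2:
        return PolypharmacyFlag(pid, frozenset(), 0, False)

    # Sweep over elementary segments between interval boundaries.
    bounds = sorted({b for ivals in per_class.values() for iv in ivals for b in iv})
    concurrent = 0
    involved: set[DrugClass] = set()
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        active = [
            cls
            for cls, ivals in per_class.items()
            if any(s <= lo < e for s, e in ivals)
        ]
        n_ap = sum(1 for c in active if c in ANTIPSYCHOTIC_CLASSES)
        if len(active) >= 2 and n_ap >= 1:
            concurrent += hi - lo
            involved.update(active)
    return PolypharmacyFlag(
        pid, frozenset(involved), concurrent, concurrent >= threshold_days
    )


def classify_regimen(
    claims: pd.DataFrame,
    census_date: date,
    window_start: date,
    window_end: date,
) -> pd.DataFrame:
    """Tally monotherapy / dual / triple+ antipsychotic regimens at a census.

    A patient's regimen size is the number of distinct antipsychotic classes
    whose projected exposure interval covers ``census_date``; patients with
    no coverage are inactive and excluded from the denominator.

    Returns a one-row frame with counts (monotherapy, dual, triple_plus,
    active_patients) and matching percentage columns.
    """
    if not (window_start <= census_date <= window_end):
        raise ValueError("census_date must lie within the study window")
    ap = claims[claims["is_antipsychotic"]]
    covered_mask = [
        (d <= census_date) and (census_date < d + timedelta(days=int(ds)))
        for d, ds in zip(ap["dispense_date"], ap["days_supply"])
    ]
    covered = ap[pd.Series(covered_mask, index=ap.index)] if len(ap) else ap
    sizes = covered.groupby("patient_id")["drug_class"].nunique()
    mono = int((sizes == 1).sum())
    dual = int((sizes == 2).sum())
    triple = int((sizes >= 3).sum())
    active = int(len(sizes))
    out = {
        "monotherapy": mono,
        "dual": dual,
        "triple_plus": triple,
        "active_patients": active,
    }
    for key in ("monotherapy", "dual", "triple_plus"):
        out[f"{key}_pct"] = 100.0 * out[key] / active if active else float("nan")
    return pd.DataFrame([out])
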