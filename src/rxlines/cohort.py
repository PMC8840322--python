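"""New-user cohort selection with washout and co-medication exclusions.

The analysis population is incident (treatment-naive) antipsychotic users:
patients whose first antipsychotic dispensing falls inside the sampling
window, who had no antipsychotic dispensing during the lookback clean
period, no antidepressant dispensing on or before their index date (such
patients are assumed to be receiving antidepressant augmentation for
depression rather than schizophrenia treatment), and who are at least 16
years old at index.  Age is computed from year of birth only (index year
minus birth year), the finest resolution the source data carries.

Each excluded patient is assigned exactly one primary reason — the first
failing rule in the order: no qualifying dispensing in the window, prior
antipsychotic, prior/concomitant antidepressant, under age.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .claims_io import DrugClass

__all__ = ["CohortSpec", "ExclusionReason", "select_cohort"]


class ExclusionReason:
    NO_INDEX = "no_antipsychotic_in_window"
    PRIOR_ANTIPSYCHOTIC = "prior_antipsychotic"
    PRIOR_ANTIDEPRESSANT = "prior_antidepressant"
    UNDER_AGE = "under_age"

    ORDERED = (NO_INDEX, PRIOR_ANTIPSYCHOTIC, PRIOR_ANTIDEPRESSANT, UNDER_AGE)


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion window, washout period and age floor for cohort entry."""

    window_start: date = date(2013, 7, 1)
    window_end: date = date(2017, 9, 30)
    lookback_start: date = date(2006, 1, 1)
    min_age_years: int = 16

    def __post_init__(self) -> None:
        if not (self.lookback_start < self.window_start < self.window_end):
            raise ValueError("require lookback_start < window_start < window_end")
        if self.min_age_years < 0:
            raise ValueError("min_age_years must be >= 0")


def select_cohort(
    claims: pd.DataFrame, spec: CohortSpec = CohortSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion/exclusion rules to a classified claims frame.

    Parameters
    ----------
    claims
        Frame from :func:`rxlines.claims_io.claims_to_frame` (needs columns
        patient_id, dispense_date, drug_class, is_antipsychotic, sex,
        year_of_birth).
    spec
        Window/washout/age configuration.

    Returns
    -------
    (cohort, exclusions)
        ``cohort`` has one row per included patient
        (patient_id, index_date, age_at_index, sex); ``exclusions`` has one
        row per excluded patient (patient_id, reason).  Together they
        partition the input patients.
    """
    if claims.empty:
        empty_cohort = pd.DataFrame(
            columns=["patient_id", "index_date", "age_at_index", "sex"]
        )
        empty_excl = pd.DataFrame(columns=["patient_id", "reason"])
        return empty_cohort, empty_excl

    all_patients = pd.Index(claims["patient_id"].unique(), name="patient_id")
    ap = claims[claims["is_antipsychotic"]]

    in_window = ap[
        (ap["dispense_date"] >= spec.window_start)
        & (ap["dispense_date"] <= spec.window_end)
    ]
    index_date = in_window.groupby("patient_id")["dispense_date"].min()

    washout = ap[
        (ap["dispense_date"] >= spec.lookback_start)
        & (ap["dispense_date"] < spec.window_start)
    ]
    has_prior_ap = set(washout["patient_id"].unique())

    ad = claims[claims["drug_class"] == DrugClass.ANTIDEPRESSANT]
    first_ad = ad.groupby("patient_id")["dispense_date"].min()

    demo = (
        claims.sort_values("dispense_date")
        .groupby("patient_id")[["sex", "year_of_birth"]]
        .first()
    )

    cohort_rows: list[dict] = []
    excl_rows: list[dict] = []
    for pid in all_patients:
        if pid not in index_date.index:
            excl_rows.append({"patient_id": pid, "reason": ExclusionReason.NO_INDEX})
            continue
        idx = index_date.loc[pid]
        if pid in has_prior_ap:
            excl_rows.append(
                {"patient_id": pid, "reason": ExclusionReason.PRIOR_ANTIPSYCHOTIC}
            )
            continue
        if pid in first_ad.index and first_ad.loc[pid] <= idx:
            excl_rows.append(
                {"patient_id": pid, "reason": ExclusionReason.PRIOR_ANTIDEPRESSANT}
            )
            continue
        age = idx.year - int(demo.loc[pid, "year_of_birth"])
        if age < spec.min_age_years:
            excl_rows.append({"patient_id": pid, "reason": ExclusionReason.UNDER_AGE})
            continue
        cohort_rows.append(
            {
                "patient_id": pid,
                "index_date": idx,
                "age_at_index": age,
                "sex": demo.loc[pid, "sex"],
            }
        )

    cohort = pd.DataFrame(
        cohort_rows, columns=["patient_id", "index_date", "age_at_index", "sex"]
    )
    exclusions = pd.DataFrame(excl_rows, columns=["patient_id", "reason"])
    return cohort, exclusions
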