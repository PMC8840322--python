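"""Seeded generator of PBS-like dispensing claims with known ground truth.

The generator emulates the structure of national subsidised-dispensing
claims: one row per dispensing with patient demographics attached, oral
packs refilled on a ~30-day cadence and depot (long-acting injectable)
preparations on a ~28-day cadence, small uniform jitter on refill dates,
class-specific persistence distributions, one-step class switching,
six-month-plus treatment gaps followed by retreatment, adjunct co-medication
(antidepressants, lithium, antiepileptics), concurrent dual antipsychotic
therapy, and patients engineered to trigger each cohort exclusion rule.

Every stochastic choice is recorded per patient in a ground-truth table, so
downstream estimates (class shares, Kaplan-Meier medians, switch-matrix
cells, exclusion tallies, regimen sizes) can be checked against the values
the generator actually used.

Model sketch for an included patient with first class A:

* a persistence event time ``E1`` is drawn from A's configured distribution
  (exponential by default, parameterised by its median in days);
* with probability ``sum(switch_probs[A])`` the event is a switch, with
  destination drawn from the row; the new class runs its own persistence
  clock from the switch date; otherwise the event is a discontinuation,
  dated at the last dispensing (the generator places a final fill on the
  event day, matching the gap method's dating of discontinuation);
* a discontinued patient restarts with probability ``retreat_prob`` after a
  gap floor of ``gap_days + 1`` plus an exponential tail, on the same class
  with probability ``retreat_same_class_prob``;
* adjunct add-ons start at a random time strictly after index and refill
  monthly until the event; concurrent dual antipsychotic therapy (for
  non-switching patients) runs a second class alongside the anchor until
  the shared event day.

Administrative censoring arises naturally from the sampling-window end; no
separate censoring mechanism is injected.
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .claims_io import (
    ANTIPSYCHOTIC_CLASSES,
    ClassificationTable,
    DrugClass,
    Formulation,
)

__all__ = ["ClassParams", "SimConfig", "GroundTruth", "generate_claims", "study_like_config"]

_AP = [c.value for c in ANTIPSYCHOTIC_CLASSES]
_ADJ = ["ANTIDEPRESSANT", "LITHIUM", "ANTIEPILEPTIC"]

_DEPOT_CLASSES = {DrugClass.TYPICAL_LAT, DrugClass.ATYPICAL_LAT}


class ClassParams(BaseModel):
    """Market share and persistence distribution for one antipsychotic class."""

    share: float = Field(ge=0.0, le=1.0)
    persistence_family: Literal["exponential", "weibull"] = "exponential"
    persistence_median_days: float = Field(gt=0.0)
    weibull_shape: float = Field(default=1.5, gt=0.0)


class SimConfig(BaseModel):
    """Full parameterisation of the synthetic claims generator."""

    n_patients: int = Field(ge=0)
    seed: int = Field(ge=0)
    window_start: date = date(2013, 7, 1)
    window_end: date = date(2017, 9, 30)
    lookback_start: date = date(2006, 1, 1)
    gap_days: int = Field(default=183, gt=0)

    class_params: dict[str, ClassParams]
    dispensing_interval_days: dict[str, int] = {"oral": 30, "depot": 28}
    jitter_days: int = Field(default=3, ge=0)

    # switch_probs[A][B]: probability that a class-A episode's persistence
    # event is a switch landing on class B (row sums <= 1; remainder is
    # discontinuation).
    switch_probs: dict[str, dict[str, float]] = {}

    retreat_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    retreat_gap_median_days: float = Field(default=304.0, gt=0.0)
    retreat_same_class_prob: float = Field(default=0.7, ge=0.0, le=1.0)

    addon_rates: dict[str, float] = {}
    dual_ap_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    exclusion_fractions: dict[str, float] = {}

    male_fraction: float = Field(default=0.61, ge=0.0, le=1.0)
    age_band_edges: list[int] = [16, 25, 35, 45, 55, 65, 75, 85]
    age_band_weights: list[float] = [0.15, 0.15, 0.13, 0.12, 0.15, 0.13, 0.10, 0.07]
    states: list[str] = ["NSW", "VIC", "QLD", "WA", "SA", "TAS", "ACT", "NT"]
    concessional_fraction: float = Field(default=0.8, ge=0.0, le=1.0)

    @field_validator("class_params")
    @classmethod
    def _shares_sum_to_one(cls, v: dict[str, ClassParams]) -> dict[str, ClassParams]:
        unknown = set(v) - set(_AP)
        if unknown:
            raise ValueError(f"unknown antipsychotic classes: {sorted(unknown)}")
        total = sum(p.share for p in v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class shares must sum to 1, got {total}")
        return v

    @field_validator("exclusion_fractions")
    @classmethod
    def _known_exclusions(cls, v: dict[str, float]) -> dict[str, float]:
        allowed = {"prior_antipsychotic", "prior_antidepressant", "under_age"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown exclusion kinds: {sorted(unknown)}")
        if any(not (0.0 <= f <= 1.0) for f in v.values()):
            raise ValueError("exclusion fractions must be in [0, 1]")
        if sum(v.values()) > 1.0:
            raise ValueError("exclusion fractions must sum to <= 1")
        return v

    @field_validator("addon_rates")
    @classmethod
    def _known_addons(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(_ADJ)
        if unknown:
            raise ValueError(f"unknown adjunct classes: {sorted(unknown)}")
        if any(not (0.0 <= f <= 1.0) for f in v.values()):
            raise ValueError("addon rates must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if not (self.lookback_start < self.window_start < self.window_end):
            raise ValueError("require lookback_start < window_start < window_end")
        for a, row in self.switch_probs.items():
            if a not in _AP or set(row) - set(_AP):
                raise ValueError(f"switch_probs keys must be antipsychotic classes")
            if any(p < 0 for p in row.values()) or sum(row.values()) > 1.0 + 1e-9:
                raise ValueError(f"switch_probs[{a}] must be a sub-stochastic row")
        if len(self.age_band_weights) != len(self.age_band_edges):
            raise ValueError("age_band_weights must match age_band_edges")
        if abs(sum(self.age_band_weights) - 1.0) > 1e-9:
            raise ValueError("age_band_weights must sum to 1")
        return self

    def switch_total(self, cls_name: str) -> float:
        return sum(self.switch_probs.get(cls_name, {}).values())

    def event_time_cdf(self, cls_name: str, t: float) -> float:
        """CDF of the persistence event time for a class (closed form)."""
        p = self.class_params[cls_name]
        if p.persistence_family == "exponential":
            lam = math.log(2.0) / p.persistence_median_days
            return 1.0 - math.exp(-lam * t)
        scale = p.persistence_median_days / math.log(2.0) ** (1.0 / p.weibull_shape)
        return 1.0 - math.exp(-((t / scale) ** p.weibull_shape))

    def true_switch_cell(self, from_cls: str, to_cls: str, horizon_days: int) -> float:
        """P(first switch lands on ``to_cls`` within the horizon), percent."""
        p = self.switch_probs.get(from_cls, {}).get(to_cls, 0.0)
        return 100.0 * p * self.event_time_cdf(from_cls, horizon_days)


class GroundTruth:
    """Column glossary for the per-patient ground-truth frame.

    label: 'included' or the exclusion rule the patient triggers.
    first_class / event_type ('switch'|'discontinued') / event_day (days
    from index) describe the first-line persistence event; switch_to,
    retreat_day (days from discontinuation), retreat_class and
    regimen_at_census describe the later stochastic choices.
    """

    COLUMNS = [
        "patient_id",
        "label",
        "sex",
        "year_of_birth",
        "index_date",
        "first_class",
        "event_type",
        "event_day",
        "switch_to",
        "second_event_day",
        "retreat_day",
        "retreat_class",
        "dual_class",
        "addon_classes",
        "regimen_at_census",
    ]


def _sample_event_day(rng: np.random.Generator, p: ClassParams) -> int:
    if p.persistence_family == "exponential":
        scale = p.persistence_median_days / math.log(2.0)
        x = rng.exponential(scale)
    else:
        scale = p.persistence_median_days / math.log(2.0) ** (1.0 / p.weibull_shape)
        x = scale * rng.weibull(p.weibull_shape)
    return max(1, int(round(x)))


def _molecule_for(
    rng: np.random.Generator, classification: ClassificationTable, cls: DrugClass
) -> tuple[str, str, int]:
    mols = classification.molecules(cls)
    mol = mols[int(rng.integers(len(mols)))]
    form = Formulation.DEPOT if cls in _DEPOT_CLASSES else Formulation.ORAL
    return mol, form.value, classification.days_supply(mol, form)


def _cadence_fills(
    rng: np.random.Generator,
    start_day: int,
    end_day: int,
    interval: int,
    jitter: int,
    force_final: bool,
    horizon_day: int,
) -> list[int]:
    """Refill days in [start_day, min(end_day, horizon_day)].

    ``end_day`` is the event day (exclusive for cadence fills).  When
    ``force_final`` the last fill lands exactly on ``end_day`` (if within
    the horizon), matching the gap method's dating of discontinuation.
    """
    days: list[int] = []
    t = start_day
    stop = min(end_day, horizon_day)
    while t < stop:
        days.append(t)
        step = interval + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        t += max(1, step)
    if not days and start_day < end_day and start_day <= horizon_day:
        # The opening fill always exists while it is observable, even when
        # the window ends the same day.
        days.append(start_day)
    if force_final and end_day <= horizon_day and (not days or days[-1] < end_day):
        days.append(end_day)
    return days


def generate_claims(
    config: SimConfig, classification: ClassificationTable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a claims table and its ground truth, deterministically.

    Returns ``(claims, truth)``: ``claims`` conforms to the interchange
    schema (columns patient_id, dispense_date, molecule, formulation,
    quantity, sex, year_of_birth, state, concessional) sorted by patient and
    date; ``truth`` has one row per patient (see :class:`GroundTruth`).
    """
    classification = classification or ClassificationTable.default()
    rng = np.random.default_rng(config.seed)
    window_days = (config.window_end - config.window_start).days
    census = config.window_end

    class_names = _AP
    shares = np.array([config.class_params[c].share if c in config.class_params else 0.0 for c in class_names])

    excl_kinds = ["prior_antipsychotic", "prior_antidepressant", "under_age"]
    excl_probs = [config.exclusion_fractions.get(k, 0.0) for k in excl_kinds]
    role_probs = np.array(excl_probs + [1.0 - sum(excl_probs)])

    claims_rows: list[tuple] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        role = int(rng.choice(len(role_probs), p=role_probs))
        label = excl_kinds[role] if role < len(excl_kinds) else "included"

        sex = "male" if rng.random() < config.male_fraction else "female"
        state = config.states[int(rng.integers(len(config.states)))]
        concessional = bool(rng.random() < config.concessional_fraction)
        index_date = config.window_start + timedelta(days=int(rng.integers(0, window_days + 1)))
        horizon_day = (config.window_end - index_date).days

        if label == "under_age":
            age = int(rng.integers(10, 16))
        else:
            band = int(rng.choice(len(config.age_band_edges), p=np.asarray(config.age_band_weights)))
            lo = config.age_band_edges[band]
            hi = (
                config.age_band_edges[band + 1]
                if band + 1 < len(config.age_band_edges)
                else lo + 10
            )
            age = int(rng.integers(lo, hi))
        yob = index_date.year - age

        def emit(cls: DrugClass, day_offsets: list[int], base: date) -> None:
            mol, form, _ds = _molecule_for(rng, classification, cls)
            for off in day_offsets:
                claims_rows.append(
                    (
                        pid,
                        base + timedelta(days=int(off)),
                        mol,
                        form,
                        1,
                        sex,
                        yob,
                        state,
                        "true" if concessional else "false",
                    )
                )

        first_cls_name = class_names[int(rng.choice(len(shares), p=shares))]
        first_cls = DrugClass(first_cls_name)
        p1 = config.class_params[first_cls_name]
        interval = config.dispensing_interval_days[
            "depot" if first_cls in _DEPOT_CLASSES else "oral"
        ]
        e1 = _sample_event_day(rng, p1)

        truth: dict = {
            "patient_id": pid,
            "label": label,
            "sex": sex,
            "year_of_birth": yob,
            "index_date": index_date,
            "first_class": first_cls_name,
            "event_type": None,
            "event_day": None,
            "switch_to": None,
            "second_event_day": None,
            "retreat_day": None,
            "retreat_class": None,
            "dual_class": None,
            "addon_classes": "",
            "regimen_at_census": 0,
        }

        if label == "prior_antipsychotic":
            lb_span = max(1, (config.window_start - config.lookback_start).days - 120)
            lb_day = int(rng.integers(0, lb_span))
            emit(first_cls, [lb_day, lb_day + interval], config.lookback_start)
            emit(first_cls, _cadence_fills(rng, 0, e1, interval, config.jitter_days, False, horizon_day), index_date)
        elif label == "prior_antidepressant":
            ad_back = int(rng.integers(30, 401))
            ad_date = max(config.lookback_start, index_date - timedelta(days=ad_back))
            mols = classification.molecules(DrugClass.ANTIDEPRESSANT)
            mol = mols[int(rng.integers(len(mols)))]
            claims_rows.append(
                (pid, ad_date, mol, "oral", 1, sex, yob, state, "true" if concessional else "false")
            )
            emit(first_cls, _cadence_fills(rng, 0, e1, interval, config.jitter_days, False, horizon_day), index_date)
        elif label == "under_age":
            emit(first_cls, _cadence_fills(rng, 0, e1, interval, config.jitter_days, False, horizon_day), index_date)
        else:
            # Included patient: full event model.
            s_total = config.switch_total(first_cls_name)
            is_switch = rng.random() < s_total
            truth["event_day"] = e1
            if is_switch:
                row = config.switch_probs[first_cls_name]
                dests = list(row)
                pvec = np.array([row[d] for d in dests]) / s_total
                dest_name = dests[int(rng.choice(len(dests), p=pvec))]
                dest = DrugClass(dest_name)
                truth["event_type"] = "switch"
                truth["switch_to"] = dest_name
                # Anchor class fills strictly before the switch day.
                emit(first_cls, _cadence_fills(rng, 0, e1, interval, config.jitter_days, False, horizon_day), index_date)
                # Destination class from the switch day.
                p2 = config.class_params[dest_name]
                interval2 = config.dispensing_interval_days[
                    "depot" if dest in _DEPOT_CLASSES else "oral"
                ]
                e2 = _sample_event_day(rng, p2)
                truth["second_event_day"] = e2
                if e1 <= horizon_day:
                    fills2 = _cadence_fills(
                        rng, e1, e1 + e2, interval2, config.jitter_days, True, horizon_day
                    )
                    emit(dest, fills2, index_date)
            else:
                truth["event_type"] = "discontinued"
                emit(first_cls, _cadence_fills(rng, 0, e1, interval, config.jitter_days, True, horizon_day), index_date)
                # Concurrent dual antipsychotic therapy alongside the anchor.
                if e1 >= 100 and rng.random() < config.dual_ap_rate:
                    others = [c for c in class_names if c != first_cls_name]
                    dual_name = others[int(rng.integers(len(others)))]
                    dual = DrugClass(dual_name)
                    interval_d = config.dispensing_interval_days[
                        "depot" if dual in _DEPOT_CLASSES else "oral"
                    ]
                    d_start = int(rng.integers(10, e1 - 60))
                    fills_d = _cadence_fills(
                        rng, d_start, e1, interval_d, config.jitter_days, False, horizon_day
                    )
                    # Keep every dual fill concurrent with the anchor.
                    fills_d = [f for f in fills_d if f < e1]
                    emit(dual, fills_d, index_date)
                    truth["dual_class"] = dual_name
                # Retreatment after a qualifying gap.
                if e1 <= horizon_day and rng.random() < config.retreat_prob:
                    tail_median = max(
                        1.0, config.retreat_gap_median_days - (config.gap_days + 1)
                    )
                    gap = config.gap_days + 1 + int(
                        round(rng.exponential(tail_median / math.log(2.0)))
                    )
                    truth["retreat_day"] = gap
                    others = [
                        c
                        for c in class_names
                        if c != first_cls_name and c in config.class_params
                    ]
                    if not others or rng.random() < config.retreat_same_class_prob:
                        r_name = first_cls_name
                    else:
                        r_name = others[int(rng.integers(len(others)))]
                    truth["retreat_class"] = r_name
                    r_cls = DrugClass(r_name)
                    interval_r = config.dispensing_interval_days[
                        "depot" if r_cls in _DEPOT_CLASSES else "oral"
                    ]
                    e_r = _sample_event_day(rng, config.class_params[r_name])
                    fills_r = _cadence_fills(
                        rng,
                        e1 + gap,
                        e1 + gap + e_r,
                        interval_r,
                        config.jitter_days,
                        True,
                        horizon_day,
                    )
                    emit(r_cls, fills_r, index_date)
            # Adjunct add-ons (strictly after index, monthly refills).
            addons: list[str] = []
            for adj_name, rate in config.addon_rates.items():
                if rng.random() < rate:
                    a_start = int(rng.integers(1, max(2, min(e1, horizon_day) + 1)))
                    fills_a = _cadence_fills(
                        rng, a_start, max(a_start + 1, e1), 30, config.jitter_days, False, horizon_day
                    )
                    if fills_a:
                        mols = classification.molecules(DrugClass(adj_name))
                        mol = mols[int(rng.integers(len(mols)))]
                        for off in fills_a:
                            claims_rows.append(
                                (
                                    pid,
                                    index_date + timedelta(days=int(off)),
                                    mol,
                                    "oral",
                                    1,
                                    sex,
                                    yob,
                                    state,
                                    "true" if concessional else "false",
                                )
                            )
                        addons.append(adj_name)
            truth["addon_classes"] = "|".join(addons)

        truth_rows.append(truth)

    claims = pd.DataFrame(
        claims_rows,
        columns=[
            "patient_id",
            "dispense_date",
            "molecule",
            "formulation",
            "quantity",
            "sex",
            "year_of_birth",
            "state",
            "concessional",
        ],
    )
    claims = claims.sort_values(
        ["patient_id", "dispense_date", "molecule"], kind="mergesort"
    ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=GroundTruth.COLUMNS)
    if len(truth):
        sizes = _regimen_truth(claims, classification, census)
        truth["regimen_at_census"] = (
            truth["patient_id"].map(sizes).fillna(0).astype(int)
        )
    return claims, truth


def _regimen_truth(
    claims: pd.DataFrame, classification: ClassificationTable, census: date
) -> pd.Series:
    """Distinct antipsychotic classes covering the census date, per patient."""
    if claims.empty:
        return pd.Series(dtype=int)
    cls = [
        classification.classify(m, f)
        for m, f in zip(claims["molecule"], claims["formulation"])
    ]
    ds = [
        classification.days_supply(m, f)
        for m, f in zip(claims["molecule"], claims["formulation"])
    ]
    frame = claims.assign(drug_class=cls, days_supply=ds)
    frame = frame[[c.is_antipsychotic for c in frame["drug_class"]]]
    covered = frame[
        [
            (d <= census) and (census < d + timedelta(days=int(s)))
            for d, s in zip(frame["dispense_date"], frame["days_supply"])
        ]
    ]
    return covered.groupby("patient_id")["drug_class"].nunique()


def study_like_config(n_patients: int = 5000, seed: int = 20130701) -> SimConfig:
    """A packaged configuration that qualitatively mirrors the study setting.

    Class shares follow the published any-line prescribing shares
    (62/19/9/7/3% for atypical oral, typical LAT, typical oral, atypical
    LAT, clozapine); persistence medians follow the published class medians
    (7.9, 8.8, 6.2 and 12.7 months, with clozapine set far beyond follow-up
    so its median is unreached); switching favours the typical-oral to
    typical-LAT transition; and roughly half of discontinuers return to
    treatment, with a median retreatment interval of ten months.  The
    configuration is illustrative of that setting, not a reproduction of
    the licensed dataset.
    """
    month = 30.44
    return SimConfig(
        n_patients=n_patients,
        seed=seed,
        class_params={
            "ORAL_ATYPICAL": ClassParams(share=0.62, persistence_median_days=round(7.9 * month)),
            "TYPICAL_LAT": ClassParams(share=0.19, persistence_median_days=round(8.8 * month)),
            "ORAL_TYPICAL": ClassParams(share=0.09, persistence_median_days=round(6.2 * month)),
            "ATYPICAL_LAT": ClassParams(share=0.07, persistence_median_days=round(12.7 * month)),
            "CLOZAPINE": ClassParams(share=0.03, persistence_median_days=round(60 * month)),
        },
        switch_probs={
            "ORAL_ATYPICAL": {"ATYPICAL_LAT": 0.05, "ORAL_TYPICAL": 0.03, "TYPICAL_LAT": 0.03, "CLOZAPINE": 0.01},
            "ORAL_TYPICAL": {"TYPICAL_LAT": 0.40, "ORAL_ATYPICAL": 0.20},
            "TYPICAL_LAT": {"ORAL_ATYPICAL": 0.06, "CLOZAPINE": 0.09, "ATYPICAL_LAT": 0.02},
            "ATYPICAL_LAT": {"ORAL_ATYPICAL": 0.12},
            "CLOZAPINE": {},
        },
        retreat_prob=0.53,
        retreat_gap_median_days=304.0,
        retreat_same_class_prob=0.7,
        addon_rates={"ANTIDEPRESSANT": 0.22, "ANTIEPILEPTIC": 0.08, "LITHIUM": 0.04},
        dual_ap_rate=0.10,
        exclusion_fractions={
            "prior_antipsychotic": 0.10,
            "prior_antidepressant": 0.10,
            "under_age": 0.02,
        },
    )
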