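"""End-to-end orchestration: simulate -> cohort -> episodes -> reports.

The pipeline is a composition of the module-level functions; every stage is
a pure function of its input tables, so the whole run is reproducible from
the simulator seed and the analysis configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd
from pydantic import BaseModel, Field

from .claims_io import ANTIPSYCHOTIC_CLASSES, ClassificationTable, DrugClass, classify_frame
from .cohort import CohortSpec, select_cohort
from .episodes import (
    build_lines_cohort,
    classify_regimen,
    detect_polypharmacy,
    episodes_to_frame,
)
from .persistence import (
    PersistenceEvent,
    compute_persistence,
    persistence_to_frame,
    time_to_retreatment,
)
from .survival_stats import (
    ComparisonResult,
    ZeroRiskError,
    horizon_risk_ratio,
    km_estimate,
    median_survival,
)
from .switching_reporting import classify_returns, stratify, summarize_lines, switch_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "class_km", "compare_classes"]

DAYS_PER_MONTH = 30.44


class PipelineConfig(BaseModel):
    """All analysis thresholds in one place (echoed into run manifests)."""

    window_start: date = date(2013, 7, 1)
    window_end: date = date(2017, 9, 30)
    lookback_start: date = date(2006, 1, 1)
    min_age_years: int = 16
    gap_days: int = Field(default=183, gt=0)
    polypharmacy_threshold_days: int = Field(default=90, gt=0)
    horizon_days: int = Field(default=365, gt=0)
    switch_horizons: tuple[int, int] = (183, 365)
    reference_class: str = "ORAL_ATYPICAL"

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            window_start=self.window_start,
            window_end=self.window_end,
            lookback_start=self.lookback_start,
            min_age_years=self.min_age_years,
        )


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    episodes: list
    episodes_frame: pd.DataFrame
    persistence_records: list
    persistence_frame: pd.DataFrame
    line_summary: pd.DataFrame
    switch_matrices: dict
    returns: pd.DataFrame
    retreatment: pd.DataFrame
    comparisons: pd.DataFrame
    strata: dict[str, pd.DataFrame] = field(default_factory=dict)
    regimen: pd.DataFrame | None = None
    polypharmacy: pd.DataFrame | None = None


def class_km(
    records,
    drug_class: DrugClass,
    line_number: int | None = None,
    window_end: date | None = None,
    gap_days: int = 183,
):
    """Per-class KM inputs: durations and event flags from persistence records.

    Switch and discontinuation both end persistence (events); administrative
    censoring is the only non-event.  ``line_number`` restricts to one line
    (e.g. 1 for first-line persistence); None pools all lines.

    When ``window_end`` is given, follow-up is additionally capped at
    ``window_end - gap_days`` after each episode start: a discontinuation
    occurring later can never be ascertained (its six-month gap would run
    past the end of data), so leaving such subjects "at risk" beyond that
    boundary censors them exactly at their unconfirmed event times and
    biases the product-limit curve upward.  Capping restores independent
    administrative censoring.
    """
    sel = [
        r
        for r in records
        if r.drug_class == drug_class
        and (line_number is None or r.line_number == line_number)
    ]
    durations: list[int] = []
    events: list[bool] = []
    for r in sel:
        dur = r.duration_days
        ev = r.event is not PersistenceEvent.CENSORED
        if window_end is not None:
            limit = max(0, (window_end - r.start_date).days - gap_days)
            if dur > limit:
                dur, ev = limit, False
        durations.append(dur)
        events.append(ev)
    return durations, events


def compare_classes(
    records,
    horizon_days: int = 365,
    reference: DrugClass = DrugClass.ORAL_ATYPICAL,
    window_end: date | None = None,
    gap_days: int = 183,
) -> pd.DataFrame:
    """Fixed-horizon discontinuation risk ratios of each class vs reference."""
    dur_r, ev_r = class_km(records, reference, window_end=window_end, gap_days=gap_days)
    rows = []
    for cls in ANTIPSYCHOTIC_CLASSES:
        if cls == reference:
            continue
        dur_g, ev_g = class_km(records, cls, window_end=window_end, gap_days=gap_days)
        if not dur_g or not dur_r:
            continue
        try:
            res = horizon_risk_ratio(
                dur_g,
                ev_g,
                dur_r,
                ev_r,
                horizon_days=horizon_days,
                group_label=cls.value,
                reference_label=reference.value,
            )
        except ZeroRiskError:
            continue
        rows.append(
            {
                "group": res.group_label,
                "reference": res.reference_label,
                "rr": res.rr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "logrank_chi2": res.logrank_chi2,
                "p_value": res.p_value,
                "risk_group": res.risk_group,
                "risk_reference": res.risk_reference,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "reference",
            "rr",
            "ci_low",
            "ci_high",
            "logrank_chi2",
            "p_value",
            "risk_group",
            "risk_reference",
        ],
    )


def run_pipeline(
    raw_claims: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    classification: ClassificationTable | None = None,
    census_date: date | None = None,
) -> PipelineResult:
    """Run the full analysis on a raw claims frame (interchange schema)."""
    classification = classification or ClassificationTable.default()
    claims = classify_frame(raw_claims, classification)
    cohort, exclusions = select_cohort(claims, config.cohort_spec())
    cohort_claims = claims[claims["patient_id"].isin(set(cohort["patient_id"]))]
    episodes = build_lines_cohort(cohort_claims, cohort)
    records = compute_persistence(
        episodes, cohort_claims, window_end=config.window_end, gap_days=config.gap_days
    )
    line_summary = summarize_lines(episodes)
    matrices = switch_matrix(
        episodes, records, window_end=config.window_end, horizons=config.switch_horizons
    )
    returns = classify_returns(records, cohort_claims, config.window_end)
    retreat = time_to_retreatment(records, cohort_claims, config.window_end)
    comparisons = compare_classes(
        records,
        horizon_days=config.horizon_days,
        reference=DrugClass(config.reference_class),
        window_end=config.window_end,
        gap_days=config.gap_days,
    )
    strata = {
        by: stratify(episodes, cohort, by) for by in ("year", "age_band", "sex")
    }
    census = census_date or config.window_end
    regimen = classify_regimen(
        cohort_claims, census, config.window_start, config.window_end
    )
    poly_rows = []
    for pid, g in cohort_claims.groupby("patient_id", sort=True):
        flag = detect_polypharmacy(g, config.polypharmacy_threshold_days)
        poly_rows.append(
            {
                "patient_id": pid,
                "concurrent_days": flag.concurrent_days,
                "flagged": flag.flagged,
                "classes_involved": "|".join(
                    sorted(c.value for c in flag.classes_involved)
                ),
            }
        )
    polypharmacy = pd.DataFrame(
        poly_rows, columns=["patient_id", "concurrent_days", "flagged", "classes_involved"]
    )
    return PipelineResult(
        cohort=cohort,
        exclusions=exclusions,
        episodes=episodes,
        episodes_frame=episodes_to_frame(episodes),
        persistence_records=records,
        persistence_frame=persistence_to_frame(records),
        line_summary=line_summary,
        switch_matrices=matrices,
        returns=returns,
        retreatment=retreat,
        comparisons=comparisons,
        strata=strata,
        regimen=regimen,
        polypharmacy=polypharmacy,
    )


def median_persistence_by_class(
    records,
    line_number: int | None = 1,
    as_months: bool = False,
    window_end: date | None = None,
    gap_days: int = 183,
) -> dict[str, float | None]:
    """KM median persistence per antipsychotic class (days, or months/30.44)."""
    out: dict[str, float | None] = {}
    for cls in ANTIPSYCHOTIC_CLASSES:
        dur, ev = class_km(records, cls, line_number, window_end=window_end, gap_days=gap_days)
        if not dur:
            out[cls.value] = None
            continue
        med = median_survival(km_estimate(dur, ev))
        if med is not None and as_months:
            med = med / DAYS_PER_MONTH
        out[cls.value] = med
    return out
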