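"""Switch matrices, return-to-treatment classes and descriptive tables.

All reports are pure functions of the episode/persistence tables: re-running
them on identical inputs yields identical output frames.  Percentage-share
denominators follow the treatment-episode convention — a patient with
several lines of therapy contributes once per line, not once overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .claims_io import ANTIPSYCHOTIC_CLASSES, DrugClass
from .episodes import TreatmentEpisode
from .persistence import PersistenceEvent, PersistenceRecord, time_to_retreatment

__all__ = [
    "SwitchMatrix",
    "switch_matrix",
    "classify_returns",
    "summarize_lines",
    "stratify",
    "DEFAULT_AGE_BANDS",
]

_AP_NAMES = [c.value for c in ANTIPSYCHOTIC_CLASSES]

DEFAULT_AGE_BANDS: tuple[int, ...] = (16, 25, 35, 45, 55, 65, 75, 85)


@dataclass(frozen=True)
class SwitchMatrix:
    """From-class x to-class switching percentages at one horizon.

    ``percent`` rows are from-classes, columns to-classes; the diagonal is
    NaN (no self-switch).  ``denominators`` counts, per from-class, the
    first-line starters with at least ``horizon_days`` of potential
    follow-up; rows with a zero denominator are all-NaN.
    """

    horizon_days: int
    percent: pd.DataFrame
    denominators: pd.Series


def switch_matrix(
    episodes: Sequence[TreatmentEpisode],
    records: Sequence[PersistenceRecord],
    window_end: date,
    horizons: tuple[int, ...] = (183, 365),
) -> dict[int, SwitchMatrix]:
    """Proportion of first-line starters switching class within each horizon.

    A switch is a first-line persistence record ending in SWITCHED — i.e. a
    change of antipsychotic class during continuous therapy (a return to a
    different class after a qualifying gap is a retreatment, not a switch).
    Cell (A, B, h) = 100 x #{starters of A whose first switch lands on B
    within h days} / #{starters of A with full potential follow-up}.  The
    denominator requires max(horizons) days of potential follow-up (index on
    or before window_end - max(horizons)) and is shared by every horizon in
    the call, so cells are cumulative in the horizon: the same patients are
    scored at 6 and at 12 months.
    """
    line1 = [r for r in records if r.line_number == 1]
    out: dict[int, SwitchMatrix] = {}
    max_h = max(horizons)
    for h in horizons:
        denom = pd.Series(0, index=_AP_NAMES, dtype=int)
        counts = pd.DataFrame(0, index=_AP_NAMES, columns=_AP_NAMES, dtype=int)
        cutoff = window_end - timedelta(days=int(max_h))
        for r in line1:
            if r.start_date > cutoff:
                continue
            denom[r.drug_class.value] += 1
            if (
                r.event is PersistenceEvent.SWITCHED
                and r.duration_days <= h
                and r.switch_to_class is not None
            ):
                counts.loc[r.drug_class.value, r.switch_to_class.value] += 1
        percent = counts.astype(float)
        for cls in _AP_NAMES:
            if denom[cls] > 0:
                percent.loc[cls] = 100.0 * counts.loc[cls] / denom[cls]
            else:
                percent.loc[cls] = np.nan
        np.fill_diagonal(percent.values, np.nan)
        out[h] = SwitchMatrix(horizon_days=h, percent=percent, denominators=denom)
    return out


def classify_returns(
    records: Sequence[PersistenceRecord],
    claims: pd.DataFrame,
    window_end: date,
    horizons: tuple[int, ...] = (183, 365),
) -> pd.DataFrame:
    """Outcome of each patient's first discontinuation, by prior class.

    Every discontinued patient falls in exactly one of: recommenced the
    same class, recommenced a different class, or did not return within the
    observation window.  Shares are percentages of discontinued patients per
    prior class (rows sum to 100), with cumulative return percentages at the
    requested horizons after the discontinuation date.
    """
    retreat = time_to_retreatment(records, claims, window_end, per_patient=True)
    rows = []
    for cls in ANTIPSYCHOTIC_CLASSES:
        g = retreat[retreat["prior_class"] == cls]
        n = len(g)
        if n == 0:
            rows.append(
                {
                    "prior_class": cls.value,
                    "n_discontinued": 0,
                    "pct_same_class": np.nan,
                    "pct_different_class": np.nan,
                    "pct_no_return": np.nan,
                    **{f"pct_returned_{h}d": np.nan for h in horizons},
                }
            )
            continue
        same = int(((g["next_class"] == cls) & g["restarted"]).sum())
        diff = int((g["restarted"] & (g["next_class"] != cls)).sum())
        none = int((~g["restarted"]).sum())
        row = {
            "prior_class": cls.value,
            "n_discontinued": n,
            "pct_same_class": 100.0 * same / n,
            "pct_different_class": 100.0 * diff / n,
            "pct_no_return": 100.0 * none / n,
        }
        for h in horizons:
            row[f"pct_returned_{h}d"] = (
                100.0 * float((g["restarted"] & (g["duration_days"] <= h)).sum()) / n
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_lines(episodes: Sequence[TreatmentEpisode]) -> pd.DataFrame:
    """Per-class episode counts and percentage shares by line stratum.

    Strata: any line, first line (line 1), second-or-later lines.
    Denominators are treatment-episode counts, so patients with several
    lines contribute once per line; each percentage column sums to 100
    (up to rounding) when its denominator is non-zero.
    """
    frame = pd.DataFrame(
        {
            "drug_class": [e.drug_class.value for e in episodes],
            "line_number": [e.line_number for e in episodes],
        }
    )
    strata = {
        "any_line": frame,
        "first_line": frame[frame["line_number"] == 1],
        "later_line": frame[frame["line_number"] >= 2],
    }
    out = pd.DataFrame(index=_AP_NAMES)
    out.index.name = "drug_class"
    for name, sub in strata.items():
        counts = sub["drug_class"].value_counts().reindex(_AP_NAMES).fillna(0).astype(int)
        total = int(counts.sum())
        out[f"{name}_n"] = counts
        out[f"{name}_pct"] = 100.0 * counts / total if total else np.nan
    return out.reset_index()


def _age_band_labels(edges: Sequence[int]) -> list[str]:
    labels = [f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]}+")
    return labels


def stratify(
    episodes: Sequence[TreatmentEpisode],
    cohort: pd.DataFrame,
    by: str,
    age_bands: Sequence[int] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """Per-stratum class shares (%) of treatment episodes.

    ``by`` is one of ``year`` (episode start year), ``age_band`` (patient
    age at index, decennial bands by default) or ``sex``.  Rows are strata,
    columns the five antipsychotic classes plus an episode count.
    """
    if by not in {"year", "age_band", "sex"}:
        raise ValueError(f"unknown stratifier: {by!r}")
    frame = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "drug_class": [e.drug_class.value for e in episodes],
            "start_year": [e.start_date.year for e in episodes],
        }
    )
    demo = cohort.set_index("patient_id")
    if by == "year":
        frame["stratum"] = frame["start_year"].astype(str)
    elif by == "sex":
        frame["stratum"] = frame["patient_id"].map(demo["sex"])
    else:
        ages = frame["patient_id"].map(demo["age_at_index"])
        edges = list(age_bands) + [np.inf]
        labels = _age_band_labels(list(age_bands))
        frame["stratum"] = pd.cut(
            ages, bins=edges, labels=labels, right=False, include_lowest=True
        )
    rows = []
    for stratum, g in frame.groupby("stratum", observed=True, sort=True):
        counts = g["drug_class"].value_counts().reindex(_AP_NAMES).fillna(0)
        total = counts.sum()
        row = {"stratum": str(stratum), "n_episodes": int(total)}
        for cls in _AP_NAMES:
            row[cls] = 100.0 * counts[cls] / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
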