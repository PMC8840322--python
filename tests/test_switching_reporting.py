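from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from rxlines.claims_io import DrugClass
from rxlines.episodes import build_lines
from rxlines.persistence import compute_persistence
from rxlines.switching_reporting import (
    classify_returns,
    stratify,
    summarize_lines,
    switch_matrix,
)

WINDOW_END = date(2017, 9, 30)


def monthly(pid, molecule, formulation, start, n, step=30):
    d0 = date.fromisoformat(start)
    return [
        (pid, (d0 + timedelta(days=step * k)).isoformat(), molecule, formulation)
        for k in range(n)
    ]


def build(make_claims, rows):
    claims = make_claims(rows)
    eps = []
    for _, g in claims.groupby("patient_id"):
        eps.extend(build_lines(g))
    recs = compute_persistence(eps, claims, WINDOW_END)
    return claims, eps, recs


def test_no_switches_zero_matrix(make_claims):
    _, eps, recs = build(make_claims, monthly("P1", "olanzapine", "oral", "2014-01-01", 6))
    m = switch_matrix(eps, recs, WINDOW_END)[365]
    vals = m.percent.to_numpy()
    assert np.nansum(vals) == 0.0
    assert m.denominators["ORAL_ATYPICAL"] == 1


def test_single_switcher_hundred_percent_cell(make_claims):
    rows = monthly("P1", "chlorpromazine", "oral", "2014-01-01", 3, 30) + monthly(
        "P1", "flupenthixol", "depot", "2014-04-11", 3, 28
    )
    _, eps, recs = build(make_claims, rows)
    out = switch_matrix(eps, recs, WINDOW_END)
    assert out[183].percent.loc["ORAL_TYPICAL", "TYPICAL_LAT"] == 100.0
    assert out[183].percent.loc["ORAL_TYPICAL", "ORAL_ATYPICAL"] == 0.0
    assert out[365].percent.loc["ORAL_TYPICAL", "TYPICAL_LAT"] == 100.0


def test_switch_after_gap_not_counted_as_switch(make_claims):
    rows = monthly("P1", "chlorpromazine", "oral", "2014-01-01", 2, 30) + [
        ("P1", "2014-12-01", "flupenthixol", "depot")
    ]
    _, eps, recs = build(make_claims, rows)
    m = switch_matrix(eps, recs, WINDOW_END)[365]
    assert np.nansum(m.percent.to_numpy()) == 0.0


def test_matrix_monotone_in_horizon_on_simulated_cohort():
    from rxlines import generate_claims, run_pipeline, study_like_config

    claims, _ = generate_claims(study_like_config(n_patients=400, seed=5))
    res = run_pipeline(claims)
    m6 = res.switch_matrices[183].percent.to_numpy()
    m12 = res.switch_matrices[365].percent.to_numpy()
    mask = ~np.isnan(m6) & ~np.isnan(m12)
    assert np.all(m12[mask] >= m6[mask] - 1e-9)


def test_patient_without_full_followup_not_in_denominator(make_claims):
    start = (WINDOW_END - timedelta(days=100)).isoformat()
    _, eps, recs = build(make_claims, monthly("P1", "olanzapine", "oral", start, 3, 30))
    m = switch_matrix(eps, recs, WINDOW_END)[365]
    assert m.denominators["ORAL_ATYPICAL"] == 0
    assert np.isnan(m.percent.loc["ORAL_ATYPICAL"]).all()


# --- returns ----------------------------------------------------------------


def test_returns_same_different_none(make_claims):
    rows = (
        # SAME: discontinues olanzapine, returns to olanzapine.
        monthly("S", "olanzapine", "oral", "2014-01-01", 2, 30)
        + [("S", "2015-01-01", "olanzapine", "oral")]
        # DIFF: discontinues olanzapine, returns on typical LAT.
        + monthly("D", "olanzapine", "oral", "2014-01-01", 2, 30)
        + [("D", "2015-01-01", "flupenthixol", "depot")]
        # NONE: discontinues, never returns.
        + monthly("N", "olanzapine", "oral", "2014-01-01", 2, 30)
    )
    claims, eps, recs = build(make_claims, rows)
    out = classify_returns(recs, claims, WINDOW_END)
    row = out[out["prior_class"] == "ORAL_ATYPICAL"].iloc[0]
    assert row["n_discontinued"] == 3
    assert row["pct_same_class"] == pytest.approx(100 / 3)
    assert row["pct_different_class"] == pytest.approx(100 / 3)
    assert row["pct_no_return"] == pytest.approx(100 / 3)
    # Shares always sum to 100.
    assert (
        row["pct_same_class"] + row["pct_different_class"] + row["pct_no_return"]
        == pytest.approx(100.0)
    )


# --- line summary -----------------------------------------------------------


def test_single_patient_single_line_is_hundred_percent(make_claims):
    _, eps, _ = build(make_claims, monthly("P1", "clozapine", "oral", "2014-01-01", 4))
    out = summarize_lines(eps)
    row = out[out["drug_class"] == "CLOZAPINE"].iloc[0]
    assert row["any_line_n"] == 1 and row["any_line_pct"] == 100.0
    assert out["later_line_n"].sum() == 0


def test_percentages_sum_to_hundred_per_stratum():
    from rxlines import generate_claims, run_pipeline, study_like_config

    claims, _ = generate_claims(study_like_config(n_patients=300, seed=13))
    res = run_pipeline(claims)
    out = res.line_summary
    for col in ("any_line_pct", "first_line_pct", "later_line_pct"):
        assert out[col].sum() == pytest.approx(100.0, abs=0.5)


def test_reports_are_deterministic_functions_of_inputs():
    from rxlines import generate_claims, run_pipeline, study_like_config

    claims, _ = generate_claims(study_like_config(n_patients=200, seed=2))
    r1 = run_pipeline(claims)
    r2 = run_pipeline(claims)
    pd.testing.assert_frame_equal(r1.line_summary, r2.line_summary)
    pd.testing.assert_frame_equal(r1.returns, r2.returns)
    pd.testing.assert_frame_equal(
        r1.switch_matrices[365].percent, r2.switch_matrices[365].percent
    )


# --- stratification ---------------------------------------------------------


def _cohort_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "index_date", "age_at_index", "sex"]
    )


def test_single_stratum_reduces_to_line_summary(make_claims):
    rows = monthly("P1", "olanzapine", "oral", "2014-01-01", 3) + monthly(
        "P2", "clozapine", "oral", "2014-02-01", 3
    )
    claims, eps, _ = build(make_claims, rows)
    cohort = _cohort_frame(
        [("P1", date(2014, 1, 1), 30, "male"), ("P2", date(2014, 2, 1), 40, "male")]
    )
    out = stratify(eps, cohort, by="year")
    assert out["stratum"].tolist() == ["2014"]
    assert out.iloc[0]["ORAL_ATYPICAL"] == 50.0
    assert out.iloc[0]["CLOZAPINE"] == 50.0


def test_sex_split_recovers_known_excess(make_claims):
    rows = []
    cohort_rows = []
    for i in range(10):
        pid = f"F{i}"
        mol = "flupenthixol" if i < 5 else "olanzapine"
        form = "depot" if i < 5 else "oral"
        rows += monthly(pid, mol, form, "2014-01-01", 2)
        cohort_rows.append((pid, date(2014, 1, 1), 40, "female"))
    for i in range(10):
        pid = f"M{i}"
        mol = "flupenthixol" if i < 2 else "olanzapine"
        form = "depot" if i < 2 else "oral"
        rows += monthly(pid, mol, form, "2014-01-01", 2)
        cohort_rows.append((pid, date(2014, 1, 1), 40, "male"))
    claims, eps, _ = build(make_claims, rows)
    out = stratify(eps, _cohort_frame(cohort_rows), by="sex").set_index("stratum")
    assert out.loc["female", "TYPICAL_LAT"] > out.loc["male", "TYPICAL_LAT"]


def test_age_band_stratification_uses_index_age(make_claims):
    rows = monthly("Y", "paliperidone", "depot", "2014-01-01", 2) + monthly(
        "O", "flupenthixol", "depot", "2014-01-01", 2
    )
    claims, eps, _ = build(make_claims, rows)
    cohort = _cohort_frame(
        [("Y", date(2014, 1, 1), 22, "male"), ("O", date(2014, 1, 1), 78, "male")]
    )
    out = stratify(eps, cohort, by="age_band").set_index("stratum")
    assert out.loc["16-24", "ATYPICAL_LAT"] == 100.0
    assert out.loc["75-84", "TYPICAL_LAT"] == 100.0


def test_unknown_stratifier_rejected(make_claims):
    claims, eps, _ = build(make_claims, monthly("P1", "olanzapine", "oral", "2014-01-01", 2))
    with pytest.raises(ValueError):
        stratify(eps, _cohort_frame([("P1", date(2014, 1, 1), 30, "male")]), by="state")
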