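from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from rxlines.claims_io import ClassificationTable, classify_frame


@pytest.fixture(scope="session")
def table() -> ClassificationTable:
    return ClassificationTable.default()


def raw_claims(rows, sex="male", yob=1980, state="NSW", concessional=False):
    """Build a raw claims frame from (pid, iso_date, molecule, formulation) rows.

    Rows may optionally carry a 5th element overriding year_of_birth.
    """
    recs = []
    for row in rows:
        pid, d, mol, form = row[:4]
        recs.append(
            {
                "patient_id": pid,
                "dispense_date": date.fromisoformat(d),
                "molecule": mol,
                "formulation": form,
                "quantity": 1,
                "sex": sex,
                "year_of_birth": row[4] if len(row) > 4 else yob,
                "state": state,
                "concessional": concessional,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def make_claims(table):
    """Classified claims frame factory from compact row tuples."""

    def _make(rows, **kwargs):
        return classify_frame(raw_claims(rows, **kwargs), table)

    return _make
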