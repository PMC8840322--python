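"""Claims data model, CSV interchange format, and drug-class resolution.

A *claim* is one dispensing event: a patient received one supply of one
medicine on one date.  Analyses downstream never look at the molecule
itself; every (molecule, formulation) pair is mapped to an analysis class —
five antipsychotic classes (oral typical, oral atypical, typical long-acting
therapy, atypical long-acting therapy, clozapine) plus three adjunct
categories (antidepressant, lithium, antiepileptic) that drive exclusion and
line-progression rules.

The classification ships as a packaged, editable CSV keyed on
(molecule, formulation) rather than on national item codes, so the same
partition can be applied to any claims extract.  Exposure duration is not
recorded in dispensing claims; each entry therefore carries a
``default_days_supply`` (30 days for oral packs, 28 for depot injections)
used to project exposure intervals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Formulation",
    "DrugClass",
    "Sex",
    "ANTIPSYCHOTIC_CLASSES",
    "ADJUNCT_CLASSES",
    "CLASS_PRIORITY",
    "ClaimRecord",
    "DrugClassEntry",
    "ClassificationTable",
    "UnknownDrugError",
    "ClaimsSchemaError",
    "LoadReport",
    "read_claims",
    "write_claims",
    "claims_to_frame",
    "load_claims_frame",
]

CLAIMS_COLUMNS = [
    "patient_id",
    "dispense_date",
    "molecule",
    "formulation",
    "quantity",
    "sex",
    "year_of_birth",
    "state",
    "concessional",
]


class Formulation(str, Enum):
    ORAL = "oral"
    DEPOT = "depot"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class DrugClass(str, Enum):
    ORAL_TYPICAL = "ORAL_TYPICAL"
    ORAL_ATYPICAL = "ORAL_ATYPICAL"
    TYPICAL_LAT = "TYPICAL_LAT"
    ATYPICAL_LAT = "ATYPICAL_LAT"
    CLOZAPINE = "CLOZAPINE"
    ANTIDEPRESSANT = "ANTIDEPRESSANT"
    LITHIUM = "LITHIUM"
    ANTIEPILEPTIC = "ANTIEPILEPTIC"

    @property
    def is_antipsychotic(self) -> bool:
        return self in ANTIPSYCHOTIC_CLASSES


# Reporting row order; doubles as the deterministic same-day tie-break
# priority when two antipsychotic classes start on the same date.
ANTIPSYCHOTIC_CLASSES: tuple[DrugClass, ...] = (
    DrugClass.ORAL_ATYPICAL,
    DrugClass.TYPICAL_LAT,
    DrugClass.ORAL_TYPICAL,
    DrugClass.ATYPICAL_LAT,
    DrugClass.CLOZAPINE,
)

ADJUNCT_CLASSES: tuple[DrugClass, ...] = (
    DrugClass.ANTIDEPRESSANT,
    DrugClass.LITHIUM,
    DrugClass.ANTIEPILEPTIC,
)

CLASS_PRIORITY: dict[DrugClass, int] = {
    **{c: i for i, c in enumerate(ANTIPSYCHOTIC_CLASSES)},
    **{c: 100 + i for i, c in enumerate(ADJUNCT_CLASSES)},
}


class UnknownDrugError(KeyError):
    """A (molecule, formulation) pair absent from the classification table."""

    def __init__(self, molecule: str, formulation: str):
        super().__init__((molecule, formulation))
        self.molecule = molecule
        self.formulation = formulation

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown drug: ({self.molecule!r}, {self.formulation!r})"


class ClaimsSchemaError(ValueError):
    """The claims file is structurally unusable (missing file/columns)."""


@dataclass(frozen=True)
class DrugClassEntry:
    molecule: str
    formulation: Formulation
    drug_class: DrugClass
    default_days_supply: int

    def __post_init__(self) -> None:
        if self.default_days_supply < 1:
            raise ValueError("default_days_supply must be >= 1")


@dataclass(frozen=True)
class ClaimRecord:
    """One dispensing event with demographics and resolved analysis class."""

    patient_id: str
    dispense_date: date
    molecule: str
    formulation: Formulation
    quantity: int
    sex: Sex
    year_of_birth: int
    state: str
    concessional: bool
    drug_class: DrugClass
    days_supply: int


class ClassificationTable:
    """Lookup from (molecule, formulation) to analysis class and days supply.

    Case-insensitive on molecule.  Duplicate pairs are rejected at load time.
    """

    def __init__(self, entries: Iterable[DrugClassEntry]):
        self._entries: dict[tuple[str, Formulation], DrugClassEntry] = {}
        for e in entries:
            key = (e.molecule.lower(), e.formulation)
            if key in self._entries:
                raise ValueError(f"duplicate classification entry: {key}")
            self._entries[key] = e

    @classmethod
    def default(cls) -> "ClassificationTable":
        """The packaged class table (five antipsychotic classes + adjuncts)."""
        with resources.files("rxlines.data").joinpath("drug_classes.csv").open(
            "r", encoding="utf-8"
        ) as fh:
            return cls._from_reader(csv.DictReader(fh))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassificationTable":
        path = Path(path)
        if not path.exists():
            raise ClaimsSchemaError(f"classification file not found: {path}")
        with path.open("r", encoding="utf-8", newline="") as fh:
            return cls._from_reader(csv.DictReader(fh))

    @classmethod
    def _from_reader(cls, reader: csv.DictReader) -> "ClassificationTable":
        required = {"molecule", "formulation", "drug_class", "default_days_supply"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ClaimsSchemaError(
                f"classification CSV must have columns {sorted(required)}"
            )
        entries = [
            DrugClassEntry(
                molecule=row["molecule"].strip().lower(),
                formulation=Formulation(row["formulation"].strip().lower()),
                drug_class=DrugClass(row["drug_class"].strip()),
                default_days_supply=int(row["default_days_supply"]),
            )
            for row in reader
        ]
        return cls(entries)

    def classify(self, molecule: str, formulation: Formulation | str) -> DrugClass:
        return self.entry(molecule, formulation).drug_class

    def days_supply(self, molecule: str, formulation: Formulation | str) -> int:
        return self.entry(molecule, formulation).default_days_supply

    def entry(self, molecule: str, formulation: Formulation | str) -> DrugClassEntry:
        form = Formulation(formulation)
        try:
            return self._entries[(molecule.lower(), form)]
        except KeyError:
            raise UnknownDrugError(molecule, form.value) from None

    def molecules(self, drug_class: DrugClass) -> list[str]:
        return sorted(
            e.molecule for e in self._entries.values() if e.drug_class == drug_class
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())


def classify_drug(
    molecule: str, formulation: Formulation | str, classification: ClassificationTable
) -> DrugClass:
    """Resolve one (molecule, formulation) pair to its analysis class."""
    return classification.classify(molecule, formulation)


@dataclass
class LoadReport:
    n_accepted: int = 0
    n_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)  # (line no, why)

    def reject(self, line_no: int, reason: str) -> None:
        self.n_rejected += 1
        self.rejections.append((line_no, reason))


_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


def _parse_bool(raw: str) -> bool:
    s = raw.strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _parse_row(row: dict[str, str], classification: ClassificationTable) -> ClaimRecord:
    d = date.fromisoformat(row["dispense_date"].strip())
    quantity = int(row["quantity"])
    if quantity < 1:
        raise ValueError(f"quantity must be >= 1, got {quantity}")
    molecule = row["molecule"].strip().lower()
    formulation = Formulation(row["formulation"].strip().lower())
    entry = classification.entry(molecule, formulation)
    return ClaimRecord(
        patient_id=row["patient_id"].strip(),
        dispense_date=d,
        molecule=molecule,
        formulation=formulation,
        quantity=quantity,
        sex=Sex(row["sex"].strip().lower()),
        year_of_birth=int(row["year_of_birth"]),
        state=row["state"].strip(),
        concessional=_parse_bool(row["concessional"]),
        drug_class=entry.drug_class,
        days_supply=entry.default_days_supply,
    )


def read_claims(
    path: str | Path, classification: ClassificationTable
) -> tuple[list[ClaimRecord], LoadReport]:
    """Read a claims CSV, resolving drug classes row by row.

    Malformed rows (bad date, quantity < 1, unknown drug, bad enum) are
    rejected individually and reported with their 1-based line number; a
    missing file or header column aborts with :class:`ClaimsSchemaError`.
    Accepted records are returned sorted by (patient_id, dispense_date).
    """
    path = Path(path)
    if not path.exists():
        raise ClaimsSchemaError(f"claims file not found: {path}")
    report = LoadReport()
    records: list[ClaimRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(CLAIMS_COLUMNS) - set(reader.fieldnames):
            missing = set(CLAIMS_COLUMNS) - set(reader.fieldnames or [])
            raise ClaimsSchemaError(f"claims CSV missing columns: {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, classification))
            except UnknownDrugError as exc:
                report.reject(line_no, f"unknown drug {exc.molecule}/{exc.formulation}")
            except (ValueError, KeyError) as exc:
                report.reject(line_no, str(exc))
    records.sort(key=lambda r: (r.patient_id, r.dispense_date))
    report.n_accepted = len(records)
    return records, report


def write_claims(records: Sequence[ClaimRecord], path: str | Path) -> None:
    """Write records back to the interchange CSV (ISO dates, lowercase bools)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLAIMS_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.dispense_date.isoformat(),
                    r.molecule,
                    r.formulation.value,
                    r.quantity,
                    r.sex.value,
                    r.year_of_birth,
                    r.state,
                    "true" if r.concessional else "false",
                ]
            )


def claims_to_frame(records: Sequence[ClaimRecord]) -> pd.DataFrame:
    """Tabular view of classified claims used by every downstream module."""
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "dispense_date": [r.dispense_date for r in records],
            "molecule": [r.molecule for r in records],
            "formulation": [r.formulation.value for r in records],
            "quantity": [r.quantity for r in records],
            "sex": [r.sex.value for r in records],
            "year_of_birth": [r.year_of_birth for r in records],
            "state": [r.state for r in records],
            "concessional": [r.concessional for r in records],
            "drug_class": [r.drug_class for r in records],
            "days_supply": [r.days_supply for r in records],
        }
    )
    frame["is_antipsychotic"] = [r.drug_class.is_antipsychotic for r in records]
    return frame


def classify_frame(
    raw: pd.DataFrame, classification: ClassificationTable | None = None
) -> pd.DataFrame:
    """Attach drug_class / days_supply to an in-memory raw claims frame.

    ``raw`` must already use schema types (``dispense_date`` as dates,
    integer quantity).  Unknown drugs raise; for per-row rejection use
    :func:`read_claims` on a file instead.
    """
    classification = classification or ClassificationTable.default()
    entries = [
        classification.entry(m, f)
        for m, f in zip(raw["molecule"], raw["formulation"])
    ]
    frame = raw.copy()
    if frame["concessional"].dtype == object:
        frame["concessional"] = [
            _parse_bool(v) if isinstance(v, str) else bool(v)
            for v in frame["concessional"]
        ]
    frame["drug_class"] = [e.drug_class for e in entries]
    frame["days_supply"] = [e.default_days_supply for e in entries]
    frame["is_antipsychotic"] = [e.drug_class.is_antipsychotic for e in entries]
    return frame


def load_claims_frame(
    path: str | Path, classification: ClassificationTable | None = None
) -> tuple[pd.DataFrame, LoadReport]:
    """Convenience: read a claims CSV straight into the analysis frame."""
    classification = classification or ClassificationTable.default()
    records, report = read_claims(path, classification)
    return claims_to_frame(records), report
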