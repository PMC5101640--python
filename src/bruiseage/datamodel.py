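"""Typed records and CSV I/O for semi-quantitative bruise histology.

Each bruise is scored in three tissue layers (dermis, subcutis, muscle).
Hemorrhage, hyper-leukocytosis and (in the dermis) leukocyte infiltration are
recorded as present/absent; neutrophil and macrophage infiltration in the
subcutis and muscle are ordinal 0-3 scores counted in the densest 40x field
(0 = absent, 1 = 1-10 cells, 2 = 11-30 cells, 3 = >30 cells); muscle-fiber
necrosis is an ordinal 0-3 area score (0 = none, 1 = <12.5 %, 2 = 12.5-50 %,
3 = >50 %); and the predominant localization of muscle leukocytes is
interstitial or intramuscular (not applicable when no muscle leukocytes
were seen).

Booleans are serialized as the strings ``present``/``absent`` so they cannot
be confused with the ordinal scores.  The CSV dialect is fixed: comma
separator, UTF-8, header row with the exact column names in
:data:`CSV_COLUMNS`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, fields
from typing import IO, Iterable, Sequence

__all__ = [
    "CellScore",
    "NecrosisScore",
    "LeukocyteLocalization",
    "BruiseHistology",
    "PigRecord",
    "SchemaError",
    "ValidationError",
    "DuplicateError",
    "read_bruise_table",
    "write_bruise_table",
    "records_to_dataframe",
    "CSV_COLUMNS",
]

VALID_SCORES = (0, 1, 2, 3)


class SchemaError(ValueError):
    """CSV header does not match the documented schema."""


class ValidationError(ValueError):
    """A cell value violates the scoring scheme."""


class DuplicateError(ValueError):
    """Two rows share the same (pig_id, bruise_label)."""


def _check_score(value: int, name: str) -> int:
    if not isinstance(value, int) or isinstance(value, bool) or value not in VALID_SCORES:
        raise ValidationError(f"{name} must be an integer in {{0, 1, 2, 3}}, got {value!r}")
    return value


class CellScore(int):
    """Ordinal 0-3 leukocyte count score (densest 40x field).

    0 = absent, 1 = 1-10 cells, 2 = 11-30 cells, 3 = >30 cells.
    """

    def __new__(cls, value: int) -> "CellScore":
        _check_score(value, "cell score")
        return super().__new__(cls, value)


class NecrosisScore(int):
    """Ordinal 0-3 necrotic muscle-fiber area score.

    0 = none, 1 = <12.5 %, 2 = 12.5-50 %, 3 = >50 % of the fiber area.
    """

    def __new__(cls, value: int) -> "NecrosisScore":
        _check_score(value, "necrosis score")
        return super().__new__(cls, value)


class LeukocyteLocalization(enum.Enum):
    """Predominant (>50 %) localization of leukocytes in muscle tissue."""

    INTERSTITIAL = "interstitial"
    INTRAMUSCULAR = "intramuscular"
    NOT_APPLICABLE = "not_applicable"


# boolean fields in serialization order
_BOOL_FIELDS = (
    "dermis_hemorrhage",
    "dermis_hyperleukocytosis",
    "dermis_leukocytes",
    "subcutis_hemorrhage",
    "subcutis_hyperleukocytosis",
    "muscle_hemorrhage",
    "muscle_hyperleukocytosis",
)
_CELL_FIELDS = (
    "subcutis_neutrophils",
    "subcutis_macrophages",
    "muscle_neutrophils",
    "muscle_macrophages",
)

CSV_COLUMNS = (
    "pig_id",
    "bruise_label",
    "dermis_hemorrhage",
    "dermis_hyperleukocytosis",
    "dermis_leukocytes",
    "subcutis_hemorrhage",
    "subcutis_hyperleukocytosis",
    "subcutis_neutrophils",
    "subcutis_macrophages",
    "muscle_hemorrhage",
    "muscle_hyperleukocytosis",
    "muscle_necrosis",
    "muscle_neutrophils",
    "muscle_macrophages",
    "muscle_leukocyte_localization",
    "gross_pattern",
)


@dataclass(frozen=True)
class BruiseHistology:
    """Full histological score vector for one bruise."""

    pig_id: str
    bruise_label: str
    dermis_hemorrhage: bool
    dermis_hyperleukocytosis: bool
    dermis_leukocytes: bool
    subcutis_hemorrhage: bool
    subcutis_hyperleukocytosis: bool
    subcutis_neutrophils: CellScore
    subcutis_macrophages: CellScore
    muscle_hemorrhage: bool
    muscle_hyperleukocytosis: bool
    muscle_necrosis: NecrosisScore
    muscle_neutrophils: CellScore
    muscle_macrophages: CellScore
    muscle_leukocyte_localization: LeukocyteLocalization
    gross_pattern: str = ""

    def __post_init__(self) -> None:
        if not self.pig_id:
            raise ValidationError("pig_id must be non-empty")
        if not self.bruise_label:
            raise ValidationError("bruise_label must be non-empty")
        for name in _BOOL_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, bool):
                raise ValidationError(f"{name} must be a bool, got {v!r}")
        for name in _CELL_FIELDS:
            object.__setattr__(self, name, CellScore(getattr(self, name)))
        object.__setattr__(self, "muscle_necrosis", NecrosisScore(self.muscle_necrosis))
        loc = self.muscle_leukocyte_localization
        if not isinstance(loc, LeukocyteLocalization):
            raise ValidationError(
                f"muscle_leukocyte_localization must be a LeukocyteLocalization, got {loc!r}"
            )
        if loc is LeukocyteLocalization.NOT_APPLICABLE:
            if self.muscle_neutrophils != 0 or self.muscle_macrophages != 0:
                raise ValidationError(
                    "muscle_leukocyte_localization may be not_applicable only when "
                    "both muscle cell scores are 0 "
                    f"(got neutrophils={int(self.muscle_neutrophils)}, "
                    f"macrophages={int(self.muscle_macrophages)})"
                )


@dataclass
class PigRecord:
    """One pig and its ordered collection of bruises."""

    pig_id: str
    bruises: list[BruiseHistology] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bruises:
            raise ValidationError(f"pig {self.pig_id!r} has no bruises")
        for b in self.bruises:
            if b.pig_id != self.pig_id:
                raise ValidationError(
                    f"bruise with pig_id {b.pig_id!r} grouped under pig {self.pig_id!r}"
                )
        labels = [b.bruise_label for b in self.bruises]
        if len(set(labels)) != len(labels):
            raise DuplicateError(f"pig {self.pig_id!r} has duplicate bruise labels: {labels}")

    def bruise(self, label: str) -> BruiseHistology:
        for b in self.bruises:
            if b.bruise_label == label:
                return b
        raise KeyError(f"pig {self.pig_id!r} has no bruise labelled {label!r}")

    def has_label(self, label: str) -> bool:
        return any(b.bruise_label == label for b in self.bruises)


def _parse_bool(raw: str, row: int, column: str) -> bool:
    if raw == "present":
        return True
    if raw == "absent":
        return False
    raise ValidationError(
        f"row {row}, column {column!r}: expected 'present' or 'absent', got {raw!r}"
    )


def _parse_score(raw: str, row: int, column: str) -> int:
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}, column {column!r}: expected an integer score, got {raw!r}"
        ) from None
    if value not in VALID_SCORES:
        raise ValidationError(
            f"row {row}, column {column!r}: score {value} outside the valid range {{0..3}}"
        )
    return value


def _row_to_bruise(raw: dict[str, str], row: int) -> BruiseHistology:
    missing = [c for c in CSV_COLUMNS if raw.get(c) in (None,) or (raw.get(c) == "" and c != "gross_pattern")]
    if missing:
        raise ValidationError(f"row {row}: missing value(s) for column(s) {missing}")
    try:
        loc = LeukocyteLocalization(raw["muscle_leukocyte_localization"])
    except ValueError:
        raise ValidationError(
            f"row {row}, column 'muscle_leukocyte_localization': "
            f"{raw['muscle_leukocyte_localization']!r} is not one of "
            f"{[m.value for m in LeukocyteLocalization]}"
        ) from None
    kwargs: dict[str, object] = {
        "pig_id": raw["pig_id"],
        "bruise_label": raw["bruise_label"],
        "muscle_leukocyte_localization": loc,
        "gross_pattern": raw.get("gross_pattern", "") or "",
    }
    for name in _BOOL_FIELDS:
        kwargs[name] = _parse_bool(raw[name], row, name)
    for name in _CELL_FIELDS + ("muscle_necrosis",):
        kwargs[name] = _parse_score(raw[name], row, name)
    try:
        return BruiseHistology(**kwargs)  # type: ignore[arg-type]
    except ValidationError as exc:
        raise ValidationError(f"row {row}: {exc}") from None


def read_bruise_table(source: IO[str]) -> list[PigRecord]:
    """Read a bruise-histology CSV into validated :class:`PigRecord` objects.

    Rows are grouped by ``pig_id`` preserving the order of first appearance.
    Raises :class:`SchemaError` for a bad header, :class:`ValidationError`
    for any out-of-range cell (naming the row and column), and
    :class:`DuplicateError` for repeated ``(pig_id, bruise_label)`` pairs.
    """
    reader = csv.DictReader(source)
    header = reader.fieldnames
    if header is None:
        raise SchemaError("empty input: no header row")
    missing = [c for c in CSV_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"header is missing required column(s): {missing}")
    extra = [c for c in header if c not in CSV_COLUMNS]
    if extra:
        raise SchemaError(f"header has unknown column(s): {extra}")

    seen: set[tuple[str, str]] = set()
    grouped: dict[str, list[BruiseHistology]] = {}
    for i, raw in enumerate(reader, start=2):  # row 1 is the header
        bruise = _row_to_bruise(raw, i)
        key = (bruise.pig_id, bruise.bruise_label)
        if key in seen:
            raise DuplicateError(f"row {i}: duplicate (pig_id, bruise_label) = {key}")
        seen.add(key)
        grouped.setdefault(bruise.pig_id, []).append(bruise)
    return [PigRecord(pig_id=pid, bruises=bruises) for pid, bruises in grouped.items()]


def _bruise_to_row(b: BruiseHistology) -> list[str]:
    row = []
    for col in CSV_COLUMNS:
        v = getattr(b, col)
        if col in _BOOL_FIELDS:
            row.append("present" if v else "absent")
        elif isinstance(v, LeukocyteLocalization):
            row.append(v.value)
        elif isinstance(v, int):
            row.append(str(int(v)))
        else:
            row.append(str(v))
    return row


def write_bruise_table(records: Iterable[PigRecord], sink: IO[str]) -> int:
    """Write records to CSV (header always included); returns rows written."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    n = 0
    for rec in records:
        for b in rec.bruises:
            writer.writerow(_bruise_to_row(b))
            n += 1
    return n


def records_to_dataframe(records: Iterable[PigRecord]):
    """Flatten records into a pandas DataFrame, one row per bruise."""
    import pandas as pd

    rows = []
    for rec in records:
        for b in rec.bruises:
            row = {}
            for f in fields(b):
                v = getattr(b, f.name)
                if isinstance(v, LeukocyteLocalization):
                    v = v.value
                elif isinstance(v, bool):
                    pass
                elif isinstance(v, int):
                    v = int(v)
                row[f.name] = v
            rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))
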