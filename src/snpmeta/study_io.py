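"""Reading, validating and serving per-study genotype count tables.

A study table holds one row per case-control cohort of a biallelic SNP
association study: the six genotype counts (TT/TC/CC in cases and in
controls) plus the metadata the downstream analyses stratify on
(ethnicity, source of controls, and any extra grouping labels).

The packaged fixture ``glaucoma_rs1063192.tsv`` contains the 16 published
cohorts (14 studies; two studies each contribute two independent cohorts)
on the CDKN2B rs1063192 variant and glaucoma risk: 11,316 cases and
24,055 controls in total.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "StudyRecord",
    "StudyTable",
    "StudyTableError",
    "read_study_table",
    "write_study_table",
    "load_fixture",
    "table_totals",
    "ETHNICITIES",
    "SOC_CATEGORIES",
    "MANDATORY_COLUMNS",
]

#: Closed vocabulary for the ethnicity label.
ETHNICITIES = ("Caucasian", "Asian", "African", "other")

#: Closed vocabulary for the source-of-controls label:
#: hospital-based (HB) or population-based (PB) recruitment.
SOC_CATEGORIES = ("HB", "PB")

#: Column names every input file must carry, in canonical order.
MANDATORY_COLUMNS = (
    "study_id",
    "year",
    "ethnicity",
    "soc",
    "case_tt",
    "case_tc",
    "case_cc",
    "ctrl_tt",
    "ctrl_tc",
    "ctrl_cc",
)

#: Optional columns recognised by name; anything else becomes an extra
#: grouping label.
OPTIONAL_COLUMNS = ("genotyping_method", "hwe_reported")

_COUNT_FIELDS = ("case_tt", "case_tc", "case_cc", "ctrl_tt", "ctrl_tc", "ctrl_cc")


class StudyTableError(ValueError):
    """Raised on malformed input files or invalid study records."""


@dataclass(frozen=True)
class StudyRecord:
    """One cohort's genotype counts and metadata.

    Counts are for the three genotypes of a biallelic SNP whose effect
    allele is C: TT, TC and CC, separately in cases and controls.
    """

    study_id: str
    year: int
    ethnicity: str
    soc: str
    case_tt: int
    case_tc: int
    case_cc: int
    ctrl_tt: int
    ctrl_tc: int
    ctrl_cc: int
    genotyping_method: str | None = None
    hwe_flag_reported: str | None = None
    extra_groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise StudyTableError(
                    f"study {self.study_id!r}: field {name} must be an integer, "
                    f"got {value!r}"
                )
            if value < 0:
                raise StudyTableError(
                    f"study {self.study_id!r}: field {name} is negative ({value})"
                )
        if self.n_cases < 1:
            raise StudyTableError(f"study {self.study_id!r}: no cases")
        if self.n_controls < 1:
            raise StudyTableError(f"study {self.study_id!r}: no controls")
        if self.ethnicity not in ETHNICITIES:
            raise StudyTableError(
                f"study {self.study_id!r}: unknown ethnicity {self.ethnicity!r} "
                f"(expected one of {ETHNICITIES})"
            )
        if self.soc not in SOC_CATEGORIES:
            raise StudyTableError(
                f"study {self.study_id!r}: unknown source-of-controls "
                f"{self.soc!r} (expected one of {SOC_CATEGORIES})"
            )
        object.__setattr__(
            self, "extra_groups", MappingProxyType(dict(self.extra_groups))
        )

    @property
    def n_cases(self) -> int:
        return self.case_tt + self.case_tc + self.case_cc

    @property
    def n_controls(self) -> int:
        return self.ctrl_tt + self.ctrl_tc + self.ctrl_cc

    def label(self, name: str) -> str:
        """Return the value of a grouping label (built-in or extra)."""
        if name == "ethnicity":
            return self.ethnicity
        if name == "soc":
            return self.soc
        try:
            return self.extra_groups[name]
        except KeyError:
            raise KeyError(
                f"study {self.study_id!r} carries no label {name!r}"
            ) from None


@dataclass(frozen=True)
class StudyTable:
    """An ordered collection of study cohorts.

    ``study_id`` values need not be unique (a publication may contribute
    several independent cohorts); identity is (study_id, row index).
    """

    records: tuple[StudyRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, index: int) -> StudyRecord:
        return self.records[index]

    def filter(self, label: str, category: str) -> "StudyTable":
        """Sub-table of rows whose grouping label equals ``category``."""
        kept = tuple(r for r in self.records if r.label(label) == category)
        return StudyTable(kept, provenance=f"{self.provenance} [{label}={category}]")

    def drop_row(self, index: int) -> "StudyTable":
        """Sub-table with row ``index`` removed (leave-one-out support)."""
        kept = self.records[:index] + self.records[index + 1 :]
        return StudyTable(kept, provenance=f"{self.provenance} [-row {index}]")

    def categories(self, label: str) -> tuple[str, ...]:
        """Distinct values of a label, in order of first appearance."""
        seen: dict[str, None] = {}
        for record in self.records:
            seen.setdefault(record.label(label), None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: mandatory, optional, then extra-label columns."""
        rows = []
        for record in self.records:
            row = {name: getattr(record, name) for name in MANDATORY_COLUMNS}
            if record.genotyping_method is not None:
                row["genotyping_method"] = record.genotyping_method
            if record.hwe_flag_reported is not None:
                row["hwe_reported"] = record.hwe_flag_reported
            row.update(record.extra_groups)
            rows.append(row)
        return pd.DataFrame(rows)


def _dialect_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise StudyTableError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    return "\t" if dialect == "tsv" else ","


def read_study_table(path: str | Path, dialect: str | None = None) -> StudyTable:
    """Read and validate a study table from a delimited text file.

    Parameters
    ----------
    path
        TSV or CSV file with a header row naming at least the mandatory
        columns (:data:`MANDATORY_COLUMNS`). Unknown columns are kept as
        extra grouping labels on each record.
    dialect
        ``"tsv"`` or ``"csv"``; inferred from the file extension when
        omitted.

    Raises
    ------
    StudyTableError
        If a mandatory column is missing, or a count is negative or not
        an integer (the error names the offending row and field).
    """
    sep = _dialect_sep(path, dialect)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise StudyTableError(f"missing mandatory column(s): {', '.join(missing)}")
    extra_cols = [
        c
        for c in frame.columns
        if c not in MANDATORY_COLUMNS and c not in OPTIONAL_COLUMNS
    ]

    records = []
    for i, raw in enumerate(frame.to_dict(orient="records"), start=1):
        counts = {}
        for name in _COUNT_FIELDS:
            text = str(raw[name]).strip()
            try:
                value = int(text)
            except ValueError:
                raise StudyTableError(
                    f"row {i}, field {name}: {text!r} is not an integer"
                ) from None
            if value < 0:
                raise StudyTableError(f"row {i}, field {name}: negative count {value}")
            counts[name] = value
        try:
            year = int(str(raw["year"]).strip())
        except ValueError:
            raise StudyTableError(
                f"row {i}, field year: {raw['year']!r} is not an integer"
            ) from None
        try:
            record = StudyRecord(
                study_id=str(raw["study_id"]).strip(),
                year=year,
                ethnicity=str(raw["ethnicity"]).strip(),
                soc=str(raw["soc"]).strip(),
                genotyping_method=(
                    str(raw["genotyping_method"]).strip()
                    if "genotyping_method" in raw
                    else None
                ),
                hwe_flag_reported=(
                    str(raw["hwe_reported"]).strip() if "hwe_reported" in raw else None
                ),
                extra_groups={c: str(raw[c]).strip() for c in extra_cols},
                **counts,
            )
        except StudyTableError as err:
            raise StudyTableError(f"row {i}: {err}") from None
        records.append(record)
    return StudyTable(tuple(records), provenance=str(path))


def write_study_table(
    table: StudyTable, path: str | Path, dialect: str | None = None
) -> None:
    """Write a study table back to TSV/CSV; round-trips with the reader."""
    sep = _dialect_sep(path, dialect)
    table.to_frame().to_csv(path, sep=sep, index=False)


def load_fixture() -> StudyTable:
    """Load the packaged 16-cohort glaucoma rs1063192 genotype table."""
    source = resources.files("snpmeta.data").joinpath("glaucoma_rs1063192.tsv")
    with resources.as_file(source) as path:
        table = read_study_table(path, dialect="tsv")
    return StudyTable(table.records, provenance="packaged glaucoma rs1063192 fixture")


def table_totals(table: StudyTable) -> tuple[int, int, int]:
    """Total cases, total controls and number of rows of a table."""
    cases = sum(r.n_cases for r in table)
    controls = sum(r.n_controls for r in table)
    return cases, controls, len(table)
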