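"""Reading, writing and validating specimen and fossil measurement tables.

Tables are plain CSV (RFC 4180) or XLSX.  The extant table has one row per
measured claw::

    taxon, specimen_id, pes, category, body_mass_g, IU, OU, IS, IS2, OS

``pes`` is ``left``/``right``/``unknown``; ``category`` is one of the four
behavioural groups (aliases such as "climbing" for scansorial and
"ground-dwelling" for terrestrial are accepted).  The fossil table is the
same minus ``category`` and ``body_mass_g``; sheath angles are optional but
IS2 and OS must be jointly present or jointly absent.  Angle columns are in
degrees, body mass in grams.  Left and right claws of one specimen are
separate rows — they are treated as independent observations.

Malformed rows are never silently dropped: readers return a
:class:`ValidationReport` listing every rejected row and why.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .geometry import ClawMeasures, Metric

__all__ = [
    "Category",
    "Pes",
    "SpecimenRecord",
    "FossilRecord",
    "Dataset",
    "ValidationReport",
    "SchemaError",
    "read_extant_table",
    "read_fossil_table",
    "write_extant_table",
    "write_fossil_table",
    "write_results",
    "MASS_RANGE_G",
    "ANGLE_COLUMNS",
]

ANGLE_COLUMNS = ("IU", "OU", "IS", "IS2", "OS")

#: Body-mass envelope of the reference extant sample (grams).  Masses outside
#: it are flagged as warnings, not rejected.
MASS_RANGE_G = (36.0, 1930.0)


class Category(str, Enum):
    """Behavioural category of an extant specimen."""

    TERRESTRIAL = "terrestrial"
    PERCHING = "perching"
    PREDATORY = "predatory"
    SCANSORIAL = "scansorial"


_CATEGORY_ALIASES = {
    "terrestrial": Category.TERRESTRIAL,
    "ground-dwelling": Category.TERRESTRIAL,
    "ground dwelling": Category.TERRESTRIAL,
    "grnd": Category.TERRESTRIAL,
    "perching": Category.PERCHING,
    "prch": Category.PERCHING,
    "predatory": Category.PREDATORY,
    "raptorial": Category.PREDATORY,
    "pred": Category.PREDATORY,
    "scansorial": Category.SCANSORIAL,
    "climbing": Category.SCANSORIAL,
    "clmb": Category.SCANSORIAL,
}


def parse_category(value: str) -> Category:
    key = str(value).strip().lower()
    if key not in _CATEGORY_ALIASES:
        raise ValueError(f"unknown behavioural category {value!r}")
    return _CATEGORY_ALIASES[key]


class Pes(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


_PES_ALIASES = {
    "left": Pes.LEFT, "l": Pes.LEFT,
    "right": Pes.RIGHT, "r": Pes.RIGHT,
    "unknown": Pes.UNKNOWN, "?": Pes.UNKNOWN, "": Pes.UNKNOWN, "nan": Pes.UNKNOWN,
}


def parse_pes(value: object) -> Pes:
    key = str(value).strip().lower()
    if key not in _PES_ALIASES:
        raise ValueError(f"unknown pes side {value!r}")
    return _PES_ALIASES[key]


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


@dataclass
class SpecimenRecord:
    """One measured extant claw (pedal digit III) with behavioural label."""

    taxon: str
    specimen_id: str
    pes: Pes
    category: Category
    body_mass_g: float
    measures: ClawMeasures

    def __post_init__(self) -> None:
        if not (self.body_mass_g > 0) or not math.isfinite(self.body_mass_g):
            raise ValueError(f"body mass must be positive, got {self.body_mass_g}")


@dataclass
class FossilRecord:
    """One measured fossil claw; behavioural category unknown, mass unknown."""

    taxon: str
    specimen_id: str
    pes: Pes
    measures: ClawMeasures

    def __post_init__(self) -> None:
        m = self.measures
        if m.IU is None or m.OU is None:
            raise ValueError("fossil records need both ungual angles IU and OU")
        if (m.IS2 is None) != (m.OS is None):
            raise ValueError("sheath angles IS2 and OS must be jointly present or absent")

    @property
    def has_sheath(self) -> bool:
        return self.measures.IS2 is not None and self.measures.OS is not None


@dataclass
class ValidationReport:
    """Per-row validation outcome; accepted + rejected = input rows."""

    n_input: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)
    warnings: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def summary(self) -> str:
        lines = [f"{self.n_accepted}/{self.n_input} rows accepted"]
        lines += [f"  row {i}: REJECTED: {r}" for i, r in self.rejected]
        lines += [f"  row {i}: warning: {w}" for i, w in self.warnings]
        return "\n".join(lines)


@dataclass
class Dataset:
    """A validated collection of extant specimen records."""

    records: list[SpecimenRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def categories(self) -> list[Category]:
        seen: list[Category] = []
        for r in self.records:
            if r.category not in seen:
                seen.append(r.category)
        return seen

    def subset_complete(self, metrics: Sequence[Union[Metric, str]]) -> "Dataset":
        """Records having every listed metric measured."""
        keep = [r for r in self.records if r.measures.has_all(metrics)]
        return Dataset(keep, provenance=self.provenance)

    def check_fittable(self) -> None:
        counts: dict[Category, int] = {}
        for r in self.records:
            counts[r.category] = counts.get(r.category, 0) + 1
        if sum(1 for n in counts.values() if n >= 2) < 2:
            raise ValueError(
                "model fitting needs at least 2 categories with at least 2 records each"
            )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "taxon": r.taxon,
                "specimen_id": r.specimen_id,
                "pes": r.pes.value,
                "category": r.category.value,
                "body_mass_g": r.body_mass_g,
            }
            row.update(r.measures.as_dict())
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["taxon", "specimen_id", "pes", "category", "body_mass_g", *ANGLE_COLUMNS],
        )


_EXTANT_REQUIRED = ["taxon", "specimen_id", "pes", "category", "body_mass_g"]
_FOSSIL_REQUIRED = ["taxon", "specimen_id", "pes", "IU", "OU"]


def _read_table(path: Union[str, Path], fmt: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        return pd.read_excel(path)
    return pd.read_csv(path)


def _parse_angles(row: pd.Series) -> dict[str, float]:
    vals: dict[str, float] = {}
    for col in ANGLE_COLUMNS:
        if col in row.index and pd.notna(row[col]) and str(row[col]).strip() != "":
            v = float(row[col])
            vals[col] = v
    return vals


def read_extant_table(
    path: Union[str, Path], fmt: Optional[str] = None
) -> tuple[Dataset, ValidationReport]:
    """Read an extant specimen table; returns (dataset, validation report)."""
    df = _read_table(path, fmt)
    missing = [c for c in _EXTANT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    report = ValidationReport(n_input=len(df))
    records: list[SpecimenRecord] = []
    for i, row in df.iterrows():
        try:
            mass = float(row["body_mass_g"])
            rec = SpecimenRecord(
                taxon=str(row["taxon"]),
                specimen_id=str(row["specimen_id"]),
                pes=parse_pes(row["pes"]),
                category=parse_category(row["category"]),
                body_mass_g=mass,
                measures=ClawMeasures(**_parse_angles(row)),
            )
        except (ValueError, TypeError) as err:
            report.rejected.append((int(i), str(err)))
            continue
        if not (MASS_RANGE_G[0] <= mass <= MASS_RANGE_G[1]):
            report.warnings.append(
                (int(i), f"body mass {mass} g outside reference range {MASS_RANGE_G}")
            )
        records.append(rec)
    report.n_accepted = len(records)
    return Dataset(records, provenance=str(path)), report


def read_fossil_table(
    path: Union[str, Path], fmt: Optional[str] = None
) -> tuple[list[FossilRecord], ValidationReport]:
    """Read a fossil claw table; returns (records, validation report)."""
    df = _read_table(path, fmt)
    missing = [c for c in _FOSSIL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    report = ValidationReport(n_input=len(df))
    records: list[FossilRecord] = []
    for i, row in df.iterrows():
        try:
            rec = FossilRecord(
                taxon=str(row["taxon"]),
                specimen_id=str(row["specimen_id"]),
                pes=parse_pes(row["pes"]),
                measures=ClawMeasures(**_parse_angles(row)),
            )
        except (ValueError, TypeError) as err:
            report.rejected.append((int(i), str(err)))
            continue
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


def write_extant_table(dataset: Dataset, path: Union[str, Path]) -> None:
    write_results(dataset.to_dataframe(), path)


def fossils_to_dataframe(fossils: Iterable[FossilRecord]) -> pd.DataFrame:
    rows = []
    for r in fossils:
        row = {"taxon": r.taxon, "specimen_id": r.specimen_id, "pes": r.pes.value}
        row.update(r.measures.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["taxon", "specimen_id", "pes", *ANGLE_COLUMNS])


def write_fossil_table(fossils: Iterable[FossilRecord], path: Union[str, Path]) -> None:
    write_results(fossils_to_dataframe(fossils), path)


def write_results(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a tidy results table as CSV: fixed column order, floats at 6
    significant digits, blanks for absent values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        table.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")
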