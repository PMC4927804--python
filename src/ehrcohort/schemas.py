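"""Common-data-model table schemas, typed records, readers/writers and code matching.

Every downstream stage (cohort construction, phenotyping, SES estimation,
reporting) consumes the tables defined here.  Tables travel as pandas
DataFrames with the column names fixed by :data:`SCHEMAS`; on-disk format is
UTF-8 CSV with a header row.  Vital-sign values are canonicalised at
ingestion to metres / kilograms / kg·m⁻²; imperial units present in a source
file are converted on read with exact factors (1 in = 0.0254 m,
1 lb = 0.45359237 kg).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "IN_TO_M",
    "LB_TO_KG",
    "FT_TO_M",
    "Column",
    "TableSchema",
    "SCHEMAS",
    "TableSet",
    "SchemaError",
    "RowError",
    "RowValidationError",
    "read_table",
    "write_table",
    "code_matches",
    "match_mask",
    "PersonRecord",
    "EnrollmentSpan",
    "VitalRecord",
    "LabRecord",
    "EncounterDiagnosis",
    "ProcedureRecord",
    "DispenseRecord",
    "PregnancyFlag",
    "GeocodeAssignment",
]

# exact conversion factors (international inch / avoirdupois pound)
IN_TO_M = 0.0254
FT_TO_M = 0.3048
CM_TO_M = 0.01
LB_TO_KG = 0.45359237

SEXES = frozenset({"female", "male", "unknown"})
RACE_ETHNICITIES = frozenset(
    {
        "white",
        "hispanic",
        "asian",
        "black",
        "native_hawaiian_pacific_islander",
        "american_indian_alaskan_native",
        "other_unknown",
    }
)
INSURANCES = frozenset({"private", "medicare", "medicaid_state_subsidized", "other_unknown"})
VITAL_KINDS = frozenset({"height", "weight", "bmi"})
LAB_TESTS = frozenset({"hba1c", "fasting_glucose", "random_glucose", "ogtt_2h"})
DX_SETTINGS = frozenset({"inpatient", "outpatient"})
CODE_SYSTEMS = frozenset({"cpt4", "icd9_proc", "hcpcs"})
ENCOUNTER_TYPES = frozenset({"primary_care", "other"})
SES_DOMAINS = frozenset({"education", "income"})

#: unit labels accepted in the optional ``unit`` column of the vitals table,
#: mapped to multiplicative factors into canonical units, per vital kind.
UNIT_FACTORS: Mapping[str, Mapping[str, float]] = {
    "height": {"m": 1.0, "cm": CM_TO_M, "in": IN_TO_M, "inches": IN_TO_M, "ft": FT_TO_M},
    "weight": {"kg": 1.0, "lb": LB_TO_KG, "lbs": LB_TO_KG},
    "bmi": {"kg/m2": 1.0},
}


# ---------------------------------------------------------------------------
# typed records


@dataclass(frozen=True, slots=True)
class PersonRecord:
    person_id: str
    birth_date: dt.date
    sex: str
    race_ethnicity: str
    site_id: str
    insurance: str


@dataclass(frozen=True, slots=True)
class EnrollmentSpan:
    person_id: str
    start_date: dt.date
    end_date: dt.date


@dataclass(frozen=True, slots=True)
class VitalRecord:
    person_id: str
    measure_date: dt.date
    kind: str
    value: float
    record_seq: int = 0


@dataclass(frozen=True, slots=True)
class LabRecord:
    person_id: str
    result_date: dt.date
    test: str
    value: float


@dataclass(frozen=True, slots=True)
class EncounterDiagnosis:
    person_id: str
    dx_date: dt.date
    code: str
    setting: str


@dataclass(frozen=True, slots=True)
class ProcedureRecord:
    person_id: str
    px_date: dt.date
    code: str
    code_system: str


@dataclass(frozen=True, slots=True)
class DispenseRecord:
    person_id: str
    dispense_date: dt.date
    drug_class: str


@dataclass(frozen=True, slots=True)
class PregnancyFlag:
    person_id: str
    pregnant_in_window: bool


@dataclass(frozen=True, slots=True)
class GeocodeAssignment:
    person_id: str
    block_group_id: str


# ---------------------------------------------------------------------------
# schema machinery


class SchemaError(ValueError):
    """A table-level defect: missing column, duplicate key, bad probability mass."""


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based physical line in the file (header is line 1)
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}, column {self.column!r}: {self.message}"


class RowValidationError(ValueError):
    def __init__(self, table: str, errors: Sequence[RowError]):
        self.table = table
        self.errors = list(errors)
        head = "; ".join(str(e) for e in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} invalid row(s) in table {table!r}: {head}{more}")


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # 'str' | 'date' | 'float' | 'int' | 'bool'
    allowed: frozenset | None = None
    required: bool = True
    positive: bool = False


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


SCHEMAS: dict[str, TableSchema] = {
    "persons": TableSchema(
        "persons",
        (
            Column("person_id", "str"),
            Column("birth_date", "date"),
            Column("sex", "str", allowed=SEXES),
            Column("race_ethnicity", "str", allowed=RACE_ETHNICITIES),
            Column("site_id", "str"),
            Column("insurance", "str", allowed=INSURANCES),
        ),
    ),
    "enrollment": TableSchema(
        "enrollment",
        (
            Column("person_id", "str"),
            Column("start_date", "date"),
            Column("end_date", "date"),
        ),
    ),
    "vitals": TableSchema(
        "vitals",
        (
            Column("person_id", "str"),
            Column("measure_date", "date"),
            Column("kind", "str", allowed=VITAL_KINDS),
            Column("value", "float", positive=True),
            Column("record_seq", "int"),
        ),
    ),
    "labs": TableSchema(
        "labs",
        (
            Column("person_id", "str"),
            Column("result_date", "date"),
            Column("test", "str", allowed=LAB_TESTS),
            Column("value", "float", positive=True),
        ),
    ),
    "diagnoses": TableSchema(
        "diagnoses",
        (
            Column("person_id", "str"),
            Column("dx_date", "date"),
            Column("code", "str"),
            Column("setting", "str", allowed=DX_SETTINGS),
        ),
    ),
    "procedures": TableSchema(
        "procedures",
        (
            Column("person_id", "str"),
            Column("px_date", "date"),
            Column("code", "str"),
            Column("code_system", "str", allowed=CODE_SYSTEMS),
        ),
    ),
    "dispenses": TableSchema(
        "dispenses",
        (
            Column("person_id", "str"),
            Column("dispense_date", "date"),
            Column("drug_class", "str"),
        ),
    ),
    "encounters": TableSchema(
        "encounters",
        (
            Column("person_id", "str"),
            Column("encounter_date", "date"),
            Column("encounter_type", "str", allowed=ENCOUNTER_TYPES),
        ),
    ),
    "geocodes": TableSchema(
        "geocodes",
        (
            Column("person_id", "str"),
            Column("block_group_id", "str"),
        ),
    ),
    "block_groups": TableSchema(
        "block_groups",
        (
            Column("block_group_id", "str"),
            Column("domain", "str", allowed=SES_DOMAINS),
            Column("level", "str"),
            Column("probability", "float"),
        ),
    ),
    "pregnancy": TableSchema(
        "pregnancy",
        (
            Column("person_id", "str"),
            Column("pregnant_in_window", "bool"),
        ),
    ),
}

PROBABILITY_SUM_TOL = 1e-9


def _parse_column(raw: pd.Series, col: Column, errors: list[RowError]) -> pd.Series:
    """Parse one string column to its typed form, appending row errors."""
    stripped = raw.str.strip()
    blank = stripped == ""
    if col.required:
        for idx in stripped.index[blank]:
            errors.append(RowError(idx + 2, col.name, "required value is blank"))
    if col.kind == "date":
        parsed = pd.to_datetime(stripped, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & ~blank
        for idx in stripped.index[bad]:
            errors.append(RowError(idx + 2, col.name, f"not an ISO date: {stripped[idx]!r}"))
        return parsed
    if col.kind in ("float", "int"):
        parsed = pd.to_numeric(stripped, errors="coerce")
        bad = parsed.isna() & ~blank
        for idx in stripped.index[bad]:
            errors.append(RowError(idx + 2, col.name, f"not numeric: {stripped[idx]!r}"))
        if col.positive:
            neg = parsed <= 0
            for idx in stripped.index[neg & ~parsed.isna()]:
                errors.append(RowError(idx + 2, col.name, f"must be > 0, got {parsed[idx]}"))
        if col.kind == "int":
            frac = (~parsed.isna()) & (parsed != parsed.round())
            for idx in stripped.index[frac]:
                errors.append(RowError(idx + 2, col.name, f"not an integer: {stripped[idx]!r}"))
        return parsed
    if col.kind == "bool":
        lowered = stripped.str.lower()
        ok = lowered.isin(["true", "false", "1", "0", ""])
        for idx in stripped.index[~ok]:
            errors.append(RowError(idx + 2, col.name, f"not a boolean: {stripped[idx]!r}"))
        return lowered.isin(["true", "1"])
    if col.allowed is not None:
        bad = ~stripped.isin(col.allowed) & ~blank
        for idx in stripped.index[bad]:
            errors.append(
                RowError(idx + 2, col.name, f"value {stripped[idx]!r} not in {sorted(col.allowed)}")
            )
    return stripped


def _convert_vital_units(df: pd.DataFrame, unit_raw: pd.Series, errors: list[RowError]) -> None:
    units = unit_raw.str.strip().str.lower()
    for idx in df.index:
        unit = units[idx]
        if unit == "":
            continue
        kind = df.at[idx, "kind"]
        factor = UNIT_FACTORS.get(kind, {}).get(unit)
        if factor is None:
            errors.append(RowError(idx + 2, "unit", f"unknown unit {unit!r} for kind {kind!r}"))
        else:
            df.at[idx, "value"] = df.at[idx, "value"] * factor


def _table_checks(name: str, df: pd.DataFrame) -> None:
    if name == "persons" and df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise SchemaError(f"duplicate person_id {dup!r} in persons table")
    if name == "geocodes" and df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise SchemaError(f"person {dup!r} has more than one geocode assignment")
    if name == "enrollment":
        bad = df["start_date"] > df["end_date"]
        if bad.any():
            raise SchemaError(f"{int(bad.sum())} enrollment span(s) with start_date > end_date")
    if name == "block_groups" and len(df):
        if ((df["probability"] < 0) | (df["probability"] > 1)).any():
            raise SchemaError("block-group probabilities must lie in [0, 1]")
        sums = df.groupby(["block_group_id", "domain"])["probability"].sum()
        off = sums[(sums - 1.0).abs() > PROBABILITY_SUM_TOL]
        if len(off):
            bg, domain = off.index[0]
            raise SchemaError(
                f"probabilities for block group {bg!r} domain {domain!r} sum to {off.iloc[0]!r}, not 1"
            )
    if name == "procedures" and len(df):
        has_dot = df["code"].str.contains(".", regex=False)
        bad = (df["code_system"] == "icd9_proc") != has_dot
        if bad.any():
            i = df.index[bad][0]
            raise SchemaError(
                f"procedure code {df.at[i, 'code']!r} inconsistent with code_system "
                f"{df.at[i, 'code_system']!r} (ICD-9 procedure codes contain a period)"
            )


def read_table(path, schema: TableSchema | str, *, strict: bool = True) -> pd.DataFrame:
    """Read one CSV table, parse and validate it, and return a typed DataFrame.

    Rows violating an invariant are reported with their physical line number;
    with ``strict=True`` (default) any bad row raises :class:`RowValidationError`,
    otherwise bad rows are dropped and the errors attached as ``df.attrs['row_errors']``.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c.name for c in schema.columns if c.name not in raw.columns]
    if missing:
        raise SchemaError(f"table {schema.name!r} is missing required column(s) {missing}")
    raw = raw.reset_index(drop=True)
    errors: list[RowError] = []
    out = pd.DataFrame(index=raw.index)
    for col in schema.columns:
        out[col.name] = _parse_column(raw[col.name], col, errors)
    if schema.name == "vitals" and "unit" in raw.columns:
        _convert_vital_units(out, raw["unit"], errors)
    if errors:
        if strict:
            raise RowValidationError(schema.name, errors)
        bad_lines = {e.line - 2 for e in errors}
        out = out.drop(index=[i for i in bad_lines if i in out.index]).reset_index(drop=True)
    if schema.name == "vitals":
        out["record_seq"] = out["record_seq"].astype("int64")
    _table_checks(schema.name, out)
    out.attrs["row_errors"] = errors
    return out


def write_table(df: pd.DataFrame, path, schema: TableSchema | str) -> None:
    """Write a typed DataFrame back to CSV in canonical units / ISO dates."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        series = df[col.name]
        if col.kind == "date":
            series = pd.to_datetime(series).dt.strftime("%Y-%m-%d")
        out[col.name] = series
    out.to_csv(path, index=False)


@dataclass
class TableSet:
    """The full table bundle produced by the generator and consumed by the pipeline."""

    persons: pd.DataFrame
    enrollment: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    dispenses: pd.DataFrame
    encounters: pd.DataFrame
    geocodes: pd.DataFrame
    block_groups: pd.DataFrame
    pregnancy: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        if self.pregnancy is None:
            out.pop("pregnancy")
        return out

    def write(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            write_table(df, d / f"{name}.csv", SCHEMAS[name])

    @classmethod
    def read(cls, directory, *, strict: bool = True) -> "TableSet":
        import pathlib

        d = pathlib.Path(directory)
        kwargs = {}
        for name in SCHEMAS:
            p = d / f"{name}.csv"
            if p.exists():
                kwargs[name] = read_table(p, SCHEMAS[name], strict=strict)
            elif name != "pregnancy":
                raise SchemaError(f"missing table file {p}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# diagnosis / procedure code matching


def code_matches(code: str, patterns: Iterable[str]) -> bool:
    """True iff ``code`` equals a pattern or extends it at a sub-code boundary.

    ``"401"`` matches ``"401"``, ``"401.9"`` and ``"401.91"`` but not
    ``"4011"``; ``"790.2"`` matches ``"790.21"`` (digits after the decimal
    point are sub-codes).  An empty pattern set is a configuration error, not
    a silent "matches nothing".
    """
    patterns = tuple(patterns)
    if not patterns:
        raise ValueError("empty code pattern set (misconfigured code list?)")
    code = code.strip()
    if not code:
        raise ValueError("empty code")
    for p in patterns:
        if code == p:
            return True
        if "." in p:
            if code.startswith(p):
                return True
        elif code.startswith(p + "."):
            return True
    return False


def match_mask(codes: pd.Series, patterns: Iterable[str]) -> pd.Series:
    """Vectorised :func:`code_matches` over a string Series."""
    patterns = tuple(patterns)
    if not patterns:
        raise ValueError("empty code pattern set (misconfigured code list?)")
    mask = pd.Series(False, index=codes.index)
    for p in patterns:
        if "." in p:
            mask |= codes.str.startswith(p)
        else:
            mask |= (codes == p) | codes.str.startswith(p + ".")
    return mask
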