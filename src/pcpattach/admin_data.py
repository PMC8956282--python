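"""Schemas, readers/writers and integrity checks for the administrative tables.

Six delimited-text tables (comma-separated, UTF-8, header row, ISO-8601
dates) carry the inputs:

* ``claims``   — fee-for-service physician claims (one billed service each),
* ``roster``   — formal patient–provider enrollment intervals,
* ``chc``      — community health centre encounters,
* ``hospital`` — emergency-department visits and admissions,
* ``survey``   — self-reported has-a-PCP answers (the reference standard),
* ``persons``  — the population registry (birth date, sex).

Identifiers are opaque strings and are never parsed. Every input row either
becomes a validated record or a row-indexed diagnostic; nothing is silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CLAIM_SETTINGS = frozenset({"office", "emergency_department", "nursing_home", "other"})
ENCOUNTER_TYPES = frozenset({"ed_visit", "admission"})
SEXES = frozenset({"F", "M"})

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


@dataclass(frozen=True)
class TableSchema:
    """Column layout of one administrative table."""

    name: str
    columns: tuple[str, ...]
    date_columns: tuple[str, ...] = ()
    optional_date_columns: tuple[str, ...] = ()  # empty string means open/absent
    enum_columns: Mapping[str, frozenset] = field(default_factory=dict)
    bool_columns: tuple[str, ...] = ()
    int_columns: tuple[str, ...] = ()
    id_columns: tuple[str, ...] = ()  # must be non-empty strings


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in (
        TableSchema(
            name="claims",
            columns=("patient_id", "provider_id", "service_date", "service_code", "setting"),
            date_columns=("service_date",),
            enum_columns={"setting": CLAIM_SETTINGS},
            id_columns=("patient_id", "provider_id"),
        ),
        TableSchema(
            name="roster",
            columns=("patient_id", "provider_id", "start_date", "end_date"),
            date_columns=("start_date",),
            optional_date_columns=("end_date",),
            id_columns=("patient_id", "provider_id"),
        ),
        TableSchema(
            name="chc",
            columns=("patient_id", "visit_date"),
            date_columns=("visit_date",),
            id_columns=("patient_id",),
        ),
        TableSchema(
            name="hospital",
            columns=("patient_id", "encounter_date", "encounter_type"),
            date_columns=("encounter_date",),
            enum_columns={"encounter_type": ENCOUNTER_TYPES},
            id_columns=("patient_id",),
        ),
        TableSchema(
            name="survey",
            columns=("respondent_id", "survey_date", "has_pcp", "age_years"),
            date_columns=("survey_date",),
            bool_columns=("has_pcp",),
            int_columns=("age_years",),
            id_columns=("respondent_id",),
        ),
        TableSchema(
            name="persons",
            columns=("patient_id", "birth_date", "sex"),
            date_columns=("birth_date",),
            enum_columns={"sex": SEXES},
            id_columns=("patient_id",),
        ),
    )
}


class TableValidationError(ValueError):
    """A table failed schema validation.

    ``problems`` is a list of ``(row, message)`` pairs where ``row`` is the
    1-based data-row index (the header is row 0) or ``None`` for file-level
    problems such as a wrong header.
    """

    def __init__(self, table: str, problems: list[tuple[int | None, str]]):
        self.table = table
        self.problems = problems
        shown = "; ".join(
            (f"row {r}: {m}" if r is not None else m) for r, m in problems[:10]
        )
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"invalid {table} table: {shown}{more}")


def _parse_date(value: str) -> pd.Timestamp:
    ts = pd.to_datetime(value, format="%Y-%m-%d", errors="raise")
    return ts


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate one administrative table.

    Returns a DataFrame with dates as ``datetime64[ns]`` (``NaT`` for an open
    ``end_date``), booleans as ``bool``, counts as ``int64`` and identifiers
    as strings. Raises :class:`TableValidationError` listing every offending
    row (1-based data rows) if any row fails; raises ``FileNotFoundError``
    for a missing file.
    """
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{sch.name} table not found: {path}")

    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    problems: list[tuple[int | None, str]] = []

    got, want = list(raw.columns), list(sch.columns)
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        if missing or extra:
            raise TableValidationError(
                sch.name,
                [(None, f"header mismatch: missing={missing} extra={extra}")],
            )
        raw = raw[want]  # same columns, different order

    out: dict[str, object] = {}
    for col in sch.columns:
        vals = raw[col]
        if col in sch.id_columns:
            bad = vals.str.strip() == ""
            for i in raw.index[bad]:
                problems.append((i + 1, f"empty {col}"))
            out[col] = vals
        elif col in sch.date_columns or col in sch.optional_date_columns:
            optional = col in sch.optional_date_columns
            parsed = pd.to_datetime(vals.replace("", None), format="%Y-%m-%d", errors="coerce")
            bad = parsed.isna() & (vals != "")
            if not optional:
                bad = bad | (vals == "")
            for i in raw.index[bad]:
                problems.append((i + 1, f"unparseable date in {col}: {vals[i]!r}"))
            out[col] = parsed
        elif col in sch.enum_columns:
            allowed = sch.enum_columns[col]
            bad = ~vals.isin(allowed)
            for i in raw.index[bad]:
                problems.append((i + 1, f"invalid {col}: {vals[i]!r} (allowed: {sorted(allowed)})"))
            out[col] = vals
        elif col in sch.bool_columns:
            low = vals.str.lower()
            parsed_b = low.map(lambda v: True if v in _TRUE else (False if v in _FALSE else None))
            bad = parsed_b.isna()
            for i in raw.index[bad]:
                problems.append((i + 1, f"invalid boolean in {col}: {vals[i]!r}"))
            out[col] = parsed_b
        elif col in sch.int_columns:
            parsed_i = pd.to_numeric(vals, errors="coerce")
            bad = parsed_i.isna() | (parsed_i % 1 != 0) | (parsed_i < 0)
            for i in raw.index[bad]:
                problems.append((i + 1, f"invalid non-negative integer in {col}: {vals[i]!r}"))
            out[col] = parsed_i
        else:
            out[col] = vals

    if problems:
        problems.sort(key=lambda p: (p[0] is None, p[0]))
        raise TableValidationError(sch.name, problems)

    df = pd.DataFrame(out, columns=sch.columns)
    if sch.name == "roster" and len(df):
        closed = df["end_date"].notna()
        bad_iv = closed & (df["end_date"] < df["start_date"])
        if bad_iv.any():
            raise TableValidationError(
                sch.name,
                [(i + 1, "end_date before start_date") for i in df.index[bad_iv]],
            )
    for col in sch.bool_columns:
        df[col] = df[col].astype(bool)
    for col in sch.int_columns:
        df[col] = df[col].astype("int64")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | TableSchema) -> None:
    """Write a table in the canonical dialect (ISO dates, lowercase booleans)."""
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    out = df[list(sch.columns)].copy()
    for col in sch.date_columns + sch.optional_date_columns:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out[col] = out[col].fillna("")
    for col in sch.bool_columns:
        out[col] = out[col].map({True: "true", False: "false"})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, encoding="utf-8")


@dataclass
class IntegrityReport:
    """Cross-table referential findings; empty when the bundle is consistent."""

    orphans: dict[str, list[str]] = field(default_factory=dict)
    duplicate_roster: list[dict] = field(default_factory=list)
    overlapping_roster: list[dict] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (any(self.orphans.values()) or self.duplicate_roster or self.overlapping_roster)

    def summary(self) -> str:
        if self.is_empty:
            return "integrity: OK"
        lines = ["integrity: PROBLEMS"]
        for table, ids in sorted(self.orphans.items()):
            if ids:
                lines.append(f"  {table}: {len(ids)} patient id(s) absent from persons (e.g. {ids[:3]})")
        if self.duplicate_roster:
            lines.append(f"  roster: {len(self.duplicate_roster)} duplicate interval(s)")
        if self.overlapping_roster:
            lines.append(f"  roster: {len(self.overlapping_roster)} overlapping interval pair(s)")
        return "\n".join(lines)


def _overlapping_pairs(intervals: pd.DataFrame) -> list[dict]:
    """Sorted-sweep overlap detection within one patient's roster intervals."""
    rows = intervals.sort_values(["start_date", "end_date"], na_position="last")
    recs = rows.to_dict("records")
    found = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            a_end = a["end_date"] if pd.notna(a["end_date"]) else pd.Timestamp.max
            if b["start_date"] <= a_end:
                found.append(
                    {
                        "patient_id": a["patient_id"],
                        "providers": (a["provider_id"], b["provider_id"]),
                        "starts": (a["start_date"], b["start_date"]),
                    }
                )
            else:
                break
    return found


def check_integrity(
    claims: pd.DataFrame,
    roster: pd.DataFrame,
    chc: pd.DataFrame,
    hospital: pd.DataFrame,
    survey: pd.DataFrame,
    persons: pd.DataFrame,
) -> IntegrityReport:
    """Report orphan patient ids and duplicate/overlapping roster intervals.

    Reporting only — never raises. Survey respondents are joined on
    ``respondent_id`` = ``patient_id``.
    """
    known = set(persons["patient_id"])
    report = IntegrityReport()
    event_tables = {
        "claims": claims["patient_id"],
        "roster": roster["patient_id"],
        "chc": chc["patient_id"],
        "hospital": hospital["patient_id"],
        "survey": survey["respondent_id"],
    }
    for name, ids in event_tables.items():
        orphan = sorted(set(ids) - known)
        report.orphans[name] = orphan

    if len(roster):
        dup_mask = roster.duplicated(subset=["patient_id", "provider_id", "start_date", "end_date"], keep="first")
        report.duplicate_roster = roster[dup_mask].to_dict("records")
        deduped = roster[~dup_mask]
        for _, grp in deduped.groupby("patient_id", sort=True):
            if len(grp) > 1:
                report.overlapping_roster.extend(_overlapping_pairs(grp))
    return report


def active_roster_at(roster: pd.DataFrame, index_dates: pd.Series) -> pd.Series:
    """Provider actively rostering each patient on that patient's index date.

    ``index_dates`` maps patient_id -> Timestamp. A patient may hold at most
    one active interval on any date; when intervals overlap the one with the
    latest start_date wins (provider_id breaks residual ties
    deterministically). Returns a Series patient_id -> provider_id covering
    only patients with an active interval.
    """
    if roster.empty or index_dates.empty:
        return pd.Series(dtype=object, name="provider_id")
    idx = index_dates.rename("index_date").rename_axis("patient_id").reset_index()
    merged = roster.merge(idx, on="patient_id", how="inner")
    open_end = merged["end_date"].isna()
    covered = (merged["start_date"] <= merged["index_date"]) & (
        open_end | (merged["end_date"] >= merged["index_date"])
    )
    active = merged[covered]
    if active.empty:
        return pd.Series(dtype=object, name="provider_id")
    active = active.sort_values(
        ["patient_id", "start_date", "provider_id"], ascending=[True, False, True]
    )
    chosen = active.groupby("patient_id", sort=True).first()
    return chosen["provider_id"]


def validate_records(rows: Iterable[dict], schema: str) -> None:
    """Validate already-parsed records against a schema's invariants (helper)."""
    sch = SCHEMAS[schema]
    for i, row in enumerate(rows, start=1):
        for col in sch.id_columns:
            if not str(row[col]).strip():
                raise TableValidationError(sch.name, [(i, f"empty {col}")])
        for col, allowed in sch.enum_columns.items():
            if row[col] not in allowed:
                raise TableValidationError(sch.name, [(i, f"invalid {col}: {row[col]!r}")])
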