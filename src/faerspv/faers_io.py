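"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS distributes spontaneous adverse-event reports as "$"-delimited ASCII
files, one table per aspect of a report: DEMO (demographics and
administrative data), DRUG (reported medications and their roles), REAC
(MedDRA-coded reaction terms), OUTC (outcome codes), INDI (indications) and
THER (therapy dates).  This module parses those files into normalized
:class:`pandas.DataFrame` record sets, maps FAERS code values onto readable
categories, and writes result tables back out as tab-delimited text.

The parser is total: no input line raises.  Lines whose field count does not
match the header, or that fail a table-specific validity check (e.g. a REAC
row without a preferred term), are counted and skipped, never silently
dropped.  Files use the modern (post-2014) FAERS column names; legacy
quarters can be adapted through a user-supplied column mapping.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER")

#: mandatory source columns per table kind (modern FAERS ASCII names)
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod", "reporter_country"),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "caseid", "pt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "INDI": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
}

AGE_UNIT_CODES = {
    "DEC": "decade", "YR": "year", "MON": "month",
    "WK": "week", "DY": "day", "HR": "hour",
}

SEX_CODES = {"F": "F", "M": "M"}

OCCUPATION_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health-professional",
    "RN": "registered nurse",
    "CN": "consumer",
    "LW": "lawyer",
}

ROLE_CODES = {
    "PS": "primary suspect",
    "SS": "secondary suspect",
    "C": "concomitant",
    "I": "interacting",
}

OUTCOME_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital anomaly",
    "RI": "required intervention",
    "OT": "other serious",
}


class SchemaError(ValueError):
    """A mandatory column is absent from a table header."""


@dataclass
class ParsedTable:
    """One parsed FAERS table: normalized records plus skip accounting."""

    kind: str
    records: pd.DataFrame
    n_lines: int = 0
    n_skipped: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    def _count_skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1


def parse_date(raw: str | None, partial: str = "absent") -> _dt.date | None:
    """Parse a FAERS date field (``YYYYMMDD`` with truncated variants).

    Full 8-digit values yield a date; 6-digit (``YYYYMM``) and 4-digit
    (``YYYY``) values yield ``None`` under the default ``partial="absent"``
    policy, or the first day of the period under ``partial="first"``.
    Anything unparseable yields ``None``.  Total function: never raises.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s.isdigit():
        return None
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        if partial == "first":
            if len(s) == 6:
                return _dt.date(int(s[:4]), int(s[4:6]), 1)
            if len(s) == 4:
                return _dt.date(int(s), 1, 1)
    except ValueError:
        return None
    return None


def _parse_age(raw: str) -> float | None:
    try:
        v = float(raw)
    except ValueError:
        return None
    return v if v >= 0 else None


def read_table(
    path: str | Path,
    kind: str,
    column_mapping: Mapping[str, str] | None = None,
    date_policy: str = "absent",
) -> ParsedTable:
    """Read one ``$``-delimited FAERS table into a normalized record frame.

    Parameters
    ----------
    path
        Text file whose first line is a ``$``-separated header.
    kind
        One of ``DEMO, DRUG, REAC, OUTC, INDI, THER``.
    column_mapping
        Optional ``{file column: canonical column}`` renaming applied after
        lower-casing the header, for legacy quarters whose column names
        differ from the modern schema.
    date_policy
        Partial-date policy forwarded to :func:`parse_date`.

    Returns
    -------
    ParsedTable
        ``records`` holds one row per valid data line with normalized
        column names and decoded categorical values; unknown source columns
        are preserved as opaque extras.  Skipped-line counts are recorded
        on the result and logged.

    Raises
    ------
    SchemaError
        If a mandatory column for ``kind`` is missing from the header.
    """
    kind = kind.upper()
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {TABLE_KINDS}")
    path = Path(path)
    with open(path, encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
        columns = [c.strip().lower() for c in header_line.split("$")]
        if column_mapping:
            mapping = {k.lower(): v.lower() for k, v in column_mapping.items()}
            columns = [mapping.get(c, c) for c in columns]
        for col in MANDATORY_COLUMNS[kind]:
            if col not in columns:
                raise SchemaError(f"{kind} table {path.name} lacks mandatory column {col!r}")
        result = ParsedTable(kind=kind, records=pd.DataFrame())
        rows: list[dict] = []
        ncol = len(columns)
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            result.n_lines += 1
            fields = line.split("$")
            if len(fields) != ncol:
                result._count_skip("field count mismatch")
                continue
            raw = dict(zip(columns, (f.strip() for f in fields)))
            rec = _normalize_row(kind, raw, result, date_policy)
            if rec is not None:
                rows.append(rec)
    if result.n_skipped:
        logger.warning("%s %s: skipped %d of %d lines (%s)", kind, path.name,
                       result.n_skipped, result.n_lines, result.skip_reasons)
    result.records = pd.DataFrame(rows, columns=_frame_columns(kind, rows))
    return result


_NORMALIZED_COLUMNS = {
    "DEMO": ["primary_id", "case_id", "receipt_date", "event_date", "age_value",
             "age_unit", "sex", "reporter_occupation", "reporter_country"],
    "DRUG": ["primary_id", "case_id", "drug_seq", "name", "active_ingredient",
             "role", "route"],
    "REAC": ["primary_id", "case_id", "pt"],
    "OUTC": ["primary_id", "case_id", "outcome"],
    "INDI": ["primary_id", "case_id", "drug_seq", "indication_pt"],
    "THER": ["primary_id", "case_id", "drug_seq", "start_date"],
}

_CONSUMED = {
    "DEMO": {"primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod", "reporter_country"},
    "DRUG": {"primaryid", "caseid", "drug_seq", "role_cod", "drugname",
             "prod_ai", "route"},
    "REAC": {"primaryid", "caseid", "pt"},
    "OUTC": {"primaryid", "caseid", "outc_cod"},
    "INDI": {"primaryid", "caseid", "indi_drug_seq", "indi_pt"},
    "THER": {"primaryid", "caseid", "dsg_drug_seq", "start_dt"},
}


def _frame_columns(kind: str, rows: list[dict]) -> list[str]:
    cols = list(_NORMALIZED_COLUMNS[kind])
    if rows:
        for k in rows[0]:
            if k not in cols:
                cols.append(k)
    return cols


def _normalize_row(kind: str, raw: Mapping[str, str], result: ParsedTable,
                   date_policy: str) -> dict | None:
    """Decode one raw row; return None (and count) if it is unusable."""
    pid, cid = raw.get("primaryid", ""), raw.get("caseid", "")
    if not pid or not cid:
        result._count_skip("missing identifier")
        return None
    rec: dict = {"primary_id": pid, "case_id": cid}

    if kind == "DEMO":
        rec["receipt_date"] = parse_date(raw["fda_dt"], date_policy)
        rec["event_date"] = parse_date(raw["event_dt"], date_policy)
        rec["age_value"] = _parse_age(raw["age"]) if raw["age"] else None
        rec["age_unit"] = AGE_UNIT_CODES.get(raw["age_cod"].upper(), "unknown")
        rec["sex"] = SEX_CODES.get(raw["sex"].upper(), "unknown")
        rec["reporter_occupation"] = OCCUPATION_CODES.get(raw["occp_cod"].upper(), "unknown")
        rec["reporter_country"] = raw["reporter_country"] or "unknown"
    elif kind == "DRUG":
        if not raw["drugname"]:
            result._count_skip("empty drug name")
            return None
        role = ROLE_CODES.get(raw["role_cod"].upper())
        if role is None:
            result._count_skip("invalid role code")
            return None
        try:
            seq = int(raw["drug_seq"])
        except ValueError:
            result._count_skip("invalid drug_seq")
            return None
        rec.update(drug_seq=seq, name=raw["drugname"],
                   active_ingredient=raw.get("prod_ai", ""), role=role,
                   route=raw.get("route", ""))
    elif kind == "REAC":
        if not raw["pt"]:
            result._count_skip("empty preferred term")
            return None
        rec["pt"] = raw["pt"]
    elif kind == "OUTC":
        outcome = OUTCOME_CODES.get(raw["outc_cod"].upper())
        if outcome is None:
            result._count_skip("invalid outcome code")
            return None
        rec["outcome"] = outcome
    elif kind == "INDI":
        if not raw["indi_pt"]:
            result._count_skip("empty indication term")
            return None
        try:
            rec["drug_seq"] = int(raw["indi_drug_seq"])
        except ValueError:
            result._count_skip("invalid drug_seq")
            return None
        rec["indication_pt"] = raw["indi_pt"]
    elif kind == "THER":
        try:
            rec["drug_seq"] = int(raw["dsg_drug_seq"])
        except ValueError:
            result._count_skip("invalid drug_seq")
            return None
        rec["start_date"] = parse_date(raw["start_dt"], date_policy)

    for k, v in raw.items():
        if k not in _CONSUMED[kind]:
            rec[k] = v
    return rec


def read_corpus(directory: str | Path, suffix: str = ".txt",
                column_mapping: Mapping[str, Mapping[str, str]] | None = None,
                date_policy: str = "absent") -> dict[str, ParsedTable]:
    """Read all six tables ``DEMO.txt`` ... ``THER.txt`` from one directory."""
    directory = Path(directory)
    out = {}
    for kind in TABLE_KINDS:
        mapping = (column_mapping or {}).get(kind)
        out[kind] = read_table(directory / f"{kind}{suffix}", kind,
                               column_mapping=mapping, date_policy=date_policy)
    return out


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write result tables as tab-delimited text, one file per table.

    Column order follows each frame; rows are written in frame order, so
    identical inputs produce byte-identical files.  Returns the written
    paths keyed by table name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        p = out_dir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False, lineterminator="\n")
        paths[name] = p
    return paths
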