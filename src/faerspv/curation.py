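"""Curation of spontaneous-report corpora.

Turns raw FAERS-style tables into an analysis-ready corpus: case-level
deduplication (one report per case, the most recent version), matching of
the target drug by generic and trade name among primary-suspect records,
PT-to-SOC dictionary mapping, indication-term exclusion, minimum report
count filtering, and the derived classification fields used by the
descriptive and subgroup analyses (reporter class, age group and
time-to-onset bin).
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

UNMAPPED_SOC = "unmapped"

AGE_GROUPS = ("<18", "18–40", "40–60", "60–80", "≥80")
_AGE_EDGES = (0.0, 18.0, 40.0, 60.0, 80.0)

TTO_BINS = ("<30", "30–180", "180–360", "360–540", "≥540")
_TTO_EDGES = (0, 30, 180, 360, 540)

#: conversion factors from FAERS age units to years
AGE_UNIT_TO_YEARS = {
    "decade": 10.0,
    "year": 1.0,
    "month": 1.0 / 12.0,
    "week": 1.0 / 52.0,
    "day": 1.0 / 365.25,
    "hour": 1.0 / 8766.0,
}

HEALTH_PROFESSIONAL_OCCUPATIONS = frozenset(
    {"physician", "pharmacist", "registered nurse", "other health-professional"}
)
NON_HEALTH_PROFESSIONAL_OCCUPATIONS = frozenset({"consumer", "lawyer"})


def normalize_name(name: str) -> str:
    """Normalize a drug or term name: uppercase, trim, strip trailing
    punctuation, collapse internal whitespace."""
    s = str(name).strip().upper()
    s = s.rstrip(".,;:!?/\\-")
    return re.sub(r"\s+", " ", s).strip()


class MedDRADictionary:
    """Case-normalized PT -> SOC lookup.

    Every PT maps to exactly one SOC; looking up an unmapped PT yields the
    sentinel SOC ``"unmapped"`` rather than raising, so a partial dictionary
    degrades gracefully.  The packaged toy dictionary covers the PTs used by
    the synthetic generator and the test corpus; real MedDRA is licensed and
    must be supplied by the user as a two-column delimited file (PT, SOC).
    """

    def __init__(self, entries: dict[str, str]):
        self._entries = {normalize_name(pt): soc for pt, soc in entries.items()}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return normalize_name(pt) in self._entries

    def lookup(self, pt: str) -> str:
        return self._entries.get(normalize_name(pt), UNMAPPED_SOC)

    @property
    def pts(self) -> list[str]:
        return sorted(self._entries)

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "MedDRADictionary":
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        pt_col, soc_col = frame.columns[:2]
        return cls(dict(zip(frame[pt_col], frame[soc_col])))

    @classmethod
    def packaged(cls) -> "MedDRADictionary":
        """The toy PT->SOC dictionary shipped with the package."""
        with resources.files("faerspv.data").joinpath("meddra_toy.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
        return cls(dict(zip(frame["pt"], frame["soc"])))


def map_pt_to_soc(pt: str, dictionary: MedDRADictionary) -> str:
    """Map one preferred term to its system organ class (or ``"unmapped"``)."""
    return dictionary.lookup(pt)


@dataclass
class DrugQuery:
    """Names identifying the target drug and the drug-role to search.

    Both the generic and trade names are searched against the verbatim drug
    name and the active-ingredient field, after normalization, requiring
    whole-string equality or whole-word containment (so "KINERET" matches
    "KINERET 100MG" but not "KINERETIN").
    """

    generic_names: list[str]
    trade_names: list[str] = field(default_factory=list)
    role_filter: str = "primary suspect"

    def __post_init__(self):
        self.generic_names = [normalize_name(n) for n in self.generic_names]
        self.trade_names = [normalize_name(n) for n in self.trade_names]
        if not (self.generic_names or self.trade_names):
            raise ValueError("DrugQuery requires at least one name")

    @property
    def all_names(self) -> list[str]:
        return self.generic_names + self.trade_names

    def matches_name(self, name: str) -> bool:
        norm = normalize_name(name)
        if not norm:
            return False
        for q in self.all_names:
            if norm == q or re.search(rf"(?<![A-Z0-9]){re.escape(q)}(?![A-Z0-9])", norm):
                return True
        return False


def _pid_sort_key(pid: str) -> tuple[int, int, str]:
    s = str(pid)
    return (1, int(s), "") if s.isdigit() else (0, 0, s)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one demographic record per case: the most recent report version.

    Exact full-row duplicates are removed first.  Within a case, the record
    with the latest receipt date wins; when dates tie or are absent, the
    greatest primary_id (numerically when both are numeric, else
    lexicographically) is kept, mirroring the "latest version" intuition.
    Idempotent; the result has one row per ``case_id``.
    """
    if demo.empty:
        return demo.copy()
    out = demo.drop_duplicates(keep="first").copy()
    date_ord = out["receipt_date"].map(
        lambda d: d.toordinal() if isinstance(d, _dt.date) else -1)
    pid_key = out["primary_id"].map(_pid_sort_key)
    out = (out.assign(_date=date_ord, _pid=pid_key)
              .sort_values(["case_id", "_date", "_pid"], kind="stable")
              .groupby("case_id", sort=False).tail(1)
              .drop(columns=["_date", "_pid"])
              .sort_index())
    return out.reset_index(drop=True)


def match_target_reports(drugs: pd.DataFrame, query: DrugQuery) -> set[str]:
    """Primary keys of reports containing >=1 drug record that matches the
    query names under the query's role filter."""
    if drugs.empty:
        return set()
    role_ok = drugs["role"] == query.role_filter
    sub = drugs.loc[role_ok]
    name_ok = sub["name"].map(query.matches_name)
    if "active_ingredient" in sub.columns:
        name_ok = name_ok | sub["active_ingredient"].map(query.matches_name)
    return set(sub.loc[name_ok, "primary_id"])


def matched_drug_seqs(drugs: pd.DataFrame, query: DrugQuery) -> pd.DataFrame:
    """(primary_id, drug_seq) rows of the drug records matching the query."""
    if drugs.empty:
        return pd.DataFrame(columns=["primary_id", "drug_seq"])
    role_ok = drugs["role"] == query.role_filter
    sub = drugs.loc[role_ok]
    name_ok = sub["name"].map(query.matches_name)
    if "active_ingredient" in sub.columns:
        name_ok = name_ok | sub["active_ingredient"].map(query.matches_name)
    return sub.loc[name_ok, ["primary_id", "drug_seq"]]


def filter_min_count(pairs: pd.DataFrame, min_count: int = 3,
                     count_col: str = "a") -> pd.DataFrame:
    """Drop drug-term rows whose report count falls below ``min_count``."""
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    return pairs.loc[pairs[count_col] >= min_count].copy()


def exclude_indication_pts(pairs: pd.DataFrame, exclusion: list[str],
                           pt_col: str = "term") -> pd.DataFrame:
    """Remove rows whose PT is on the indication exclusion list.

    Events that merely restate the treated disease (e.g. "Rheumatoid
    arthritis" reported under an arthritis drug) are not adverse events; the
    exclusion list is an input, matched case-insensitively.
    """
    excl = {normalize_name(p) for p in exclusion}
    if not excl:
        return pairs.copy()
    drop = pairs[pt_col].map(normalize_name).isin(excl)
    if int(drop.sum()):
        logger.info("excluded %d indication-term rows", int(drop.sum()))
    return pairs.loc[~drop].copy()


def classify_reporter(occupation: str | None) -> str:
    """Collapse the reporter occupation code into health professional /
    non-health professional / unknown."""
    if occupation is None or pd.isna(occupation):
        return "unknown"
    occ = str(occupation).strip().lower()
    if occ in HEALTH_PROFESSIONAL_OCCUPATIONS:
        return "health professional"
    if occ in NON_HEALTH_PROFESSIONAL_OCCUPATIONS:
        return "non-health professional"
    return "unknown"


def age_in_years(age_value: float | None, age_unit: str) -> float | None:
    """Convert an (age value, unit code) pair to years; None when unusable."""
    if age_value is None or pd.isna(age_value):
        return None
    factor = AGE_UNIT_TO_YEARS.get(age_unit)
    if factor is None:
        return None
    years = float(age_value) * factor
    if years < 0:
        logger.warning("negative age %r %s ignored", age_value, age_unit)
        return None
    return years


def assign_age_group(age_value: float | None, age_unit: str) -> str:
    """Bin an age into the standard strata.

    Intervals are half-open left-closed: [0,18), [18,40), [40,60), [60,80),
    [80,inf) — an exact 40th birthday falls in "40–60".  Missing values,
    unknown units and negative ages map to "unknown".
    """
    years = age_in_years(age_value, age_unit)
    if years is None:
        return "unknown"
    group = AGE_GROUPS[0]
    for edge, label in zip(_AGE_EDGES, AGE_GROUPS):
        if years >= edge:
            group = label
    return group


def compute_tto(therapy_start: _dt.date | None,
                event_date: _dt.date | None) -> tuple[int | None, str]:
    """Days from therapy start to event onset, with the matching bin.

    Negative spans (event before exposure) and missing dates yield
    ``(None, "unknown")``.  Bins are half-open left-closed.
    """
    if therapy_start is None or event_date is None:
        return None, "unknown"
    days = (event_date - therapy_start).days
    if days < 0:
        return None, "unknown"
    label = TTO_BINS[0]
    for edge, lab in zip(_TTO_EDGES, TTO_BINS):
        if days >= edge:
            label = lab
    return days, label


@dataclass
class Corpus:
    """A deduplicated, curated report corpus.

    ``demo`` carries one row per case with the derived classification
    columns (``reporter_class``, ``age_group``, ``tto_days``, ``tto_bin``);
    the remaining tables are restricted to the kept report versions.
    ``target_keys`` are the primary ids of reports naming the query drug in
    the queried role.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    target_keys: set[str]
    query: DrugQuery | None = None

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def n_target_reports(self) -> int:
        return len(self.target_keys)

    def target_demo(self) -> pd.DataFrame:
        return self.demo.loc[self.demo["primary_id"].isin(self.target_keys)]


def _earliest_target_therapy_start(drug: pd.DataFrame, ther: pd.DataFrame,
                                   query: DrugQuery) -> dict[str, _dt.date]:
    """Earliest therapy start date per report among the query-matched drug's
    records (the conservative exposure date for time-to-onset)."""
    matched = matched_drug_seqs(drug, query)
    if matched.empty or ther.empty:
        return {}
    joined = ther.merge(matched, on=["primary_id", "drug_seq"], how="inner")
    joined = joined.dropna(subset=["start_date"])
    joined = joined[joined["start_date"].map(lambda d: isinstance(d, _dt.date))]
    if joined.empty:
        return {}
    return joined.groupby("primary_id")["start_date"].min().to_dict()


def reaction_events(corpus: Corpus, level: str = "PT",
                    dictionary: MedDRADictionary | None = None,
                    keys: set[str] | None = None) -> pd.DataFrame:
    """One row per reaction record, with drug attribution and event term.

    The counting unit of the disproportionality tables is the reaction
    record (each PT occurrence in a report).  Records of target reports are
    attributed to the query's first generic name; every other report is
    attributed to its primary-suspect drug (lowest drug_seq, normalized),
    or ``"UNSPECIFIED"`` when the report has none.  ``level="SOC"`` maps
    each PT through the dictionary.  ``keys`` optionally restricts to a
    report subset (e.g. one stratum).
    """
    ps = corpus.drug.loc[corpus.drug["role"] == "primary suspect"]
    first_ps = (ps.sort_values(["primary_id", "drug_seq"], kind="stable")
                  .groupby("primary_id", sort=False)["name"].first()
                  .map(normalize_name).to_dict())
    label = (corpus.query.generic_names[0] if corpus.query and corpus.query.generic_names
             else "TARGET")
    ev = corpus.reac[["primary_id", "pt"]].copy()
    if keys is not None:
        ev = ev.loc[ev["primary_id"].isin(keys)].copy()
    ev["drug"] = [label if pid in corpus.target_keys
                  else first_ps.get(pid, "UNSPECIFIED")
                  for pid in ev["primary_id"]]
    if level.upper() == "SOC":
        if dictionary is None:
            raise ValueError("SOC-level events require a PT->SOC dictionary")
        ev["term"] = ev["pt"].map(dictionary.lookup)
    else:
        ev["term"] = ev["pt"]
    return ev[["primary_id", "drug", "term", "pt"]].reset_index(drop=True)


def curate(tables: dict, query: DrugQuery) -> Corpus:
    """Run the full curation chain on raw parsed tables.

    Deduplicates the DEMO table, restricts every other table to the kept
    report versions, matches the target drug, and populates the derived
    demographic fields.  ``tables`` maps kind to either a
    :class:`~faerspv.faers_io.ParsedTable` or a bare DataFrame.
    """
    def _frame(kind: str) -> pd.DataFrame:
        t = tables[kind]
        return t.records if hasattr(t, "records") else t

    demo = deduplicate(_frame("DEMO"))
    kept = set(demo["primary_id"])
    drug = _frame("DRUG")
    drug = drug.loc[drug["primary_id"].isin(kept)].reset_index(drop=True)
    reac = _frame("REAC")
    reac = reac.loc[reac["primary_id"].isin(kept)].reset_index(drop=True)
    outc = _frame("OUTC")
    outc = outc.loc[outc["primary_id"].isin(kept)].reset_index(drop=True)
    indi = _frame("INDI")
    indi = indi.loc[indi["primary_id"].isin(kept)].reset_index(drop=True)
    ther = _frame("THER")
    ther = ther.loc[ther["primary_id"].isin(kept)].reset_index(drop=True)

    target_keys = match_target_reports(drug, query)

    demo = demo.copy()
    demo["reporter_class"] = demo["reporter_occupation"].map(classify_reporter)
    demo["age_group"] = [assign_age_group(v, u) for v, u in
                         zip(demo["age_value"], demo["age_unit"])]
    starts = _earliest_target_therapy_start(drug, ther, query)
    tto = [compute_tto(starts.get(pid), ev) if pid in target_keys else (None, "unknown")
           for pid, ev in zip(demo["primary_id"], demo["event_date"])]
    demo["tto_days"] = [d for d, _ in tto]
    demo["tto_bin"] = [b for _, b in tto]

    return Corpus(demo=demo, drug=drug, reac=reac, outc=outc, indi=indi,
                  ther=ther, target_keys=target_keys, query=query)
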