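"""Descriptive summary tables of a curated corpus.

Demographics/outcome/time-to-onset breakdowns with percentages, top
indication and concomitant-medication rankings, and the conventional
formatted signal table (point estimate with 95% interval in parentheses,
two decimals).

Denominator conventions: the age, sex, reporter, country and route blocks
use the number of deduplicated target reports; the outcomes block uses the
number of outcome *records* (a report can carry several outcomes); the
time-to-onset block uses its own category total (known bins plus unknown).
These are the only conventions under which the percentage columns of
published spontaneous-report summary tables are arithmetically consistent.
Each block exposes its denominator in the output rather than asserting one.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .curation import AGE_GROUPS, TTO_BINS, Corpus, matched_drug_seqs, normalize_name

OUTCOME_ORDER = ("other serious", "hospitalization", "death", "life-threatening",
                 "disability", "congenital anomaly", "required intervention")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed-table
    convention; Python's built-in round is half-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: float, denominator: float) -> float:
    """``100 * count / denominator`` rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, 2)


def _block(counts: pd.Series, denominator: int, order: list[str] | None = None) -> pd.DataFrame:
    if order is not None:
        counts = counts.reindex(order, fill_value=0)
    out = pd.DataFrame({"category": counts.index, "count": counts.values})
    out["pct"] = [percentage(c, denominator) for c in out["count"]]
    return out.reset_index(drop=True)


@dataclass
class DemographicsSummary:
    """Per-category counts and percentages, one frame per variable block."""

    blocks: dict[str, pd.DataFrame]
    denominators: dict[str, int]

    def __getitem__(self, block: str) -> pd.DataFrame:
        return self.blocks[block]


def demographics_table(corpus: Corpus, top_countries: int = 3) -> DemographicsSummary:
    """Build the descriptive summary of the target drug's reports.

    Blocks: age group, sex, reporter occupation, country (top ``top_countries``
    plus "Other"), route of the matched drug, outcomes, time to onset.
    Empty corpus yields an empty summary.
    """
    demo = corpus.target_demo()
    if demo.empty:
        return DemographicsSummary(blocks={}, denominators={})
    n = len(demo)
    blocks: dict[str, pd.DataFrame] = {}
    denoms: dict[str, int] = {}

    blocks["age_group"] = _block(demo["age_group"].value_counts(), n,
                                 order=list(AGE_GROUPS) + ["unknown"])
    denoms["age_group"] = n
    sex = demo["sex"].map({"F": "Female", "M": "Male"}).fillna("unknown")
    blocks["sex"] = _block(sex.value_counts(), n, order=["Female", "Male", "unknown"])
    denoms["sex"] = n
    occ = demo["reporter_occupation"].value_counts().sort_values(ascending=False)
    blocks["reporter"] = _block(occ, n)
    denoms["reporter"] = n

    country = demo["reporter_country"].value_counts()
    known = country.drop(index="unknown", errors="ignore")
    head = known.head(top_countries)
    rest = int(known.iloc[top_countries:].sum()) + int(country.get("unknown", 0))
    cblock = pd.concat([head, pd.Series({"Other": rest})])
    blocks["country"] = _block(cblock.sort_values(ascending=False), n)
    denoms["country"] = n

    matched = matched_drug_seqs(corpus.drug, corpus.query) if corpus.query else \
        pd.DataFrame(columns=["primary_id", "drug_seq"])
    drug = corpus.drug.merge(matched, on=["primary_id", "drug_seq"], how="inner")
    first_route = (drug.sort_values(["primary_id", "drug_seq"], kind="stable")
                       .groupby("primary_id", sort=False)["route"].first()
                       .replace("", "Unknown"))
    first_route = first_route.reindex(demo["primary_id"]).fillna("Unknown")
    blocks["route"] = _block(first_route.value_counts().sort_values(ascending=False), n)
    denoms["route"] = n

    outc = corpus.outc.loc[corpus.outc["primary_id"].isin(corpus.target_keys)]
    n_outc = len(outc)
    blocks["outcomes"] = _block(outc["outcome"].value_counts(), n_outc,
                                order=list(OUTCOME_ORDER))
    denoms["outcomes"] = n_outc

    tto = demo["tto_bin"].value_counts().reindex(list(TTO_BINS) + ["unknown"],
                                                 fill_value=0)
    n_tto = int(tto.sum())
    blocks["tto"] = _block(tto, n_tto)
    denoms["tto"] = n_tto
    return DemographicsSummary(blocks=blocks, denominators=denoms)


def top_indications_concomitants(corpus: Corpus, top: int = 5
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top indications of the matched drug and top concomitant medications.

    Indications are counted from the matched primary-suspect drug's
    indication terms in target reports; concomitants by normalized name of
    the non-primary-suspect drug records.  Both descending, ties broken
    alphabetically.
    """
    matched = matched_drug_seqs(corpus.drug, corpus.query)
    indi = corpus.indi.merge(matched, on=["primary_id", "drug_seq"], how="inner")
    ind = (indi.groupby("indication_pt").size().rename("count").reset_index()
               .rename(columns={"indication_pt": "term"})
               .sort_values(["count", "term"], ascending=[False, True], kind="stable")
               .head(top).reset_index(drop=True))
    non_ps = corpus.drug.loc[
        corpus.drug["primary_id"].isin(corpus.target_keys)
        & (corpus.drug["role"] != "primary suspect")].copy()
    if non_ps.empty:
        con = pd.DataFrame(columns=["term", "count"])
    else:
        non_ps["term"] = non_ps["name"].map(normalize_name)
        con = (non_ps.groupby("term").size().rename("count").reset_index()
                     .sort_values(["count", "term"], ascending=[False, True],
                                  kind="stable")
                     .head(top).reset_index(drop=True))
    return ind, con


def _fmt(x: float) -> str:
    return "NA" if pd.isna(x) else f"{round_half_up(x, 2):.2f}"


def _fmt_ci(v: float, lo: float, hi: float) -> str:
    if pd.isna(v):
        return "NA"
    return f"{_fmt(v)} ({_fmt(lo)}, {_fmt(hi)})"


def format_signal_table(stats: pd.DataFrame, soc_col: str = "soc",
                        term_col: str = "term") -> pd.DataFrame:
    """Render a statistics frame in the conventional published layout.

    Columns: SOC, PT, case reports, ROR (95% CI), PRR (95% CI), Chisq,
    IC (IC025), EBGM (EBGM05); numbers at two decimals, undefined values as
    "NA".  Deterministic: identical inputs render identically.
    """
    rows = []
    for r in stats.to_dict("records"):
        rows.append({
            "SOC": r.get(soc_col, ""),
            "PT": r.get(term_col, ""),
            "Case reports": int(r["n"]),
            "ROR (95% CI)": _fmt_ci(r["ror"], r["ror_lo95"], r["ror_hi95"]),
            "PRR (95% CI)": _fmt_ci(r["prr"], r["prr_lo95"], r["prr_hi95"]),
            "Chisq": _fmt(r["chisq"]),
            "IC (IC025)": (f"{_fmt(r['ic'])} ({_fmt(r['ic025'])})"
                           if not pd.isna(r["ic"]) else "NA"),
            "EBGM (EBGM05)": (f"{_fmt(r['ebgm'])} ({_fmt(r['ebgm05'])})"
                              if not pd.isna(r["ebgm"]) else "NA"),
        })
    return pd.DataFrame(rows, columns=["SOC", "PT", "Case reports",
                                       "ROR (95% CI)", "PRR (95% CI)", "Chisq",
                                       "IC (IC025)", "EBGM (EBGM05)"])
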