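"""Published reference tables shipped with the package.

Two transcribed tables from a large published FAERS disproportionality
analysis of the IL-1 blockers anakinra and canakinumab serve as external
consistency anchors:

* ``published_category_counts.tsv`` — the descriptive summary's per-category
  counts and printed percentages (age, sex, reporter, route, outcomes,
  time to onset), used to check the percentage rule end to end.
* ``published_pt_signals.tsv`` — the top-20 PT-level signal rows per drug
  with all four algorithms' printed statistics, used to check internal
  identities (IC = log2 EBGM under the MGPS-linked convention; ROR >= PRR
  whenever ROR >= 1).

These are check inputs only; no pipeline computation reads them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: block -> denominator rule ("reports" or "block_total"); outcomes counts
#: are outcome records, so their block total IS the record denominator
BLOCK_DENOMINATORS = {
    "age_group": "reports",
    "sex": "reports",
    "reporter": "reports",
    "route": "reports",
    "outcomes": "block_total",
    "tto": "block_total",
}

REPORT_TOTALS = {"anakinra": 7544, "canakinumab": 8044}


def _read(name: str) -> pd.DataFrame:
    with resources.files("faerspv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_category_counts() -> pd.DataFrame:
    """Published per-category counts with their printed percentages."""
    return _read("published_category_counts.tsv")


def load_pt_signals() -> pd.DataFrame:
    """Published top-20 PT-level signal rows (40 rows, both drugs)."""
    return _read("published_pt_signals.tsv")


def block_denominator(drug: str, block: str, counts: pd.DataFrame) -> int:
    """Denominator for one drug/block under the published conventions."""
    rule = BLOCK_DENOMINATORS[block]
    if rule == "reports":
        return REPORT_TOTALS[drug]
    sub = counts.loc[(counts["drug"] == drug) & (counts["block"] == block)]
    return int(sub["count"].sum())
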