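"""Stratified views of a curated corpus.

Reporter-class comparisons, adverse-event rankings within death reports,
age distributions of common events, and coadministration-stratified signal
detection.  Strata always partition the corpus: every report falls in
exactly one stratum of a dimension, with an explicit "unknown" stratum
rather than silent exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .curation import Corpus, normalize_name, reaction_events, MedDRADictionary
from .curation import AGE_GROUPS
from .disproportionality import (GammaMixturePrior, SignalCriteria,
                                 signal_table)

logger = logging.getLogger(__name__)

DIMENSIONS = ("reporter class", "age group", "outcome", "coadministered drug")


@dataclass
class Stratum:
    """One stratum of a partition: dimension, label, and member reports."""

    dimension: str
    value: str
    report_keys: set[str]

    def __len__(self) -> int:
        return len(self.report_keys)


def _death_keys(corpus: Corpus) -> set[str]:
    outc = corpus.outc
    return set(outc.loc[outc["outcome"] == "death", "primary_id"])


def coadmin_keys(corpus: Corpus, coadmin: list[str]) -> set[str]:
    """Reports carrying >=1 non-primary-suspect drug matching the list."""
    names = {normalize_name(c) for c in coadmin}
    non_ps = corpus.drug.loc[corpus.drug["role"] != "primary suspect"]
    hit = non_ps["name"].map(normalize_name).isin(names)
    return set(non_ps.loc[hit, "primary_id"])


def stratify(corpus: Corpus, dimension: str,
             coadmin: list[str] | None = None) -> list[Stratum]:
    """Partition the corpus along one dimension.

    ``reporter class`` and ``age group`` use the derived demographic
    columns; ``outcome`` splits into death / other outcome / no-outcome
    ("unknown") strata so that reports with several outcome records still
    land in exactly one stratum; ``coadministered drug`` splits into
    with/without the given concomitant list.  Strata are disjoint and
    jointly cover the corpus.
    """
    keys = set(corpus.demo["primary_id"])
    if dimension == "reporter class":
        labels = ("health professional", "non-health professional", "unknown")
        col = corpus.demo["reporter_class"]
        return [Stratum(dimension, lab,
                        set(corpus.demo.loc[col == lab, "primary_id"]))
                for lab in labels]
    if dimension == "age group":
        labels = AGE_GROUPS + ("unknown",)
        col = corpus.demo["age_group"]
        return [Stratum(dimension, lab,
                        set(corpus.demo.loc[col == lab, "primary_id"]))
                for lab in labels]
    if dimension == "outcome":
        death = _death_keys(corpus)
        any_out = set(corpus.outc["primary_id"])
        return [Stratum(dimension, "death", death & keys),
                Stratum(dimension, "other outcome", (any_out - death) & keys),
                Stratum(dimension, "unknown", keys - any_out)]
    if dimension == "coadministered drug":
        if coadmin is None:
            raise ValueError("coadministered-drug stratification needs a drug list")
        with_keys = coadmin_keys(corpus, coadmin) & keys
        return [Stratum(dimension, "with coadministration", with_keys),
                Stratum(dimension, "without coadministration", keys - with_keys)]
    raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")


def death_report_ranking(corpus: Corpus, reporter_class: str,
                         signal_pts: list[str] | None = None,
                         top: int = 5) -> pd.DataFrame:
    """Rank adverse events inside the target drug's death reports.

    Restricts to target reports that carry a death outcome and were filed
    by the given reporter class, counts PT occurrences (limited to
    ``signal_pts``, the significant-signal list, when provided) and returns
    the ``top`` PTs by descending count, ties broken alphabetically.
    """
    death = _death_keys(corpus) & corpus.target_keys
    cls = corpus.demo.loc[corpus.demo["reporter_class"] == reporter_class,
                          "primary_id"]
    keys = death & set(cls)
    sub = corpus.reac.loc[corpus.reac["primary_id"].isin(keys)]
    if signal_pts is not None:
        wanted = {normalize_name(p) for p in signal_pts}
        sub = sub.loc[sub["pt"].map(normalize_name).isin(wanted)]
    if sub.empty:
        return pd.DataFrame(columns=["pt", "count"])
    counts = (sub.groupby("pt").size().rename("count").reset_index()
                 .sort_values(["count", "pt"], ascending=[False, True],
                              kind="stable"))
    return counts.head(top).reset_index(drop=True)


def age_distribution(signal_pts: list[str], corpus: Corpus) -> pd.DataFrame:
    """PT-by-age-group matrix of reaction-record counts in target reports.

    Rows are the given PTs; columns the age strata plus "unknown".  Counts
    are reaction records, so a PT reported twice in one report counts
    twice; row sums equal each PT's total target-report record count.
    """
    cols = list(AGE_GROUPS) + ["unknown"]
    age_of = dict(zip(corpus.demo["primary_id"], corpus.demo["age_group"]))
    sub = corpus.reac.loc[corpus.reac["primary_id"].isin(corpus.target_keys)].copy()
    wanted = {normalize_name(p): p for p in signal_pts}
    sub["pt_norm"] = sub["pt"].map(normalize_name)
    sub = sub.loc[sub["pt_norm"].isin(wanted)]
    sub["age_group"] = sub["primary_id"].map(age_of)
    mat = pd.DataFrame(0, index=[wanted[k] for k in sorted(wanted)], columns=cols)
    if not sub.empty:
        counts = sub.groupby(["pt_norm", "age_group"]).size()
        for (ptn, grp), cnt in counts.items():
            mat.loc[wanted[ptn], grp] = cnt
    mat.index.name = "pt"
    return mat


def coadmin_strata_signals(corpus: Corpus, coadmin: list[str], soc_filter: str,
                           prior: GammaMixturePrior,
                           dictionary: MedDRADictionary | None = None,
                           criteria: SignalCriteria = SignalCriteria(),
                           restrict_comparator: bool = False) -> dict[str, pd.DataFrame]:
    """Strongest flagged signal per coadministration stratum within one SOC.

    Target-drug reports are split into with/without the coadministered
    drugs; each stratum's a/b cells are rebuilt from its own reports while
    the comparator c/d cells default to the full-corpus background
    (``restrict_comparator=True`` rebuilds them inside the stratum).  Only
    PTs mapping to ``soc_filter`` are considered; each stratum returns its
    flagged rows ranked by EBGM (empty frame when nothing is flagged,
    logged).
    """
    dictionary = dictionary or MedDRADictionary.packaged()
    events = reaction_events(corpus, level="PT", dictionary=dictionary)
    target_label = events.loc[events["primary_id"].isin(corpus.target_keys), "drug"]
    label = target_label.iloc[0] if len(target_label) else "TARGET"
    if coadmin:
        with_keys = coadmin_keys(corpus, coadmin) & corpus.target_keys
        strata = {
            "with coadministration": with_keys,
            "without coadministration": corpus.target_keys - with_keys,
        }
    else:
        strata = {"all": set(corpus.target_keys)}
    soc_pts = {pt for pt in events["pt"].unique()
               if dictionary.lookup(pt) == soc_filter}
    results: dict[str, pd.DataFrame] = {}
    for name, keys in strata.items():
        if not keys:
            logger.info("coadmin stratum %r is empty", name)
            results[name] = pd.DataFrame()
            continue
        in_stratum = events["primary_id"].isin(keys)
        is_target = events["drug"] == label
        stratum_target = events.loc[in_stratum & is_target]
        comparator = events.loc[in_stratum & ~is_target] if restrict_comparator \
            else events.loc[~is_target]
        a = stratum_target.groupby("pt").size()
        c_tot = comparator.groupby("pt").size()
        n_t = len(stratum_target)
        n_c = len(comparator)
        rows = []
        for pt in sorted(soc_pts):
            ai = int(a.get(pt, 0))
            ci = int(c_tot.get(pt, 0))
            rows.append({"term": pt, "a": ai, "b": n_t - ai,
                         "c": ci, "d": n_c - ci})
        tab = pd.DataFrame(rows, columns=["term", "a", "b", "c", "d"])
        tab = tab.loc[(tab["a"] >= criteria.min_n) & (tab["d"] > 0)]
        if tab.empty:
            logger.info("coadmin stratum %r: no PT reaches the count gate", name)
            results[name] = pd.DataFrame()
            continue
        stats = signal_table(tab, prior, criteria=criteria)
        flagged = stats.loc[stats["signal"]]
        results[name] = (flagged.sort_values(["ebgm", "term"],
                                             ascending=[False, True],
                                             kind="stable")
                                .reset_index(drop=True))
    return results
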