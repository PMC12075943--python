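"""End-to-end convenience wrappers: raw tables to flagged signal table."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import curation, disproportionality as dp, faers_io
from .curation import Corpus, DrugQuery, MedDRADictionary


def load_and_curate(data_dir: str | Path, query: DrugQuery,
                    date_policy: str = "absent") -> Corpus:
    """Read the six FAERS tables from a directory and curate them."""
    tables = faers_io.read_corpus(data_dir, date_policy=date_policy)
    return curation.curate(tables, query)


def run_signal_analysis(corpus: Corpus, level: str = "PT",
                        dictionary: MedDRADictionary | None = None,
                        min_count: int = 3,
                        exclusion: list[str] | None = None,
                        criteria: dp.SignalCriteria = dp.SignalCriteria(),
                        ic_mode: str = "mgps-linked",
                        prior: dp.GammaMixturePrior | None = None,
                        ) -> tuple[pd.DataFrame, dp.GammaMixturePrior]:
    """Full disproportionality pass for the corpus's target drug.

    Builds reaction-record events at the requested level, fits the MGPS
    prior on every drug-term pair in the corpus (unless one is supplied),
    tabulates the target drug against the background, applies the
    indication exclusion and the minimum-count gate, and returns the
    statistics table (with SOC annotation at PT level) plus the prior.
    """
    dictionary = dictionary or MedDRADictionary.packaged()
    events = curation.reaction_events(corpus, level=level, dictionary=dictionary)
    if prior is None:
        all_pairs = dp.build_tables(events)
        prior = dp.fit_mgps_prior(all_pairs["a"], all_pairs["E"])
    label = events.loc[events["primary_id"].isin(corpus.target_keys), "drug"]
    target = label.iloc[0] if len(label) else "TARGET"
    tables = dp.tables_for_drug(events, target)
    tables = curation.exclude_indication_pts(tables, exclusion or [])
    tables = curation.filter_min_count(tables, min_count)
    if tables.empty:
        return tables, prior
    stats = dp.signal_table(tables, prior, criteria=criteria, ic_mode=ic_mode)
    if level.upper() == "PT":
        stats.insert(0, "soc", stats["term"].map(dictionary.lookup))
    return stats, prior
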