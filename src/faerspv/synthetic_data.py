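"""Synthetic FAERS-style corpora with known ground truth.

Real spontaneous-report data cannot ship with the package, so every
pipeline stage is exercised on generated corpora that emulate the FAERS
structure: case-level reports with demographics, one primary-suspect drug
plus concomitants, several MedDRA-coded reaction terms per report, outcome
codes, therapy dates, duplicate case versions and heavy missingness.

Drug-event associations are *planted*: a :class:`PlantedAssociation`
multiplies the background probability of one preferred term by a relative
reporting rate ``rho`` inside the reports of one drug (optionally only in
one age group, or only when a given concomitant is present), after which
the report's term distribution is renormalized.  The generator records this
ground truth so recovery can be scored exactly.

Everything is driven by one seed: per-aspect generators are spawned
deterministically from it, so a config generates byte-identical files on
every run.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import MedDRADictionary

_EPOCH = _dt.date(2015, 1, 1)

#: primary-suspect drug vocabulary with marginal usage probabilities
DEFAULT_DRUGS: dict[str, float] = {
    "ANAKINRA": 0.05, "CANAKINUMAB": 0.05, "METHOTREXATE": 0.06,
    "ADALIMUMAB": 0.07, "ETANERCEPT": 0.06, "TOCILIZUMAB": 0.05,
    "INFLIXIMAB": 0.05, "IBUPROFEN": 0.05, "PARACETAMOL": 0.05,
    "ASPIRIN": 0.05, "OMEPRAZOLE": 0.04, "AMOXICILLIN": 0.05,
    "ATORVASTATIN": 0.05, "METFORMIN": 0.05, "LISINOPRIL": 0.04,
    "WARFARIN": 0.04, "RITUXIMAB": 0.05, "COLCHICINE": 0.04,
    "NAPROXEN": 0.05, "GOLIMUMAB": 0.05,
}

CONCOMITANT_POOL = (
    "PREDNISONE", "METHOTREXATE", "ACETAMINOPHEN", "OMEPRAZOLE", "COLCHICINE",
    "ASPIRIN", "FOLIC ACID", "VITAMIN D", "IBUPROFEN", "PANTOPRAZOLE",
)

INDICATION_POOL = {
    "Rheumatoid arthritis": 0.40,
    "Still's disease": 0.25,
    "Product used for unknown indication": 0.20,
    "Juvenile idiopathic arthritis": 0.15,
}

_OCC_CODES = ("MD", "PH", "OT", "RN", "CN", "LW")
_OCC_PROBS = (0.16, 0.08, 0.06, 0.01, 0.67, 0.02)
_COUNTRIES = ("US", "FR", "JP", "GB", "DE")
_COUNTRY_PROBS = (0.60, 0.12, 0.08, 0.10, 0.10)
_ROUTES = ("Subcutaneous", "Unknown", "Intravenous", "Oral")
_ROUTE_PROBS = (0.70, 0.20, 0.05, 0.05)
_OUTCOME_CODES = ("OT", "HO", "DE", "LT", "DS", "CA", "RI")
_OUTCOME_PROBS = (0.45, 0.35, 0.10, 0.05, 0.03, 0.01, 0.01)
_AGE_BOUNDS = ((0, 18), (18, 40), (40, 60), (60, 80), (80, 95))


def default_background_pts() -> dict[str, float]:
    """Zipf-weighted background multinomial over the toy dictionary's PTs.

    Ranks follow the dictionary file order, so common reaction terms (the
    injection-site family, pyrexia, infections) sit in the head of the
    distribution and rare terms in the tail, roughly mimicking the skew of
    real reporting frequencies.
    """
    pts = _dictionary_pts_in_file_order()
    weights = np.array([1.0 / (rank + 3.0) for rank in range(len(pts))])
    weights /= weights.sum()
    return dict(zip(pts, weights))


def _dictionary_pts_in_file_order() -> list[str]:
    from importlib import resources
    with resources.files("faerspv.data").joinpath("meddra_toy.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    return list(frame["pt"])


@dataclass(frozen=True)
class PlantedAssociation:
    """One planted drug-event association.

    ``relative_rate`` (rho) multiplies the background probability of ``pt``
    within reports whose primary-suspect drug is ``drug``; the optional
    ``age_group`` / ``coadmin`` conditions restrict the boost to reports in
    that age stratum or carrying that concomitant, letting subgroup
    analyses be validated against ground truth.
    """

    drug: str
    pt: str
    relative_rate: float
    age_group: str | None = None
    coadmin: str | None = None

    def __post_init__(self):
        if self.relative_rate <= 0:
            raise ValueError("relative_rate must be positive")


@dataclass
class SyntheticConfig:
    """Knobs of the report generator; defaults emulate a desk-scale FAERS.

    The reactions-per-report count is ``1 + Poisson(poisson_mean)``
    truncated at ``max_reactions``; the default mean of 2 gives close to
    three reaction records per report, matching the records-to-reports
    ratio of large spontaneous-report corpora.
    """

    n_reports: int = 20_000
    drugs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUGS))
    background_pts: dict[str, float] = field(default_factory=default_background_pts)
    associations: list[PlantedAssociation] = field(default_factory=list)
    duplicate_fraction: float = 0.05
    poisson_mean: float = 2.0
    max_reactions: int = 10
    sex_female: float = 0.60
    age_group_probs: tuple[float, ...] = (0.15, 0.20, 0.30, 0.25, 0.10)
    missing_age: float = 0.30
    missing_sex: float = 0.05
    missing_event_date: float = 0.30
    missing_occupation: float = 0.05
    therapy_date_rate: float = 0.70
    outcome_rate: float = 0.60
    concomitant_max: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for name, p in [("duplicate_fraction", self.duplicate_fraction),
                        ("sex_female", self.sex_female),
                        ("missing_age", self.missing_age),
                        ("missing_sex", self.missing_sex),
                        ("missing_event_date", self.missing_event_date),
                        ("missing_occupation", self.missing_occupation),
                        ("therapy_date_rate", self.therapy_date_rate),
                        ("outcome_rate", self.outcome_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        drug_total = sum(self.drugs.values())
        self.drugs = {k: v / drug_total for k, v in self.drugs.items()}
        pt_total = sum(self.background_pts.values())
        self.background_pts = {k: v / pt_total for k, v in self.background_pts.items()}
        for assoc in self.associations:
            if assoc.drug not in self.drugs:
                raise ValueError(f"planted drug {assoc.drug!r} not in vocabulary")
            if assoc.pt not in self.background_pts:
                raise ValueError(f"planted PT {assoc.pt!r} not in background")


def planted_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth table of every planted (drug, PT, rho) association."""
    rows = [{"drug": a.drug, "pt": a.pt, "relative_rate": a.relative_rate,
             "age_group": a.age_group or "", "coadmin": a.coadmin or ""}
            for a in config.associations]
    return pd.DataFrame(rows, columns=["drug", "pt", "relative_rate",
                                       "age_group", "coadmin"])


def expected_planted_count(config: SyntheticConfig, assoc: PlantedAssociation) -> float:
    """Expected a-cell count for a planted pair (ignoring duplicates and
    conditional restrictions), useful when designing a scenario."""
    p = np.array(list(config.background_pts.values()))
    idx = list(config.background_pts).index(assoc.pt)
    boosted = p.copy()
    boosted[idx] *= assoc.relative_rate
    boosted /= boosted.sum()
    mean_k = 1 + config.poisson_mean  # truncation effect negligible at the default
    return config.n_reports * config.drugs[assoc.drug] * mean_k * boosted[idx]


def _date_str(d: _dt.date | None) -> str:
    return d.strftime("%Y%m%d") if d is not None else ""


def generate_frames(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Generate the six raw tables as string-valued DataFrames.

    Column names and code values follow the modern FAERS ASCII schema, so
    the output of :func:`generate` is readable by
    :func:`faerspv.faers_io.read_table` with zero skips.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    r_demo, r_drug, r_reac, r_outc, r_ther, r_dup = (
        np.random.default_rng(c) for c in ss.spawn(6))
    n = cfg.n_reports

    case_ids = np.array([str(10_000_000 + i) for i in range(n)])
    sex = np.where(r_demo.random(n) < cfg.sex_female, "F", "M")
    grp_idx = r_demo.choice(len(_AGE_BOUNDS), size=n, p=cfg.age_group_probs)
    lo = np.array([_AGE_BOUNDS[g][0] for g in grp_idx])
    hi = np.array([_AGE_BOUNDS[g][1] for g in grp_idx])
    age = lo + np.floor(r_demo.random(n) * (hi - lo)).astype(int)
    occ = r_demo.choice(_OCC_CODES, size=n, p=_OCC_PROBS)
    country = r_demo.choice(_COUNTRIES, size=n, p=_COUNTRY_PROBS)
    receipt_off = r_demo.integers(0, 9 * 365, size=n)
    event_lag = r_demo.integers(10, 400, size=n)
    miss_age = r_demo.random(n) < cfg.missing_age
    miss_sex = r_demo.random(n) < cfg.missing_sex
    miss_event = r_demo.random(n) < cfg.missing_event_date
    miss_occ = r_demo.random(n) < cfg.missing_occupation

    drug_names = list(cfg.drugs)
    ps_drug = r_drug.choice(drug_names, size=n, p=list(cfg.drugs.values()))
    n_con = r_drug.integers(0, cfg.concomitant_max + 1, size=n)
    con_lists = [list(r_drug.choice(CONCOMITANT_POOL, size=k, replace=False))
                 for k in n_con]
    route = r_drug.choice(_ROUTES, size=n, p=_ROUTE_PROBS)
    ind_names = list(INDICATION_POOL)
    ind_probs = np.array(list(INDICATION_POOL.values()))
    indication = r_drug.choice(ind_names, size=n, p=ind_probs / ind_probs.sum())

    # reactions: group reports sharing the same boosted term distribution so
    # each group is drawn in one vectorized multinomial pass
    k_react = np.minimum(1 + r_reac.poisson(cfg.poisson_mean, size=n),
                         cfg.max_reactions)
    pts = np.array(list(cfg.background_pts))
    bg = np.array(list(cfg.background_pts.values()))
    age_labels = np.array(["<18", "18–40", "40–60", "60–80", "≥80"])[grp_idx]
    profiles: dict[tuple[int, ...], list[int]] = {}
    for i in range(n):
        applicable = tuple(
            j for j, a in enumerate(cfg.associations)
            if a.drug == ps_drug[i]
            and (a.age_group is None or a.age_group == age_labels[i])
            and (a.coadmin is None or a.coadmin in con_lists[i]))
        profiles.setdefault(applicable, []).append(i)
    reactions: list[list[str]] = [[] for _ in range(n)]
    for key in sorted(profiles):
        idx = profiles[key]
        p = bg.copy()
        for j in key:
            p[np.flatnonzero(pts == cfg.associations[j].pt)[0]] *= \
                cfg.associations[j].relative_rate
        p /= p.sum()
        total = int(k_react[idx].sum())
        drawn = r_reac.choice(pts, size=total, p=p)
        pos = 0
        for i in idx:
            reactions[i] = list(drawn[pos:pos + k_react[i]])
            pos += k_react[i]

    has_out = r_outc.random(n) < cfg.outcome_rate
    out_code = r_outc.choice(_OUTCOME_CODES, size=n, p=_OUTCOME_PROBS)
    has_ther = r_ther.random(n) < cfg.therapy_date_rate
    tto_days = np.floor(r_ther.exponential(120.0, size=n)).astype(int)

    dup_mask = r_dup.random(n) < cfg.duplicate_fraction
    dup_delay = r_dup.integers(30, 400, size=n)
    dup_extra_pt = r_dup.choice(pts, size=n, p=bg)

    demo_rows, drug_rows, reac_rows = [], [], []
    outc_rows, indi_rows, ther_rows = [], [], []
    for i in range(n):
        cid = case_ids[i]
        receipt = _EPOCH + _dt.timedelta(days=int(receipt_off[i]))
        event = None if miss_event[i] else receipt - _dt.timedelta(days=int(event_lag[i]))
        ther_start = None
        if has_ther[i] and event is not None:
            ther_start = event - _dt.timedelta(days=int(tto_days[i]))
        versions = [(cid + "1", receipt, None)]
        if dup_mask[i]:
            versions.append((cid + "2",
                             receipt + _dt.timedelta(days=int(dup_delay[i])),
                             str(dup_extra_pt[i])))
        for pid, rcpt, extra_pt in versions:
            demo_rows.append((pid, cid, _date_str(rcpt), _date_str(event),
                              "" if miss_age[i] else str(int(age[i])),
                              "" if miss_age[i] else "YR",
                              "" if miss_sex[i] else sex[i],
                              "" if miss_occ[i] else occ[i],
                              country[i]))
            drug_rows.append((pid, cid, "1", "PS", ps_drug[i], ps_drug[i], route[i]))
            for s, con in enumerate(con_lists[i], start=2):
                drug_rows.append((pid, cid, str(s), "C", con, con, ""))
            for pt in reactions[i]:
                reac_rows.append((pid, cid, pt))
            if extra_pt is not None:
                reac_rows.append((pid, cid, extra_pt))
            if has_out[i]:
                outc_rows.append((pid, cid, out_code[i]))
            indi_rows.append((pid, cid, "1", indication[i]))
            if ther_start is not None:
                ther_rows.append((pid, cid, "1", _date_str(ther_start)))

    return {
        "DEMO": pd.DataFrame(demo_rows, columns=[
            "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
            "sex", "occp_cod", "reporter_country"]),
        "DRUG": pd.DataFrame(drug_rows, columns=[
            "primaryid", "caseid", "drug_seq", "role_cod", "drugname",
            "prod_ai", "route"]),
        "REAC": pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"]),
        "OUTC": pd.DataFrame(outc_rows, columns=["primaryid", "caseid", "outc_cod"]),
        "INDI": pd.DataFrame(indi_rows, columns=[
            "primaryid", "caseid", "indi_drug_seq", "indi_pt"]),
        "THER": pd.DataFrame(ther_rows, columns=[
            "primaryid", "caseid", "dsg_drug_seq", "start_dt"]),
    }


def generate(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic corpus as FAERS-style "$"-delimited ASCII files.

    Emits DEMO/DRUG/REAC/OUTC/INDI/THER tables plus a ``TRUTH.tsv`` listing
    the planted associations.  Deterministic: identical configs (including
    the seed) produce byte-identical files.
    """
    frames = generate_frames(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, frame in frames.items():
        p = out_dir / f"{kind}.txt"
        lines = ["$".join(frame.columns)]
        lines += ["$".join(row) for row in frame.itertuples(index=False, name=None)]
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[kind] = p
    truth_path = out_dir / "TRUTH.tsv"
    planted_truth(config).to_csv(truth_path, sep="\t", index=False,
                                 lineterminator="\n")
    paths["TRUTH"] = truth_path
    return paths


def validate_against_dictionary(config: SyntheticConfig,
                                dictionary: MedDRADictionary | None = None) -> None:
    """Check that every background and planted PT exists in the dictionary."""
    dictionary = dictionary or MedDRADictionary.packaged()
    missing = [pt for pt in config.background_pts if pt not in dictionary]
    if missing:
        raise ValueError(f"background PTs missing from dictionary: {missing[:5]}")
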