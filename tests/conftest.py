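"""Shared fixtures: hand-built miniature FAERS corpora written as real files."""

from __future__ import annotations

from pathlib import Path

import pytest

from faerspv import DrugQuery, curate, read_corpus

DEMO_HEADER = "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod$reporter_country"
DRUG_HEADER = "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$route"
REAC_HEADER = "primaryid$caseid$pt"
OUTC_HEADER = "primaryid$caseid$outc_cod"
INDI_HEADER = "primaryid$caseid$indi_drug_seq$indi_pt"
THER_HEADER = "primaryid$caseid$dsg_drug_seq$start_dt"

HEADERS = {"DEMO": DEMO_HEADER, "DRUG": DRUG_HEADER, "REAC": REAC_HEADER,
           "OUTC": OUTC_HEADER, "INDI": INDI_HEADER, "THER": THER_HEADER}


def write_faers(directory: Path, rows: dict[str, list[str]]) -> Path:
    """Write $-delimited tables (one line per row string) into a directory."""
    directory.mkdir(parents=True, exist_ok=True)
    for kind, header in HEADERS.items():
        lines = [header] + rows.get(kind, [])
        (directory / f"{kind}.txt").write_text("\n".join(lines) + "\n",
                                               encoding="utf-8")
    return directory


# a 6-case corpus: C1 has two versions (the later one adds a reaction), C2
# names the trade name with trailing punctuation, C3 carries the target only
# as a concomitant, C4/C6 are death reports, C5 is background
TINY_ROWS = {
    "DEMO": [
        "11$1$20200101$20191201$17$YR$F$MD$US",
        "12$1$20210601$20191201$17$YR$F$MD$US",
        "21$2$20200301$20200214$45$YR$M$CN$US",
        "31$3$20200401$$70$YR$$PH$FR",
        "41$4$20200501$20200401$$$$MD$US",
        "51$5$20200601$20200520$30$YR$M$CN$GB",
        "61$6$20200701$20200615$10$YR$F$RN$US",
    ],
    "DRUG": [
        "11$1$1$PS$ANAKINRA$ANAKINRA$Subcutaneous",
        "12$1$1$PS$ANAKINRA$ANAKINRA$Subcutaneous",
        "21$2$1$PS$KINERET.$ANAKINRA$Subcutaneous",
        "21$2$2$C$PREDNISONE$PREDNISONE$Oral",
        "31$3$1$PS$IBUPROFEN$IBUPROFEN$Oral",
        "31$3$2$C$ANAKINRA$ANAKINRA$Subcutaneous",
        "41$4$1$PS$ANAKINRA$ANAKINRA$Subcutaneous",
        "51$5$1$PS$METHOTREXATE$METHOTREXATE$Oral",
        "61$6$1$PS$ANAKINRA$ANAKINRA$Subcutaneous",
    ],
    "REAC": [
        "11$1$Pyrexia",
        "11$1$Injection site pain",
        "12$1$Pyrexia",
        "12$1$Injection site pain",
        "12$1$Septic shock",
        "21$2$Injection site pain",
        "21$2$Rheumatoid arthritis",
        "31$3$Nausea",
        "41$4$Septic shock",
        "51$5$Pyrexia",
        "51$5$Headache",
        "61$6$Septic shock",
    ],
    "OUTC": [
        "12$1$DE",
        "21$2$HO",
        "41$4$DE",
        "61$6$DE",
    ],
    "INDI": [
        "11$1$1$Rheumatoid arthritis",
        "12$1$1$Rheumatoid arthritis",
        "21$2$1$Rheumatoid arthritis",
        "41$4$1$Still's disease",
        "61$6$1$Rheumatoid arthritis",
    ],
    "THER": [
        "12$1$1$20191101",
        "21$2$1$20200201",
        "61$6$1$20200101",
    ],
}


@pytest.fixture()
def tiny_dir(tmp_path):
    return write_faers(tmp_path / "tiny", TINY_ROWS)


@pytest.fixture()
def anakinra_query():
    return DrugQuery(generic_names=["anakinra"], trade_names=["kineret"])


@pytest.fixture()
def tiny_corpus(tiny_dir, anakinra_query):
    return curate(read_corpus(tiny_dir), anakinra_query)
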