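"""Deduplication, drug matching, dictionary mapping and classification rules."""

import datetime as dt
import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faerspv import (DrugQuery, MedDRADictionary, assign_age_group,
                     classify_reporter, compute_tto, deduplicate,
                     exclude_indication_pts, filter_min_count, map_pt_to_soc,
                     match_target_reports, normalize_name)
from faerspv.curation import AGE_GROUPS


def demo_frame(rows):
    return pd.DataFrame(rows, columns=["primary_id", "case_id", "receipt_date"])


class TestDeduplicate:
    def test_most_recent_version_kept(self):
        demo = demo_frame([("11", "X", dt.date(2020, 1, 1)),
                           ("12", "X", dt.date(2021, 6, 1))])
        out = deduplicate(demo)
        assert list(out["primary_id"]) == ["12"]

    def test_single_version_unchanged(self):
        demo = demo_frame([("11", "X", dt.date(2020, 1, 1))])
        assert len(deduplicate(demo)) == 1

    def test_tie_breaks_on_greatest_primary_id_all_orderings(self):
        # brute force over every input ordering: the survivor never changes
        rows = [("100", "X", dt.date(2020, 1, 1)), ("250", "X", dt.date(2020, 1, 1))]
        for perm in itertools.permutations(rows):
            out = deduplicate(demo_frame(list(perm)))
            assert list(out["primary_id"]) == ["250"]

    def test_numeric_tie_break_beats_lexicographic(self):
        demo = demo_frame([("99", "X", None), ("100", "X", None)])
        assert list(deduplicate(demo)["primary_id"]) == ["100"]

    def test_exact_duplicate_rows_removed_first(self):
        demo = demo_frame([("11", "X", dt.date(2020, 1, 1)),
                           ("11", "X", dt.date(2020, 1, 1))])
        assert len(deduplicate(demo)) == 1

    def test_idempotent_and_unique_case_ids(self):
        demo = demo_frame([("11", "X", dt.date(2020, 1, 1)),
                           ("12", "X", None),
                           ("21", "Y", dt.date(2019, 5, 5)),
                           ("31", "Z", None)])
        once = deduplicate(demo)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once["case_id"].is_unique
        assert len(once) <= len(demo)


class TestMatchTargetReports:
    @pytest.fixture()
    def query(self):
        return DrugQuery(generic_names=["anakinra"], trade_names=["kineret"])

    def drug_frame(self, rows):
        return pd.DataFrame(rows, columns=["primary_id", "drug_seq", "name",
                                           "active_ingredient", "role"])

    def test_trailing_punctuation_normalized(self, query):
        drugs = self.drug_frame([("1", 1, "KINERET.", "", "primary suspect")])
        assert match_target_reports(drugs, query) == {"1"}

    def test_role_filter_excludes_concomitant(self, query):
        drugs = self.drug_frame([("1", 1, "anakinra", "", "concomitant")])
        assert match_target_reports(drugs, query) == set()

    def test_whole_word_containment_matches_strength(self, query):
        drugs = self.drug_frame([("1", 1, "KINERET 100MG", "", "primary suspect"),
                                 ("2", 1, "KINERETIN", "", "primary suspect")])
        assert match_target_reports(drugs, query) == {"1"}

    def test_active_ingredient_field_searched(self, query):
        drugs = self.drug_frame([("1", 1, "BRANDX", "ANAKINRA", "primary suspect")])
        assert match_target_reports(drugs, query) == {"1"}

    def test_report_with_mixed_drugs_matched_once(self, query):
        drugs = self.drug_frame([("1", 1, "ANAKINRA", "", "primary suspect"),
                                 ("1", 2, "PREDNISONE", "", "concomitant")])
        assert match_target_reports(drugs, query) == {"1"}


class TestDictionary:
    def test_published_isr_terms_map_to_general_disorders(self):
        d = MedDRADictionary.packaged()
        soc = "General disorders and administration site conditions"
        assert map_pt_to_soc("Injection site pain", d) == soc
        assert map_pt_to_soc("Pyrexia", d) == soc
        assert map_pt_to_soc("PYREXIA ", d) == soc  # case/space-normalized

    def test_unmapped_pt_yields_sentinel(self):
        d = MedDRADictionary.packaged()
        assert map_pt_to_soc("Totally made-up event", d) == "unmapped"


class TestPairFilters:
    def pairs(self, counts):
        return pd.DataFrame({"term": list(counts), "a": list(counts.values())})

    def test_min_count_three(self):
        out = filter_min_count(self.pairs({"A": 5, "B": 3, "C": 2}), 3)
        assert list(out["term"]) == ["A", "B"]

    def test_min_count_one_is_identity(self):
        p = self.pairs({"A": 5, "B": 1})
        assert len(filter_min_count(p, 1)) == len(p)

    def test_min_count_zero_rejected(self):
        with pytest.raises(ValueError):
            filter_min_count(self.pairs({"A": 1}), 0)

    def test_survivor_count_on_generated_table(self):
        counts = {f"PT{i}": (1 if i < 40 else 3 + i % 5) for i in range(100)}
        out = filter_min_count(self.pairs(counts), 3)
        assert len(out) == 60

    def test_exclusion_removes_matching_terms_case_insensitively(self):
        p = self.pairs({"Rheumatoid arthritis": 9, "Pyrexia": 5})
        out = exclude_indication_pts(p, ["RHEUMATOID ARTHRITIS"])
        assert list(out["term"]) == ["Pyrexia"]

    def test_empty_exclusion_is_identity(self):
        p = self.pairs({"A": 1})
        pd.testing.assert_frame_equal(exclude_indication_pts(p, []), p)

    def test_exclusion_count_on_fixture(self):
        p = self.pairs({"A": 1, "B": 2, "C": 3, "D": 4})
        excl = ["A", "C", "D", "NotPresent1", "NotPresent2"]
        assert len(exclude_indication_pts(p, excl)) == 1

    def test_filters_commute(self):
        p = self.pairs({"A": 5, "B": 2, "C": 9, "Rheumatoid arthritis": 7})
        excl = ["Rheumatoid arthritis"]
        ab = filter_min_count(exclude_indication_pts(p, excl), 3)
        ba = exclude_indication_pts(filter_min_count(p, 3), excl)
        pd.testing.assert_frame_equal(ab.reset_index(drop=True),
                                      ba.reset_index(drop=True))


class TestClassifyReporter:
    @pytest.mark.parametrize("occ,expected", [
        ("physician", "health professional"),
        ("pharmacist", "health professional"),
        ("registered nurse", "health professional"),
        ("other health-professional", "health professional"),
        ("consumer", "non-health professional"),
        ("lawyer", "non-health professional"),
        ("unknown", "unknown"),
        (None, "unknown"),
    ])
    def test_mapping(self, occ, expected):
        assert classify_reporter(occ) == expected

    @given(st.text(max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_total_partition(self, occ):
        assert classify_reporter(occ) in {"health professional",
                                          "non-health professional", "unknown"}


class TestAssignAgeGroup:
    @pytest.mark.parametrize("value,unit,expected", [
        (17, "year", "<18"),
        (40, "year", "40–60"),      # left-closed boundary
        (6, "month", "<18"),
        (5, "decade", "40–60"),
        (79.99, "year", "60–80"),
        (80, "year", "≥80"),
        (None, "year", "unknown"),
        (-3, "year", "unknown"),
        (30, "unknown", "unknown"),
    ])
    def test_binning(self, value, unit, expected):
        assert assign_age_group(value, unit) == expected

    @given(st.floats(min_value=0, max_value=150, allow_nan=False),
           st.sampled_from(["decade", "year", "month", "week", "day", "hour"]))
    @settings(max_examples=200, deadline=None)
    def test_every_valid_age_falls_in_exactly_one_stratum(self, value, unit):
        assert assign_age_group(value, unit) in AGE_GROUPS


class TestComputeTto:
    def test_two_week_onset(self):
        days, b = compute_tto(dt.date(2020, 1, 1), dt.date(2020, 1, 15))
        assert (days, b) == (14, "<30")

    def test_event_before_start_is_unknown(self):
        assert compute_tto(dt.date(2020, 2, 1), dt.date(2020, 1, 1)) == (None, "unknown")

    def test_missing_dates_unknown(self):
        assert compute_tto(None, dt.date(2020, 1, 1)) == (None, "unknown")

    def test_long_latency_calendar_arithmetic(self):
        # 2020 is a leap year: 366 + 181 = 547 days
        days, b = compute_tto(dt.date(2020, 1, 1), dt.date(2021, 7, 1))
        assert (days, b) == (547, "≥540")


def test_normalize_name_rules():
    assert normalize_name("  kineret. ") == "KINERET"
    assert normalize_name("ANAKINRA\t 100 MG") == "ANAKINRA 100 MG"
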