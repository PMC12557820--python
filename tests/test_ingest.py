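"""Parsing, two-round deduplication and filtering contracts."""

import pandas as pd
import pytest

from pvsignals import ingest, synthetic
from pvsignals.core import ReportSet
from pvsignals.ingest import (MeddraMap, ParseError, deduplicate,
                              filter_primary_suspect, map_pt_to_soc,
                              parse_quarter_files)

from conftest import make_report_set


def _write(tmp_path, name, header, rows):
    lines = [header] + rows
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture()
def quarter_dir(tmp_path):
    """Three hand-built reports: joins are hand-counted in the tests."""
    _write(tmp_path, "DEMO.txt",
           "primaryid$caseid$fda_dt$event_dt$age$sex$wt$occr_country$occp_cod",
           ["101$11$20230105$20230201$63$F$70$US$MD",
            "102$12$20230110$$$M$$JP$CN",
            "103$13$20230120$$41$$$US$"])
    _write(tmp_path, "DRUG.txt",
           "primaryid$caseid$drug_seq$role_cod$drugname",
           ["101$11$1$PS$ Avacopan ",
            "101$11$2$C$RITUXIMAB",
            "102$12$1$PS$IBUPROFEN",
            "103$13$1$C$AVACOPAN",
            "999$99$1$PS$ORPHANDRUG"])  # orphan: no DEMO row
    _write(tmp_path, "REAC.txt", "primaryid$caseid$pt",
           ["101$11$Nausea", "101$11$JAUNDICE", "101$11$nausea",
            "102$12$RASH", "103$13$NAUSEA"])
    _write(tmp_path, "OUTC.txt", "primaryid$caseid$outc_cod",
           ["101$11$HO", "102$12$DE"])
    _write(tmp_path, "THER.txt", "primaryid$caseid$dsg_drug_seq$start_dt",
           ["101$11$1$20230101"])
    _write(tmp_path, "INDI.txt", "primaryid$caseid$indi_drug_seq$indi_pt",
           ["101$11$1$ANCA ASSOCIATED VASCULITIS"])
    return tmp_path


class TestParse:
    def test_hand_built_fixture_joins(self, quarter_dir):
        with pytest.warns(UserWarning, match="orphan"):
            rs = parse_quarter_files(quarter_dir)
        assert rs.n_reports == 3
        # report 101: duplicate "nausea" row collapses; names normalised
        recs = {r.primaryid: r for r in rs.records()}
        assert recs["101"].reactions == {"NAUSEA", "JAUNDICE"}
        assert {d.name for d in recs["101"].drugs} == {"AVACOPAN",
                                                       "RITUXIMAB"}
        assert recs["101"].drugs[0].start_dt == "20230101"
        assert recs["101"].outcomes == {"HO"}
        assert recs["102"].sex == "male" and recs["102"].age is None
        assert recs["103"].age == 41
        assert rs.n_events == 4  # (101,NAUSEA),(101,JAUNDICE),(102,RASH),(103,NAUSEA)

    def test_missing_mandatory_column_names_file_and_column(self, tmp_path):
        _write(tmp_path, "DEMO.txt", "primaryid$caseid", ["1$1"])
        with pytest.raises(ParseError, match="fda_dt"):
            parse_quarter_files(tmp_path)

    def test_empty_reac_file_gives_empty_reaction_sets(self, tmp_path):
        _write(tmp_path, "DEMO.txt", "primaryid$caseid$fda_dt",
               ["1$1$20230101"])
        _write(tmp_path, "REAC.txt", "primaryid$caseid$pt", [])
        rs = parse_quarter_files(tmp_path)
        assert rs.n_reports == 1 and rs.n_events == 0
        assert next(rs.records()).reactions == frozenset()

    def test_generator_roundtrip(self, tmp_path, small_bundle):
        """parse(write(bundle)) reproduces reports, events and drugs."""
        small_bundle.write(tmp_path / "q")
        rs = parse_quarter_files(tmp_path / "q")
        direct = ingest.bundle_to_reports(small_bundle)
        assert rs.n_reports == direct.n_reports
        assert rs.n_events == direct.n_events
        key = ["primaryid", "pt"]
        pd.testing.assert_frame_equal(
            rs.reactions.sort_values(key).reset_index(drop=True),
            direct.reactions.sort_values(key).reset_index(drop=True))
        pd.testing.assert_frame_equal(
            rs.drugs.sort_values(["primaryid", "drugname"])
              .reset_index(drop=True),
            direct.drugs.sort_values(["primaryid", "drugname"])
              .reset_index(drop=True))


class TestDeduplicate:
    def test_later_fda_dt_survives(self):
        rs = make_report_set([
            {"primaryid": "1", "caseid": "c", "fda_dt": "20230101"},
            {"primaryid": "2", "caseid": "c", "fda_dt": "20230301"},
        ])
        out = deduplicate(rs)
        assert list(out.demo["primaryid"]) == ["2"]

    def test_date_tie_numeric_primaryid_wins(self):
        rs = make_report_set([
            {"primaryid": "998", "caseid": "c", "fda_dt": "20230101"},
            {"primaryid": "1002", "caseid": "c", "fda_dt": "20230101"},
        ])
        out = deduplicate(rs)
        assert list(out.demo["primaryid"]) == ["1002"]

    def test_unparseable_date_never_beats_dated(self):
        rs = make_report_set([
            {"primaryid": "9", "caseid": "c", "fda_dt": "NOTADATE"},
            {"primaryid": "1", "caseid": "c", "fda_dt": "20220101"},
        ])
        out = deduplicate(rs)
        assert list(out.demo["primaryid"]) == ["1"]

    def test_second_round_collapses_duplicate_primaryids(self):
        rs = make_report_set([
            {"primaryid": "5", "caseid": "a", "fda_dt": "20230101"},
            {"primaryid": "5", "caseid": "b", "fda_dt": "20230201"},
        ])
        out = deduplicate(rs)
        assert list(out.demo["primaryid"]) == ["5"]
        assert len(out.demo) == 1

    def test_idempotent(self, report_set):
        once = deduplicate(report_set)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once.demo, twice.demo)

    def test_empty_input(self):
        out = deduplicate(ReportSet.empty())
        assert out.n_reports == 0

    def test_recovers_generator_ground_truth(self, small_bundle):
        dup, truth = synthetic.inject_duplicates(small_bundle, 0.4, seed=21)
        out = deduplicate(ingest.bundle_to_reports(dup))
        got = dict(zip(out.demo["caseid"], out.demo["primaryid"]))
        want = dict(zip(truth["caseid"], truth["primaryid"]))
        assert got == want


class TestFilterPrimarySuspect:
    def test_role_rule(self, quarter_dir):
        with pytest.warns(UserWarning):
            rs = parse_quarter_files(quarter_dir)
        out = filter_primary_suspect(rs, ["AVACOPAN", "TAVNEOS"])
        # 101 has avacopan as PS; 103 carries it only as C
        assert set(out.demo["primaryid"]) == {"101"}

    def test_empty_synonyms_rejected(self, toy_reports):
        with pytest.raises(ValueError):
            filter_primary_suspect(toy_reports, [])

    def test_count_matches_bundle_ground_truth(self, small_bundle):
        rs = ingest.bundle_to_reports(small_bundle)
        ps = small_bundle.drug[
            (small_bundle.drug["role_cod"] == "PS")
            & (small_bundle.drug["drugname"] == "AVACOPAN")]
        out = filter_primary_suspect(rs, ["AVACOPAN"])
        assert out.n_reports == ps["primaryid"].nunique()
        assert out.n_reports <= rs.n_reports

    def test_commutes_with_deduplication(self, small_bundle):
        dup, _ = synthetic.inject_duplicates(small_bundle, 0.3, seed=5)
        rs = ingest.bundle_to_reports(dup)
        a = filter_primary_suspect(deduplicate(rs), ["AVACOPAN"])
        b = deduplicate(filter_primary_suspect(rs, ["AVACOPAN"]))
        assert set(a.demo["primaryid"]) == set(b.demo["primaryid"])


class TestSocMapping:
    def test_hepatobiliary_terms_map_together(self, default_map):
        assert default_map.get("Jaundice") == "HEPATOBILIARY DISORDERS"
        assert default_map.get("  cholestasis ") == "HEPATOBILIARY DISORDERS"

    def test_strict_policy_raises_listing_terms(self, toy_reports):
        m = MeddraMap({"HEADACHE": "NEURO"})
        with pytest.raises(KeyError, match="NAUSEA"):
            map_pt_to_soc(toy_reports, m, policy="strict")

    def test_lenient_policy_buckets_unmapped(self, toy_reports):
        m = MeddraMap({"HEADACHE": "NEURO"})
        with pytest.warns(UserWarning, match="UNMAPPED"):
            out = map_pt_to_soc(toy_reports, m, policy="lenient")
        socs = set(out.reactions["soc"])
        assert socs == {"NEURO", "UNMAPPED"}

    def test_soc_counts_equal_hand_tally(self, toy_reports):
        m = MeddraMap({"HEADACHE": "NEURO", "NAUSEA": "GI", "RASH": "SKIN"})
        out = map_pt_to_soc(toy_reports, m)
        tally = out.reactions.groupby("soc").size().to_dict()
        assert tally == {"NEURO": 2, "GI": 3, "SKIN": 3}

    def test_empty_reactions_pass_through(self):
        rs = make_report_set([{"primaryid": "1"}])
        out = map_pt_to_soc(rs, MeddraMap({}), policy="strict")
        assert out.n_events == 0

    def test_event_count_matches_generator(self, small_bundle):
        rs = ingest.bundle_to_reports(small_bundle)
        assert rs.n_events == len(
            small_bundle.reac[["primaryid", "pt"]].drop_duplicates())


def test_load_synonyms(tmp_path):
    p = tmp_path / "syn.txt"
    p.write_text("# comment\n avacopan\nTAVNEOS  # brand\n\n")
    assert ingest.load_synonyms(p) == ["AVACOPAN", "TAVNEOS"]
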