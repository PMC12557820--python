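"""Shared fixtures: synthetic bundles and a hand-built toy report set."""

import pandas as pd
import pytest

from pvsignals import ingest, synthetic
from pvsignals.core import ReportSet


@pytest.fixture(scope="session")
def small_config() -> synthetic.SimConfig:
    return synthetic.SimConfig(n_reports=400, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> synthetic.RawBundle:
    return synthetic.simulate_reports(small_config)


@pytest.fixture(scope="session")
def calibration_bundle() -> synthetic.RawBundle:
    """A larger bundle for marginal-calibration checks."""
    return synthetic.simulate_reports(
        synthetic.SimConfig(n_reports=10_000, seed=3))


@pytest.fixture(scope="session")
def default_map() -> ingest.MeddraMap:
    return ingest.MeddraMap(synthetic.default_pt_soc_map())


@pytest.fixture(scope="session")
def report_set(small_bundle, default_map) -> ReportSet:
    """Deduplicated, SOC-annotated report set from the small bundle."""
    bundle, _ = synthetic.inject_duplicates(small_bundle, 0.15, seed=12)
    rs = ingest.deduplicate(ingest.bundle_to_reports(bundle))
    return ingest.map_pt_to_soc(rs, default_map)


def make_report_set(reports) -> ReportSet:
    """Build a ReportSet from compact per-report dicts (tests only).

    Each dict: primaryid, caseid, fda_dt, optional event_dt/age/sex, drugs
    as (name, role[, start_dt]) tuples, pts as strings, outcomes as codes.
    """
    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
    for r in reports:
        demo_rows.append({
            "primaryid": r["primaryid"], "caseid": r.get("caseid",
                                                         r["primaryid"]),
            "fda_dt": r.get("fda_dt", "20230101"),
            "event_dt": r.get("event_dt", ""),
            "age": r.get("age", ""), "sex": r.get("sex", ""),
            "wt": "", "occr_country": "US", "occp_cod": "MD",
        })
        for d in r.get("drugs", ()):
            name, role = d[0], d[1]
            start = d[2] if len(d) > 2 else ""
            drug_rows.append({"primaryid": r["primaryid"], "drugname": name,
                              "role_cod": role, "start_dt": start})
        for pt in r.get("pts", ()):
            reac_rows.append({"primaryid": r["primaryid"], "pt": pt})
        for oc in r.get("outcomes", ()):
            outc_rows.append({"primaryid": r["primaryid"], "outc_cod": oc})
    empty = ReportSet.empty()
    return ReportSet(
        demo=pd.DataFrame(demo_rows) if demo_rows else empty.demo,
        drugs=pd.DataFrame(drug_rows) if drug_rows else empty.drugs,
        reactions=(pd.DataFrame(reac_rows).drop_duplicates()
                   if reac_rows else empty.reactions),
        outcomes=pd.DataFrame(outc_rows) if outc_rows else empty.outcomes,
        indications=empty.indications,
    )


@pytest.fixture()
def toy_reports() -> ReportSet:
    """Six hand-tallied reports: 3 for drug X, 3 comparator."""
    return make_report_set([
        {"primaryid": "1", "drugs": [("X", "PS")],
         "pts": ["HEADACHE", "NAUSEA"]},
        {"primaryid": "2", "drugs": [("X", "PS")], "pts": ["NAUSEA"]},
        {"primaryid": "3", "drugs": [("X", "PS")], "pts": ["RASH"]},
        {"primaryid": "4", "drugs": [("Y", "PS")], "pts": ["HEADACHE"]},
        {"primaryid": "5", "drugs": [("Y", "PS")], "pts": ["NAUSEA", "RASH"]},
        {"primaryid": "6", "drugs": [("Z", "PS")], "pts": ["RASH"]},
    ])
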