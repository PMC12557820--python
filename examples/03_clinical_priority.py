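"""Clinical prioritisation of detected signals.

Every term positive in at least one algorithm is scored 0-2 on four
criteria — designation-list relevance (DME/IME), cases-to-non-cases
reporting rate, signal stability across the four algorithms, and case
fatality — and banded low (0-2), moderate (3-5) or high (6-8).
"""

from pvsignals import ingest, priority, signals
from pvsignals.pipeline import default_data_path
from pvsignals.synthetic import (SimConfig, default_pt_soc_map,
                                 simulate_reports)

cfg = SimConfig(n_reports=8000, seed=7)
rs = ingest.deduplicate(ingest.bundle_to_reports(simulate_reports(cfg)))
rs = ingest.map_pt_to_soc(rs, ingest.MeddraMap(default_pt_soc_map()))
rs_ps = ingest.filter_primary_suspect(rs, ["AVACOPAN"])

sig = signals.compute_signal_table(rs, ["AVACOPAN"], level="PT")
desig = priority.DesignationLists.from_files(
    default_data_path("ime_terms_synthetic.tsv"),
    default_data_path("dme_terms_synthetic.tsv"))
assessed = priority.prioritize(sig, rs_ps, desig)

cols = ["term", "n", "reporting_rate", "cfr", "relevance",
        "n_pos_algorithms", "total", "band"]
print(assessed[cols].head(12).to_string(index=False))
print(f"\n{len(assessed)} terms assessed: "
      + ", ".join(f"{b}={n}" for b, n in
                  assessed['band'].value_counts().items()))
# reporting_rate is cases per 100 non-cases; cfr the percentage of the
# term's reports with a death outcome.  DME-designated rare liver events
# rank above common but benign background terms.
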