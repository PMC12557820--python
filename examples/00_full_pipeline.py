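"""The whole analysis in one call.

Simulates a quarter of FAERS-style tables on disk, then runs the pipeline:
ingest -> dedup -> primary-suspect filter -> SOC annotation -> four-algorithm
signal detection -> clinical prioritisation -> time-to-onset -> risk model.
All result tables land as TSVs with a manifest recording the config hash.
"""

from pathlib import Path

from pvsignals.pipeline import PipelineConfig, run_pipeline
from pvsignals.synthetic import SimConfig, inject_duplicates, simulate_reports

base = Path("scratch_example_pipeline")
cfg = SimConfig(n_reports=5000, seed=3)
bundle, _ = inject_duplicates(simulate_reports(cfg), cfg.duplicate_rate,
                              seed=4)
bundle.write(base / "2023Q1")

results = run_pipeline(PipelineConfig(quarter_dirs=[str(base / "2023Q1")],
                                      out_dir=str(base / "out")))
for name, df in sorted(results.items()):
    print(f"{name:18s} {len(df):4d} rows")
print(f"\noutputs under {base / 'out'}")
# Each TSV mirrors one table of a pharmacovigilance report: descriptive
# counts, SOC- and PT-level signal strength, priority bands, onset bins,
# and the case/non-case odds ratios.
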