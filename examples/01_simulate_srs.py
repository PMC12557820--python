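"""Generate a synthetic spontaneous-reporting database.

Builds a seeded FAERS-style database of 3,150 reports with planted
hepatobiliary signals for the target drug, injects duplicate report
versions, and writes the six '$'-delimited tables plus the ground-truth
survivor list.  The printed counts show the shape of the raw material every
later stage consumes.
"""

from pathlib import Path

from pvsignals.synthetic import SimConfig, inject_duplicates, simulate_reports

cfg = SimConfig(n_reports=3150, seed=1)
bundle = simulate_reports(cfg)
bundle, truth = inject_duplicates(bundle, cfg.duplicate_rate, seed=2)

out = Path("scratch_example_srs")
bundle.write(out)
truth.to_csv(out / "ground_truth_survivors.tsv", sep="\t", index=False)

n_versions = len(bundle.demo)
n_cases = bundle.demo["caseid"].nunique()
print(f"report versions written : {n_versions}")
print(f"distinct cases          : {n_cases}")
print(f"duplicate versions      : {n_versions - n_cases}")
print(f"reaction rows           : {len(bundle.reac)}")
print(f"events per case         : {len(bundle.reac.drop_duplicates(['caseid', 'pt'])) / n_cases:.2f}")
print(f"tables in {out}/        : "
      + ", ".join(sorted(p.name for p in out.glob('*.txt'))))
# The duplicate versions are the problem the deduplication stage solves;
# the ground-truth file records which version must survive.
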