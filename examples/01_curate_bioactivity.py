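"""Curate a raw bioactivity table into the three task datasets.

Builds a synthetic table (with salts, censored records, duplicates and
conflicting duplicates planted at known positions), runs the full curation
workflow for each task, and prints the per-rule bookkeeping.
"""

import hergsuite as hs

library = hs.make_library(200, seed=11)
spec = hs.FixtureSpec(n_compounds=200, seed=11)   # noise_sd 0.3 by default
table, truth = hs.plant_activity(library, spec)
print(f"raw records: {len(table.records)} "
      f"({len(truth['duplicate_ids'])} duplicated, "
      f"{len(truth['conflict_ids'])} with conflicting outcomes, "
      f"{len(truth['qualifier_ids'])} censored '>' rows)")

for task in ("binary", "multiclass", "regression"):
    ds = hs.curate_dataset(table, hs.CurationConfig(task=task))
    r = ds.report.as_dict()
    print(f"\n{task}: kept {r['kept']} compounds")
    for rule in ("qualifier_excluded", "duplicate_conflict",
                 "duplicate_high_sd", "duplicate_merged"):
        if r[rule]:
            print(f"  {rule:20s} {r[rule]:4d} records")
    if task == "regression" and "experimental_mae" in r:
        # mean |pIC50 - group mean| over duplicate measurements: an estimate
        # of the experimental error floor no model can beat
        print(f"  experimental MAE from duplicates: {r['experimental_mae']:.3f}")
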