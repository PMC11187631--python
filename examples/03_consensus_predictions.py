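"""Full pipeline: three tasks, one weighted consensus call per compound.

The binary model carries weight 0.6; multiclass and regression carry 0.2
when they agree with it (on the blocker/nonblocker dichotomy) and 0.1 when
they do not.  A compound is called a blocker when the weighted level sum
reaches 2 — a lone binary "blocker" (score 1.8) is not enough.
"""

import hergsuite as hs

library = hs.make_library(250, seed=17)
table, _ = hs.plant_activity(library, hs.FixtureSpec(n_compounds=250, seed=17))

config = hs.RunConfig(output_dir="scratch/consensus_run",
                      hyperparameters={"binary": {"max_iter": 60},
                                       "multiclass": {"n_estimators": 60}})
report = hs.run_pipeline(config, table=table)

print(report[["smiles", "binary_label", "multiclass_label", "predicted_pic50",
              "consensus_score", "consensus_call"]].head(8).to_string(index=False))
print(f"\ncalls: {report['consensus_call'].value_counts().to_dict()}")

overruled = report[(report.binary_label == "blocker")
                   & (report.consensus_call == "nonblocker")]
print(f"binary 'blocker' overruled by the consensus: {len(overruled)} compounds")

kappa = hs.cohens_kappa(
    report.binary_label,
    ["blocker" if l != "nonblocker" else "nonblocker"
     for l in report.multiclass_label])
print(f"binary vs multiclass agreement (Cohen's kappa): {kappa:.3f}")
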