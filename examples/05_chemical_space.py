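"""Chemical-space diagnostics before modeling.

Checks that the three assay contexts (SP patch clamp, HEK293 and CHO cell
lines) correlate well enough to merge, measures inter-set diversity with
mean cross-set Tanimoto, hunts activity cliffs at 80% MACCS similarity,
and embeds the library in 2D with t-SNE.
"""

import numpy as np

import hergsuite as hs

library = hs.make_library(150, seed=29)
# extra duplicate measurements so enough compounds appear in two assays
table, _ = hs.plant_activity(
    library, hs.FixtureSpec(n_compounds=150, duplicate_fraction=0.3,
                            conflict_fraction=0.02, seed=29))

# records of the same compound in different assays: correlate before merging
corr = hs.assay_correlation(
    r.with_pic50() for r in table.records if r.relation == "eq")
for (a, b), (r, p, n) in sorted(corr.items()):
    print(f"{a} vs {b}: Pearson r {r:.2f} (p {p:.2g}, n {n})")

dataset = hs.curate_dataset(table, hs.CurationConfig(task="regression"))
spec = hs.FingerprintSpec(family="maccs")
fps = hs.featurize_dataset(dataset, spec)

half = len(dataset) // 2
mean_sim = hs.cross_set_tanimoto(fps.bits[:half], fps.bits[half:])
print(f"\nmean cross-set Tanimoto (two halves): {mean_sim:.3f} "
      f"(low = chemically diverse sets)")

cliffs = hs.find_cliffs(dataset, spec, similarity_cutoff=0.8, potency_gap_min=1.0)
print(f"activity cliffs at 80% similarity: {len(cliffs)} pairs")
for c in cliffs[:3]:
    print(f"  sim {c.similarity:.2f}  pIC50 {c.pic50_a:.2f} vs {c.pic50_b:.2f} "
          f"(gap {c.potency_gap:.2f})")

cont, disc, g_cont, g_disc = hs.continuity_discontinuity(dataset, spec, cutoff=0.8)
print(f"global SAR continuity {g_cont:.3f}, discontinuity {g_disc:.3f} "
      f"(high discontinuity = cliff-rich landscape)")

coords = hs.embed_2d(hs.featurize_dataset(dataset, hs.FingerprintSpec("fcfp", 2, 1024)),
                     seed=42)
print(f"t-SNE embedding: {coords.shape[0]} points, "
      f"x range [{coords[:, 0].min():.1f}, {coords[:, 0].max():.1f}]")
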