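# Methods

This note records the scientific and numerical choices behind hergsuite:
what each stage computes, the parameters that matter, what the synthetic
data generator does and does not emulate, and where the design was
genuinely open.

## Problem setting

Blockage of the hERG potassium channel delays cardiac repolarization and
can cause fatal arrhythmia, so candidate compounds are screened against
hERG early.  Public bioactivity databases hold tens of thousands of hERG
IC50 measurements from heterogeneous assays (single-protein patch clamp,
HEK293 and CHO cell lines) with censored values, duplicated measurements
and inconsistent structure drawing.  hergsuite turns such tables into
three supervised tasks — binary blocker classification, three-tier
multiclass classification, and pIC50 regression — and combines their
predictions into one interpretable consensus call.

## Curation

Order of operations: structure standardization → unit conversion and
pIC50 → qualifier filtering → labeling → duplicate resolution.  The order
matters: deduplication keys on the *standardized* structure, so salt forms
and stereoisomers of one parent collapse into one duplicate group rather
than surviving as distinct compounds.

Standardization keeps the largest organic (carbon-containing) fragment,
applies the RDKit normalization transforms (nitro, N-oxide, azide and
related chemotypes), neutralizes charges, and strips stereo descriptors.
Structures with no organic fragment are removed as inorganic; two or more
*distinct* organic fragments constitute a mixture (identical fragments,
e.g. a dimer drawing, are collapsed).  Stereo-bearing records are not
deleted outright: flattening followed by ordinary duplicate resolution is
the behavior consistent with standard curation workflows, and it keeps the
information when the flattened duplicates agree.

Qualifier rules (classification): "> v" with v < 10 μM says only "weaker
than an active-range bound" — uninformative, excluded; "> v" with
v ≥ 10 μM is a definite inactive; "< v" with v ≤ 10 μM a definite active;
"< v" with v > 10 μM excluded.  Regression uses exact values only.  The
"≤"/"≥" relations are folded into "<"/">" (a conservative superset — the
boundary case is treated identically).

Class boundaries: nonblocker iff pIC50 ≤ 5 (IC50 ≥ 10 μM); multiclass
strong iff pIC50 ≥ 6, moderate/weak in [5, 6).  The point pIC50 = 5.0 is
the one documented asymmetry: multiclass moderate/weak but binary
nonblocker, because the operational rule "IC50 ≥ 10 μM is inactive" is
inclusive.  Boundary comparisons carry a 1e−12 relative slack: unit
conversion leaves values an ulp off the 10 μM boundary, and no assay
reports 12 significant digits.

Duplicate resolution: classification groups keep one record of the
strict-majority label and drop the whole group on a tie; regression groups
with sample (n−1) SD of pIC50 above 0.2 are dropped, otherwise one
compound is kept at the arithmetic-mean pIC50 (unbiased under the SD
gate).  Before removal, the duplicate groups yield the *experimental MAE*
— the record-weighted mean absolute deviation from each group's mean — an
estimate of the irreducible assay error that regression metrics should be
compared against.

Bookkeeping: every input record ends in exactly one counter (unparseable /
inorganic / mixture / qualifier_excluded / duplicate_conflict /
duplicate_high_sd / duplicate_merged / kept), so
`kept + Σ counters = input records` always holds exactly.
`duplicate_merged` counts records absorbed into a kept compound; without
it, merging n same-label records into one compound would break exact
conservation.

## Fingerprints

Hashed circular fingerprints: ECFP (atom-type invariants) and FCFP
(pharmacophoric feature invariants), radius 2 (diameter 4), 1024 or 2048
bits; defaults ecfp/1024.  MACCS keys are exposed with the field-standard
166 columns (RDKit's placeholder key 0 is dropped).  The bit →
atom-environment map retains every environment that set a bit, so hash
collisions are visible to the attribution code rather than silently
merged.

## Models and validation

Algorithms per task: random forest, kNN, SVM (RBF; ε-SVR for regression),
and two gradient-boosting variants — `gbt_light`
(HistGradientBoosting, the histogram/leaf-wise family) and `gbt_extreme`
(classic stagewise GradientBoosting).  Splits: stratified shuffle, 20%
test, fixed seed 42; regression stratifies on equal-frequency pIC50 bins
(5 by default) so the test set spans the potency range.  5-fold CV reports
per-metric mean ± SD.  Binary metrics take "blocker" as the positive
class; multiclass metrics are macro one-vs-rest averages and BACC is the
mean per-class recall (the most common convention; a weighted variant
would change only the averaging step).

Y-randomization retrains on labels permuted with seed `seed + r` for round
r — reproducible yet uncorrelated across rounds — and evaluates on the
untouched test split; a real model must sit far above the scrambled
distribution, which itself must straddle chance.

Hyperparameter tuning is sequential model-based optimization: random
initial trials, then a Matérn-5/2 Gaussian-process surrogate over the
unit-encoded search space with expected-improvement acquisition maximized
over 256 random candidates.  Search spaces ship as editable per-algorithm
defaults; the objective is mean CV BACC (classification) or R²
(regression), and the full trial log is returned.

Applicability domain: a query is in-domain when its mean Euclidean
distance to its k nearest training fingerprints is at most
D_c = mean + z·SD (population SD) of the training set's leave-self-out
k-NN distances; defaults k = 1, z = 0.5 (the convention of distance-based
AD estimation).  The verdict is a flag plus the raw distance — reliability
information, never suppression of a prediction.

## Consensus

Levels: nonblocker 0, weak 1, moderate(/weak) 2, strong 3, binary blocker
3.  Score = 0.6·L_bin + w_m·L_multi + w_r·L_reg, where the auxiliary
weight is 0.2 on agreement with the binary blocker/nonblocker dichotomy
and 0.1 on disagreement; call = blocker iff score ≥ 2 (with 1e−9 slack:
0.6·3 + 0.2 lands one ulp below 2 in binary floating point).  The
regression output maps to labels as strong ≥ 6, moderate [5, 6), weak
[4.5, 5), nonblocker < 4.5; for agreement purposes any non-nonblocker
label counts as "blocker".  This encoding reproduces the intended
threshold-2 behavior: unanimity is decisive in both directions, and a lone
binary "blocker" (score 1.8) is overruled unless at least one auxiliary
model lends support — which also reproduces the known failure mode where
the heavily weighted binary model steers borderline cases toward
"blocker" once any support exists.  All weights, the level encoding and
the threshold are config-exposed.

## Shapley interpretation

`shap` is not a dependency; the tree explainer is implemented here as
*exact interventional* Shapley values: for background sample z, the
coalition value v(S) is the model's raw output on the hybrid point taking
features in S from the query and the rest from z.  Root-to-leaf path
enumeration with the closed-form weights (k−1)!·m!/(k+m)! gives the exact
Shapley values of that game per tree; summing over trees and averaging
over the background preserves exactness, and additivity
(base + Σφ = raw output) holds to float round-off.  Raw output is the
positive-class probability for forests and the raw decision score for
boosted models.  kNN/SVM models fall back to a seeded kernel-regression
approximation (Shapley-kernel-weighted least squares over random
coalitions, with the efficiency constraint eliminated into the design so
additivity still holds exactly; the per-feature values are approximate).

Atom maps: each on-bit's attribution is split equally across the atom
environments that set it (collision split), then equally across the atoms
of each environment, so the atom-weight sum equals the on-bit attribution
sum exactly.  An occlusion alternative (`method="masking"`: output drop
when an atom's bits are cleared) is provided since fragment "probability
maps" in the literature are produced both ways; it carries no conservation
guarantee.  By default explanations target the binary model (the
compute-heavy path in production services); other models are explained by
passing their bundle explicitly.

## Chemical space

Assay correlation matches compounds measured in two assay contexts by
standardized SMILES (per-assay mean pIC50) and reports Pearson r with the
two-sided t-distribution p-value (n−2 df), requiring n ≥ 3.  Cross-set
mean Tanimoto quantifies inter-set diversity (self-pairs excluded in
same-set mode).  Activity cliffs: pairs with Tanimoto ≥ 0.8 (MACCS by
default — the compact key set clusters analogue series well) and either
opposing binary labels or |ΔpIC50| ≥ 1.0 log unit (an explicit gate, since
"large variation" is qualitative).  Raw SAR scores per compound:
continuity = potency-product-weighted mean of 1/similarity over pairs
(zero-similarity pairs excluded), discontinuity = mean of |ΔpIC50| ×
similarity over pairs above the cutoff; Z-normalization against a
reference panel is out of scope.  2D embedding is t-SNE with fixed seed
and PCA initialization.

## Synthetic data

`make_library` enumerates substituent combinations on six drug-like
scaffolds — syntactic substitution of branch-safe fragments, guaranteeing
chemical validity without a generative model — canonicalizes, deduplicates
and shuffles deterministically.  `plant_activity` draws the latent potency
as pIC50 = 4.5 + effect·(planted signal bits set) + N(0, noise_sd): the
4.5 intercept puts nonsignal compounds below every class boundary, so
expected label and removal counts are closed-form.  Anomalies are injected
in disjoint index ranges with full bookkeeping: exact duplicates (merged,
SD 0), conflicting duplicates (the extra record sits on the far side of
10 μM, so classification removes the group as a conflict and regression as
high-SD), censored "> 5 μM" rows (excluded by every task), and ·HCl salt
forms (standardize back to the parent).

Defaults are fixed once: 400 compounds, 3 auto-picked signal bits (library
frequency nearest 0.4, balancing the classes), effect 1.0 log unit,
noise_sd 0.3 (comparable to the ~0.3 log-unit experimental scatter seen in
public hERG duplicates), fractions 10/5/5/10%.  Noise-free variants
(noise_sd = 0) are used where a test needs analytic separability.

What the generator does *not* emulate: real hERG pharmacophores, ChEMBL's
property distributions, assay-dependent systematic bias, or activity
cliffs arising from single-atom changes.  A green test on this fixture
therefore establishes pipeline correctness (bookkeeping, thresholds,
metric formulas, signal recovery, attribution exactness) — not predictive
accuracy on real chemistry, which depends on real training data.

## Known limitations

* Kernel-approximation Shapley values for kNN/SVM are estimates; only the
  efficiency (additivity) property is exact.
* The exact tree explainer's path enumeration is exponential in the number
  of *diverging unique features per path* — negligible for the shallow
  trees used here, but deep trees with many forks per path would be slow.
* Censored "<" records kept for the multiclass task are tiered at their
  bound (the weakest consistent tier), which can under-tier a strong
  blocker reported only as "< 1 μM".
* t-SNE determinism is per seed and platform; coordinates are for
  visualization, not features.
* Hyperparameter search spaces are pragmatic defaults, not a transcription
  of any published search protocol.
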