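# Methods

## Study design modeled

The package analyzes two linked designs.  The animal arm is a rat model of
Type 2 diabetes (high-fat diet plus low-dose streptozotocin) with n = 6
animals per group, each contributing five sources: pancreas, liver,
adipose, skeletal muscle and whole blood.  The human arm is a whole-blood
cohort of adult males split into healthy controls, impaired fasting glucose
(IFG) and newly diagnosed, medication-naive T2D, with technical replicates
per subject.  Both arms are profiled on miRNA microarrays normalized to the
U6 snRNA probe; validation uses stem-loop RT-PCR referenced to 18S rRNA.

## Preprocessing

*Detection.*  A probe is detected in a (species, source) stratum iff its
mean background-subtracted intensity across the stratum's samples is
**strictly greater than 300**.  The boundary is read literally ("above
300") and covered by a dedicated test at 300 vs 301.  Detection is computed
on the stratum mean, not per sample, and is applied **before**
normalization; the pipeline asserts this order.

*U6 normalization.*  Each array is rescaled so its U6 intensity equals the
across-array geometric mean of U6.  Anchoring to the geometric mean rather
than to an arbitrary first sample makes the operation sample-order
invariant and idempotent (tested to 1e-12 relative).  Within-array ratios
are untouched.

*mRNA prefilter.*  Illumina-convention cuts p < 0.05, |Diff score| > 20,
average signal > 100, all strict.  When the user supplies only p-values a
Diff score is derived as 10·sgn(case−control)·(−log10 p) (|20| ↔ p = 0.01).

## Differential statistics

Tests run on log2 intensities (variance stabilization); fold changes are
ratios of linear group means, reported with the negative-reciprocal
convention (r if r ≥ 1 else −1/r), so |signed FC| ≥ 1 and the mapping from
ratio to signed FC is strictly increasing and antisymmetric.

The two-group test is Welch's unequal-variance t (the plain "two-tailed
t-test" of common array practice; the pooled-variance variant is a
negligible difference at n = 6 vs 6 and Welch is safer under heteroscedastic
intensities).  Degenerate inputs (fewer than two values per group, or zero
variance in both) report p = 1 with a flag rather than failing.  For
three-way human comparisons (control/IFG/T2D) a one-way ANOVA with Fisher's
LSD pairwise p-values is available as an alternative.

Subjects are the unit of replication: replicate arrays of one subject are
averaged before testing.  The replication fraction counts case subjects
whose ratio against the control-group mean lies strictly on the group's
side of 1; a ratio of exactly 1 never replicates, and the 50 % threshold is
inclusive ("at least half").

Benjamini–Hochberg q-values are attached to every record for information,
but the default filtering uses raw p < 0.05 — the filter chain
(significance AND ±1.5-fold AND 50 % replication, then all-source
concordance, then cross-species agreement) is itself a strong guard against
false discovery, and the recovery experiments bear this out (mean false
positives ≈ 0 over 20 seeds at default noise).

## Signature selection

The Venn diagram of "significant changes" uses the p < 0.05 flag only; the
±1.5-fold cut is a later focusing step, so the signature is a subset of the
all-source Venn region (asserted).  Cross-source selection requires all
three filter flags in every source plus a single sign of change across
sources.  Cross-species concordance is keyed to the human **T2D** contrast
(significant and same direction as the rat change); IFG fold changes are
recorded on each entry but deliberately excluded from the concordance rule,
because discordant pre-diabetic behaviour (miR-30d and miR-182 moving
upward in IFG while falling in T2D) is a finding, not noise.  Probe-name
reconciliation between array generations uses a small user-suppliable alias
table (default: miR-320 ≡ miR-320a).

## Targets

Prediction databases are static two-column tables; the five named web
services are never queried (they have changed since the era the analysis
models, and reproducibility demands frozen inputs).  A pair is accepted at
≥ 3 votes of k = 5.  Pair evaluation labels *inverse* when directions
strictly oppose, *concordant* when directions agree and both magnitudes
pass the ±1.5 cut (the RNA-activator pattern), *null* otherwise, including
flat (±1.0) profiles and missing mRNA records (warned).  The
insulin-signaling panel (INSR, GLUT4/SLC2A4, IRS1, CBL, FOXO1, PTPN1,
INS/INS1/INS2, AKT2) is a reporting subset only.

## qPCR arithmetic

ΔCt = Ct(target) − Ct(reference) per replicate, with the group-mean
reference Ct (plate replicates of target and reference are not paired).
ΔCt is averaged per group before ΔΔCt; fold change is E^−ΔΔCt with
amplification efficiency E fixed at 2 by default (an efficiency parameter
exists).  The SEM of the fold change is propagated by the delta method:
SEM(FC) = FC·ln E·√(SEM²(ΔCt case) + SEM²(ΔCt control)).  The raw positive
ratio is kept everywhere; the negative-reciprocal signed convention is a
rendering choice (`signed_from_ratio`), since published reports are
inconsistent about applying it to ratios below 1.

Exact identities tested: one-cycle ΔΔCt = −1 doubles expression;
swap-of-groups product equals 1 to 1e-12; adding a constant to every Ct on
a plate changes nothing.

## Clustering, PCA, correlation

Profiles are log2 fold-change vectors.  Distances are Euclidean over
pairwise-complete features, rescaled by √(p/m) (p features, m shared) so
profiles with different detection patterns remain comparable; a pair with
no shared feature is an error, not a silent zero.  Linkage is average
(UPGMA); merge heights are non-decreasing; ties break toward the
lowest-index pair (scipy's deterministic order).  The tree serializes to
Newick with branch lengths that partition merge heights.  Equality with a
brute-force average-linkage construction is asserted on 100 random
instances of up to 8 profiles.

PCA centers columns internally, drops features missing in any profile, and
fixes each component's sign so its largest-magnitude loading is positive
(bit-reproducible output).  Requested components beyond the rank truncate
with a warning.  Full-component reconstruction error ≤ 1e-8 relative and
variance-fraction conservation are tested.

Per-subject heatmap/PCA profiles can be built per subject or pooled; both
modes exist because published figures rarely state which was used.

## Synthetic data generator

Log-normal intensity model:
log2 I = baseline(feature, source) + effect(feature, stratum) +
jitter(sample) + N(0, noise_sd).  The per-array multiplicative jitter
(log2 sd 0.2) applies to all probes including U6, so U6 normalization has a
real array effect to remove; U6 itself carries only the jitter.  Dropout
(rate 0.05) is simulated by re-drawing a low baseline (log2 ∈ [4, 7], below
the detection threshold) for the affected (background feature, source) —
cells are never deleted, so the detection filter is genuinely exercised.

Defaults are the modeled study conditions: 200 background miRNAs per
source, n = 6 subjects per group, noise_sd 0.25 (log2), baseline log2 mean
11 and sd 0.8 (chosen so essentially all non-dropout background probes sit
comfortably above the 300 threshold), U6 at 5000.  Planted effects use the
printed fold changes where available (miR-144: pancreas 7.94, adipose 4.34,
liver 4.26; miR-150: adipose 3.21, liver 2.07; miR-146a: adipose −4.62;
miR-30d: pancreas −2.81; miR-182: skeletal muscle −4.23; human T2D miR-144
3.07, IFG 1.385) and moderate 2–3-fold magnitudes with the correct
direction elsewhere.  The IFG cohort flips miR-30d and miR-182 upward and
shrinks miR-144, reproducing the pre-diabetic discordance the selection
rule must tolerate.  mRNA panels are planted inverse to their miRNA
regulators in T2D except INS, which moves with miR-30d.  qPCR plates place
a planted log2 effect e as a Ct shift of −e cycles (expected ΔΔCt = −e)
with Ct noise sd 0.1 over triplicates.

What the generator does **not** emulate: probe cross-hybridization,
intensity-dependent (heteroscedastic) noise, correlated miRNA modules,
batch structure beyond a single scale factor, and biological covariates
(age, BMI).  Passing recovery tests therefore demonstrates the correctness
of the filtering logic under the declared noise model, not performance on
real arrays.

## Problem sizes and determinism

Recovery experiments run 20 seeds of the full pipeline (≈ 0.2 s per seed);
calibration uses 1000–2000 null simulations for the Welch test and 200
seeds at n = 120 for the Pearson estimator; oracle-equivalence checks use
100 random instances per filter.  All randomness flows through
`numpy.random.default_rng` seeded from a single integer; the rat, human,
mRNA, prediction and qPCR datasets use decoupled sub-seeds so adding a
stage never perturbs another stage's draws.  Identical seeds give
byte-identical output tables.

## Known limitations

- The GEO reproduction mode (re-analyzing the original deposited series) is
  not bundled; the file-based input mode accepts any externally downloaded
  TSV matrices instead.
- The replication rule needs per-subject columns; pooled-only designs get a
  replication fraction from group membership of 1 sample per "subject".
- Consensus voting treats databases as exchangeable; no weighting by
  database quality.
- PCA drops features missing in any profile rather than imputing; with
  heavy dropout this can discard substantial signal.
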