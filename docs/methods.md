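# Methods

This note documents the models implemented in `slc-funcmap`, the assumptions
behind them, the defaults of every parameter that matters, what the synthetic
data emulate (and do not), and the numerical and design choices made where the
procedure was genuinely open.

## Metabolomics normalization (`metnorm`)

**Model.** An MRM peak area is treated as the product of analyte
concentration, per-analyte instrument sensitivity, a per-run (batch)
multiplier, a per-injection factor, and multiplicative lognormal noise.
Because an internal standard spiked into the same injection shares the run and
injection factors, the target/standard area ratio cancels them; all downstream
statistics operate on log2 ratios.

**Internal-standard assignment.** Structure-matched (isotopologue) standards
are taken directly. Otherwise, for each (metabolite, standard, run) with at
least 3 calibration points, a weighted linear regression of expected
calibration concentration (µM) on the area ratio is fit and scored by
adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2). A standard's qualifying percentage
is the share of eligible runs (both analytes detected) with adj. R² ≥ 0.85;
standards reaching that in ≥ 75% of runs compete on the percentage, ties keep
all (their log2 ratios are averaged), and if none qualifies the
best-percentage standard is kept as an explicit fallback. Regression weights
default to 1/x², standard practice for MRM calibration where the relative
error is roughly constant; `none` and `1/x` are available. The regression
direction is concentration-on-ratio, mirroring how the assignment criterion is
defined, even though calibration curves are conventionally fit the other way
round; only the R² matters here and it is direction-symmetric up to the
adjustment term.

**Batch correction.** Per metabolite and run, v′ = (v − median_run)/IQR_run ×
IQR_overall + median_overall, with centering only when IQR_run = 0. A
metabolite observed in a single run is returned unchanged. The transform is
exactly idempotent when runs are affine copies of one another (each run then
carries exactly the pooled median and IQR after one pass); for runs with
different distributional shapes the pooled IQR of the corrected matrix can
differ slightly from the target, so a second pass is not a strict no-op in
general. The property test asserts the affine-copy case.

**Missing data.** A sample in which some reference standards are undetected
falls back to the reduced reference set; if all are missing, or the metabolite
area is zero, the cell is left missing rather than imputed.

## Differential abundance (`diffstat`)

Per feature, an ordinary-least-squares linear model of the batch-corrected
log2 values: intercept + induction for wild-type overexpression models, plus a
clone main effect (no interaction) for knock-out/re-expression models with two
clones. Significance is the partial F-test on the induction term; on balanced
two-group data this reproduces the pooled two-sample t-test (F = t²) to
1e-12. The log2 fold change is the difference of condition means (averaged
over clones), identical to the model coefficient under balance but more robust
to missing cells. Degenerate zero-residual fits are resolved explicitly
(zero effect → p = 1; exact nonzero effect → p = 0) using a tolerance relative
to the response scale. P values are Benjamini–Hochberg adjusted per analysis
(statsmodels' step-up implementation behind `bh_adjust`); features missing an
entire condition are excluded from the BH family. Calls use adjusted p < 0.05.
Whether unbalanced two-way designs would need a sums-of-squares convention is
moot here: designs are validated and warned when unbalanced, and balance makes
sequential and marginal tests identical.

## Ontology matching (`ontio`)

Terms match when one is a more generic or a more specific form of the other:
a path whose directional edges (`is_a`, and `has_role`, treated as chemical →
role generalization) are all traversed in one direction, with equivalence
edges (conjugate acid/base, tautomer, enantiomer) free in both directions.
Direction mixing along a path is forbidden by default — allowing it would let
sibling terms match through their common parent, which "more generic or more
specific" does not support — but `MatchPolicy(allow_mixed_directions=True)`
enables it, and `max_depth` caps path length (unbounded by default). An
equivalence-only connection is classified as such, taking precedence over
longer mixed paths. The OBO reader consumes only `id`, `name`, `is_a` and
`relationship:` tags; unknown relation types are counted and dropped, cycles
among `is_a` edges and dangling endpoints are validation errors.

## Pathway mapping (`pathnet`) and permutation testing (`permfreq`)

A pathway's reaction set includes its descendants', and a feature mapped to a
reaction maps to all ancestor pathways up to the root, so counts roll up the
hierarchy; features shared by sibling pathways are deduplicated per pathway.
Genes map through a user-supplied gene→protein table (one-to-many allowed);
unmapped genes map to no pathway, logged, not an error. Per-pathway mean log2
fold change averages all mapped genes with no significance filter and is NaN
(not zero) when nothing maps. Top-level pathways are the root's direct
children ranked by mapped-feature count, ties toward the smaller id, default
k = 9.

The hit count of a pathway is the number of analyses with at least one
significant feature mapped to it. Significance is empirical: each of B
iterations applies **one** random permutation of feature identities shared
across all analyses and pathways — preserving the joint structure, the
natural reading of shuffling "the identities of the quantified metabolites
and genes" — and p = (#{permuted count ≥ observed} + 1)/(B + 1), one-sided
for enrichment, which is what the significance maps display. B defaults to
200,000 as in the study; tests and the acceptance script use 2,000–10,000,
which bounds Monte-Carlo error at the binomial rate. Shuffling the
feature→pathway map is equivalent under exchangeability to shuffling
per-analysis significance labels; the map shuffle is implemented.

## Pair categorization (`paircat`)

Only significant pairs are categorized, by precedence: annotated substrate
(ontology match to any annotated substrate term) > metabolic conversion >
novel non-orphan > novel orphan. The categories are presented as disjoint and
overlap resolution is not otherwise specified, so precedence follows
specificity of evidence; adding reactions can therefore never demote an
annotated-substrate pair. Conversions are reactions with a substrate-matched
educt and metabolite-matched product, or — following the broader
"either educts or products" reading — the converse, recorded in the witness;
one-directional matching is available via `bidirectional=False`. Terms
occurring as both educt and product of a reaction are disqualified as anchors,
and the substrate exclusion list {hydron, hydroxide, water} (configurable) is
applied before matching.

## Profile clustering (`profclust`)

Profiles are restricted to features with finite fold changes in every
analysis, then standard-normalized per item (mean 0, sample SD 1, n−1
denominator throughout); constant profiles cannot be standardized and are
excluded with a warning. Ward-linkage agglomeration (scipy's implementation,
the minimum-variance convention on squared Euclidean distances) is cut at
k ∈ [⌈N/10⌉, ⌊N/5⌋] — the band implied by a target average cluster size of
5–10 items — choosing the k with the largest mean silhouette width, ties
toward smaller k (more conservative grouping); an empty band clamps to
[2, N−1]. Items are sorted by id before distance computation, making the
result invariant to input order.

Enrichment uses one-sided Fisher's exact tests per (cluster, property) for
properties with ≥ 3 annotated carriers among clustered items, BH-adjusted
within each property class separately, called at FDR 20%. Items absent from
the annotation table are excluded from the universe.

Metabolomics profiles use the ANOVA fold changes directly — shrinkage is a
count-model concept and does not apply to the ratio-based metabolomics
statistics; transcriptomic inputs are expected to carry upstream-shrunken
estimates.

Uniqueness scores z-standardize a gene's fold change across genes within an
analysis and across analyses for the gene (requiring ≥ 3 analyses; a gene
with zero across-analysis variance has z = 0 by the zero-deviation
convention). Hits require adjusted p < 0.05 and ≥ 50 reads in **both**
replicates of at least one condition. The output ranking statistic
min(|z_within|, |z_across|) is this package's choice — both axes are reported
and no combined threshold is imposed.

## Cluster coherence (`coherence`)

All entropies use the natural logarithm; NVI = VI/H₁,₂ is base-invariant.
"Shared entropy" is taken as the joint entropy H₁,₂, the term appearing in
the VI identity itself. The pairwise contribution cᵢⱼ = pᵢⱼ log(pᵢpⱼ/pᵢⱼ²)
(0·log(·) := 0) decomposes VI exactly; per-cluster contributions sum cᵢⱼ over
the other clustering, and per-cluster MI contributions are reported alongside.
Clusterings over different item sets are compared on their intersection, with
the dropped counts reported — the alignment rule for differently sized
cohorts is not otherwise determined. Degenerate single-cluster comparisons
define NVI = 0.

## Synthetic data (`synthio`)

The generators are pure functions of (seed, parameters), each drawing from a
single `numpy` Generator; null features carry exactly zero planted effect.

* **Ontology** — an `is_a` forest (configurable roots, depth, branching) with
  equivalence twins attached at probability `p_equivalence` and `has_role`
  edges at `p_role`; the exhaustive BFS match closure ships with the graph as
  the oracle for the matching module.
* **Pathways/reactions** — a rooted tree whose first two non-root pathways sit
  under the root (later ones attach randomly), reactions drawing 1–2 educt and
  product leaf terms, occasionally sharing a term across sides to exercise the
  anchor-disqualification rule.
* **Metabolomics** — the ± doxycycline design with four replicates per
  condition (two clones for the two-way model), two runs with a 6-point
  calibration ladder each, and peak areas as described under the normalization
  model, with one addition: each metabolite shares a per-sample lognormal
  *matrix factor* (`matrix_sd` = 1.2 log2 units) with its chemically similar
  true internal standard. The true-standard ratio therefore cancels every
  systematic factor and calibrates linearly, while decoy ratios retain two
  independent matrix factors and reliably fail the adjusted-R² rule — this is
  what makes internal-standard recovery a falsifiable target. Defaults:
  20 metabolites, 4 standards, noise_sd 0.1 (log2), injection_sd 0.1,
  clone_sd 0.5.
* **Fold-change cohorts** — cluster centroids are random directions scaled to
  pairwise separation `separation` (default 6) in Euclidean norm, plus
  Gaussian noise (default SD 0.5); categorical properties agree with the true
  cluster with probability `property_fidelity`; adjusted p values and
  negative-binomial replicate read counts (mean 200, dispersion 5) exercise
  the significance and minimum-signal filters.

What the synthetic data do **not** emulate: chromatography and peak
integration, detection limits, realistic chemistry of the toy ontology,
count-level transcriptomics (upstream differential tables are the interface),
or correlated noise between metabolites. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
assumptions, not performance on real acquisitions.

## Problem sizes and numerical choices in the verification suite

The acceptance script and tests run at desk scale: 100 random clustering
pairs of ≤ 30 items for the information-theoretic checks (agreement to
1e-12); permutation exactness on a 4-feature universe against full 4!
enumeration at B = 10,000; null calibration over 200 pathways with a
60-analysis cohort at B = 2,000 — the cohort size is chosen so the discrete
per-pathway count distribution has enough resolution for the empirical p to
approach uniformity near the 5% level; five two-clone experiments (20
metabolites each) for standard recovery and effect-recovery error; 500
all-null one-run analyses (structure-matched standards, so the regression
step is bypassed) for the realized false-positive proportion; and a 40-item,
6-cluster cohort for clustering recovery. Floating-point comparisons use
1e-12 for closed-form identities and 1e-9 for standardization round-trips.

## Known limitations

* The direction-mixing rule for ontology match paths is a documented
  interpretation; the original analysis's path semantics are not stated.
  Both behaviors are exposed through `MatchPolicy`.
* Batch correction is location/scale only; it cannot remove run effects that
  change a metabolite's distributional shape.
* The pairwise NVI values reported for the real cohorts (metabolomics vs.
  transcriptomics clusterings, family vs. fold) require the deposited
  cluster-assignment and annotation datasets; `pairwise_nvi_matrix` computes
  them directly when those files are supplied, but they are not reproducible
  from synthetic data.
* Permutation p values are one-sided (enrichment) and not adjusted across
  pathways; depletion testing would need the opposite tail.
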