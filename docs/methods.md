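# Methods

This note records the models, parameter choices and numerical decisions
behind `mirdsd`, and what the synthetic validation does and does not show.

## The pipeline in one paragraph

A gene-by-sample FPKM matrix and a clinical table enter a four-stage
pipeline: (i) differential expression selects two up- and two down-regulated
miRNA markers; (ii) optionally, a weighted co-expression network relates
gene modules to clinical traits and nominates hub genes; (iii) a compiler
turns a marker panel plus one sample's expression values into a two-layer
strand-displacement circuit; (iv) a mass-action simulator produces
fluorophore trajectories whose endpoints are compared winner-take-all to
call the sample (tumor/health, or a clinical-trait level for hub circuits).

## Differential expression

Expression is analysed on the log2(FPKM+1) scale throughout (pseudocount 1,
set once in `cohort.PSEUDOCOUNT`). The log2 fold change is the case-group
mean minus the control-group mean; the p-value is a two-sided Welch t-test
(unequal variances, Welch–Satterthwaite degrees of freedom). An optional
moderated mode (`eb_shrink`) shrinks per-group gene variances toward the
across-gene mean variance with `prior_df` pseudo-observations — a
lightweight stand-in for full empirical-Bayes moderation, adequate here
because downstream stages consume only the fold change and a p cutoff.
No multiple-testing correction is applied by default (the screen is a raw-p
filter, |log2FC| > 1 and p < 0.01, strict inequalities); genes constant
across all samples get p = 1. The marker panel takes the top n (default 2)
per direction by |log2FC|, ties broken by smaller p then gene id, so the
selection is a total order and permutation-invariant.

Representative cases per group come from K-means (k-means++ seeding, fixed
seed, K = 10 by default) on per-sample log2 profiles; the *medoid* (member
sample nearest its centroid) is returned rather than the centroid so each
representative is an actual sample that could be validated individually.

## Co-expression network

The network is unsigned: a_ij = |pearson(log2 x_i, log2 x_j)|^β with zero
diagonal (a signed variant `((1+cor)/2)^β` sits behind a flag). Zero-variance
genes get zero correlations with a warning. The soft power β is the smallest
integer in 1..20 whose scale-free topology fit reaches 0.8; if none does,
the argmax is returned with a warning flag.

**Scale-free fit.** Connectivity k_i = Σ_j a_ij is binned into 10
equal-width bins on the raw k scale (the WGCNA `scaleFreeFitIndex`
convention), empty bins are dropped, and log10(frequency) is regressed on
log10(mean k per bin); the fit index is the signed R² (negated when the
slope is positive). Equal-width *logarithmic* binning was evaluated and
rejected: on finite-sample correlation networks the log-binned histogram of
k is humped (estimation noise spreads k multiplicatively), so its signed R²
hovers near zero for every power and the index loses all selectivity,
whereas raw-scale binning reproduces the canonical behavior (fit rising
with β and crossing 0.8 near β ≈ 5–7).

Topological overlap uses the standard Ravasz-style formula
TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij), TOM_ii = 1.
Modules come from average-linkage hierarchical clustering of 1 − TOM with a
*static* cut (default height 0.95, minimum module size 30, WGCNA's
documented default size): static cutting is deterministic and sufficient
for planted-module recovery; dynamic tree cut is out of scope. Clusters
below the minimum size are relabeled unassigned (label 0, the "grey"
convention). The module eigengene is the first principal component of the
z-scored module submatrix, sign-oriented so its mean correlation with
member genes is positive and scaled to unit variance. Module–trait
association is a Pearson correlation with a two-sided t-distribution
p-value; constant traits report r = 0, p = 1 with a warning. The hub gene
is the argmax of intramodular connectivity kWithin, or of
kWithin × |gene–trait correlation| when a trait is under study — both modes
are exposed because the hub of a module legitimately changes with the trait.

## Circuit model

Strand displacement is modeled as a single irreversible bimolecular step
(long-toehold regime; reversibility, leak and sequence thermodynamics are
out of scope). Concentrations are in nM with FPKM mapped to nM by the
identity (no rescaling), rate constants in nM⁻¹s⁻¹ with default
k = 0.003. Layer-1 rates are |log2FC| × k; the magnitude is used because
health markers have negative log2FC and a negative rate is unphysical.
Gate 1 and gate 2 are initialised to the total input on their channel, so
layer 1 is stoichiometrically non-limiting and converts inputs faithfully;
only gate 3 is limiting. Gate 3 defaults to the mean concentration of the
health-channel inputs (e.g. inputs at 20 and 14 nM give 17 nM); an explicit
`gate3_nM` override supports fixing the threshold while sweeping inputs.

The layer-2 comparison mechanism is genuinely under-determined (a limiting
shared gate and an explicit subtraction are both defensible readings), so
three topologies are compiled explicitly rather than guessing one as fact:

* `shared_gate` (default): both output pools compete for the limiting
  gate 3; consumption releases the channel fluorophore. This reproduces all
  described behaviors — both channels rise, the larger pool dominates
  proportionally, and sub-threshold inputs go dark.
* `annihilation`: tumor and health outputs annihilate pairwise at k;
  survivors report through per-channel reporter complexes (each at the
  gate-3 concentration).
* `threshold_subtract`: the health output first feeds a thresholding
  complex (gate-3 concentration) at 10 × k — thresholding gates are fast in
  seesaw designs, and the speed gap is what makes "first consumes, remainder
  reports" kinetically meaningful — then both channels report through
  non-limiting reporters.

Compilation is pure (species sorted by id; identical inputs give identical
specs) and every compiled circuit passes a structural validator (declared
species, positive rates, channel bookkeeping).

## Kinetics

The ODE system d**x**/dt = S·v(**x**) with mass-action propensities
v_r = k_r [A][B] is integrated with LSODA at rtol 1e-8 and atol 1e-10 nM,
sampled on the readout grid (0 to 1000 s every 10 s — one hundred 10-s
cycles). Solver state is never floored; negative values (bounded by the
tolerance) are clipped to zero only on CSV export. The first grid column is
pinned to the exact initial state.

The Gillespie direct-method simulator is an independent cross-check, not a
second integrator: counts are concentrations × `volume_scale` (default
100 molecules per nM — a speed/accuracy compromise for tests), bimolecular
propensities are (k/volume_scale)·n_A·n_B, and each run draws from a child
stream of the seed, so results are reproducible and runs independent. When
comparing SSA means to the ODE, a one-molecule quantization floor
(1/volume_scale) is added to the 3-standard-error band: at grid points where
all runs coincide the sample SE is zero, and a finite-count simulation
cannot resolve the ODE's sub-molecule residuals there.

Mass balance is verified from first principles: an orthonormal basis of the
left null space of the stoichiometry matrix gives the conserved strand
moieties, and the maximum drift |c·x(t) − c·x(0)| must stay below 1e-6 nM
over the full horizon (observed drift is ~1e-13 nM).

## Classification

The call compares endpoint FAM and ROX concentrations: if both are below
the detection floor (`floor_delta`, default 0.5 nM) the circuit went dark —
inputs below the gate-3 threshold — and the call is indeterminate; if the
margin |FAM − ROX| is within `margin_eps` (default 1e-3 nM) the call is
indeterminate; otherwise the larger channel wins. Both constants are
configuration data recorded in the run manifest; the floor has no
experimental analogue here and was chosen as a conservative detection limit
well below any decided endpoint in the reference conditions. Confusion
summaries count indeterminate as its own column and report both an overall
accuracy (indeterminate = error) and a binary accuracy over decided calls.

Lymph-node counts bin at ≤15 / 16–28 / ≥29; the count 15 goes to the low
part because 15 is the conventional survival threshold in node-count
prognosis. The expected dominant channel per trait level (FAM for low node
counts and for indicator 1) is configuration, not hard-coded biology.

## Synthetic cohorts

`generate_cohort` draws log2(FPKM+1) values as
baseline + group shift (± planted log2FC for cases) + Σ loading·factor
(one standard-normal factor per module per sample) + N(0, σ), then
back-transforms and floors at zero. The log-normal choice (rather than
negative-binomial counts) is deliberate: the downstream circuit consumes
continuous FPKM magnitudes, so count-level realism (library size, GC bias,
batch effects) would add nothing the pipeline can see. A single cohort seed
fans out to per-stage child streams by fixed offsets. Clinical traits are
signed sums of module factors plus noise, mapped to their scales (node
counts: affine to [0, 105], rounded — 105 being the top of the clinical
binning range; indicator: thresholded at 0); samples with no module-driven
trait get uninformative random values.

Two reference conditions are frozen in `mirdsd.scenarios`:

* **Diagnostic markers** — 60 cases vs 20 controls (the cohort imbalance of
  the motivating data, scaled down), 300 genes, planted log2FC ±2.5 and
  ±1.8, noise SD 0.5. For end-to-end classification the four markers get
  *informative baselines* (up-markers start low at log2 level 3, down-markers
  high at 5, background 4): an up-regulated marker is informative precisely
  because it is scarce in health, and without that asymmetry the two
  channels would tie on control samples and no winner-take-all readout —
  molecular or otherwise — could separate the groups.
* **Scale-free modules** — 500 genes in five modules of 100 (every gene a
  member), hub loading 1.0, member loadings drawn so that
  u = l/√(l²+σ²) — the correlation a member carries with its module factor —
  follows a truncated Pareto law (α = 6) on the image of [0.3, 0.8], noise
  SD 0.35, 150 samples. The Pareto tail gives the few-strong/many-weak
  loading profile of real co-expression modules and a heavy-tailed
  connectivity distribution after soft thresholding; the 0.8 member cap
  keeps the planted hub identifiable. Module detection under these
  conditions uses cut height 0.99 (weak Pareto-tail members sit higher on
  the dendrogram than the package default 0.95 expects; inter-module
  overlap is near zero, so the higher cut absorbs the tail without merging
  modules).

**What passing on these cohorts shows — and does not.** The synthetic
generator reproduces the statistical *structure* the pipeline relies on
(planted shifts, block correlation, trait coupling) but none of the
messiness of real RNA-seq: no count noise, no batch effects, no correlated
background between modules, no measurement error in FPKM. Recovery rates
and accuracies measured here are therefore upper bounds on real-data
behavior and validate the machinery, not the clinical claim. Accuracies
reported on the original clinical cohort by the motivating analysis depend
on that specific dataset and are not reproduction targets here.

## Numerical details and edge cases

* Welch test with zero variances: identical means give p = 1, separated
  means p = 0 (perfect separation); constant genes are logged.
* Correlation matrices: non-finite entries (zero-variance genes) become 0;
  adjacency/TOM symmetry is enforced to 1e-10 and TOM clipped to [0, 1].
* Tie-breaks are lexicographic everywhere a score can tie (marker ranking,
  medoids, hub genes), making every stage deterministic.
* `detect_modules` requires cut_height ∈ (0, 1]; module labels are
  renumbered by decreasing size.
* The ODE solver failing mid-integration raises with the failing time;
  trajectories expose `at_time` only on the sampling grid.
* All file outputs are plain TSV/CSV/JSON/YAML with ≥10 significant digits,
  and `run_pipeline` manifests record the config hash, seed and solver
  tolerances; reruns with the same config are bit-identical.

## Problem sizes used in validation

The validation suite runs planted-marker recovery on 100 cohorts of
300 × 80, network recovery on 50 cohorts of 500 × 150, a 10×10
winner-take-all grid, 200 Gillespie runs at ~10³ molecules, and a
100-sample end-to-end cohort — sizes chosen so the full suite completes in
well under a minute per stage while keeping every estimate's sampling error
far from its acceptance margin.
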