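# Methods

This note documents the models, defaults, and numerical choices behind
`mucosanet`, and what the synthetic-data tests do and do not establish about
behaviour on real cohorts.

## Data model

Each omic layer is a participant-by-feature matrix of non-negative
abundances with an optional per-feature limit of detection (LOD) and a
boolean mask marking censored entries. Layers are tagged (`cytokine`,
`immune_cell`, `host_protein`, `metabolite`, `taxa`, `bact_function`,
`bact_protein`) and carry their natural units (pg/mL, % of live cells,
normalized relative abundance, proportions). The metaproteome enters as a
protein-by-participant spectral-count matrix with one taxon per protein
(proteins whose peptides match more than one genus are binned as
"undistinguishable") and an optional ko-pathway label.

## Preprocessing

* **Detection-rate filter** (default threshold 0.40): a feature is kept only
  if its censored fraction is *strictly below* the threshold, so a feature
  missing in exactly 40% of samples is removed. This is applied before any
  imputation so that imputed constants never dominate a feature.
* **Imputation.** Cytokines: censored entries become LOD/2. Metabolites:
  the "zero replacement" is half the per-feature minimum observed positive
  value by default — it mirrors the half-LOD rule and keeps values strictly
  positive for log2; literal zero and a global half-minimum are selectable
  for sensitivity analyses. Imputation is idempotent. When kit LODs are
  unavailable the per-feature minimum observed value can serve as a
  pseudo-LOD (logged prominently by the reader).
* **Technical-variability filter** (default max CV 0.25): "average
  covariance" is interpreted as the per-protein coefficient of variation
  (sample SD / mean) across repeated runs of one standard reference sample
  (7 replicates in the emulated design). Proteins absent from the reference
  runs, or with zero replicate mean, cannot be certified reproducible and
  are dropped with a warning rather than crashing.
* **Complete-case filter**: the network stage uses only participants present
  with a fully observed row in every layer (mirroring a cohort in which a
  handful of participants lack one assay).

## Inflammation stratification

The clustering stack behind the low/medium/high assignment is not uniquely
determined by the analysis description it follows, so the package defaults
to the most common heatmap-clustering stack — log2, per-feature z-score,
Euclidean distance, Ward linkage, tree cut at k = 3 — with all four choices
configurable. Cluster *labels* are deterministic: clusters are ranked by
their mean upper-quartile cytokine count (ties broken by mean standardized
level) and named low → high in ascending order, making assignments invariant
to participant order and to any strictly monotone per-feature transform
applied before standardization. Tests therefore assert recovery of planted
groups on synthetic cohorts rather than any specific real-data membership.

"In the upper quartile" is read as *strictly above* the linear-interpolation
75th-percentile sample quantile; both the comparison (> vs ≥) and the
quantile type are switches. The Amsel bacterial-vaginosis call is positive
iff at least 3 of the 4 criteria are present; a missing criterion yields an
indeterminate record excluded from tabulations.

## Metaproteome summarization

Spectral counts are normalized to the per-participant total before any
summing. Taxa proportions include the "undistinguishable" bin in the
denominator by default (a flag excludes it). The *Lactobacillus*-dominance
call rolls species-level bins (*L. crispatus*, *L. iners*, "Lactobacillus
other") up to the genus before applying the strict > 0.5 rule, so the call
is monotone in any *Lactobacillus* count. Functional profiles are
proportions of *annotated* counts only — proteins without a ko pathway are
excluded from the denominator.

## Group statistics

Kruskal–Wallis uses midranks and the tie-correction factor
1 − Σ(t³−t)/(N³−N); a pooled sample with all values identical returns
H = 0, p = 1 rather than erroring (the correction factor is zero there).
p-values are upper chi-square tails with k−1 degrees of freedom — adequate
for the group sizes used here (calibration is verified by permutation in the
test suite) but approximate for very small groups. Dunn's post hoc uses the
tie-corrected pooled-variance z statistic; the default multiplicity
adjustment is Šidák over the k(k−1)/2 pairs (the "Dunn's multiple
comparison" family familiar from Prism), with none/Bonferroni/BH
selectable — adjusted Dunn p-values are software-convention-dependent and
are not treated as exactly reproducible quantities. The Monte-Carlo Fisher
test simulates tables with fixed margins (Patefield algorithm) and uses the
+1/+1 estimator, so it never reports exactly zero; the seed is required.
Hypergeometric over-representation p-values are discrete and conservative;
the null-calibration test checks they are never anti-conservative rather
than exactly uniform.

## Bayesian-network consensus

* **Screening.** A random-forest classifier of the 3-level inflammation
  label (500 trees by default, fixed seed) ranks each layer's features by
  Gini importance; the top 5 per layer are kept, ties broken
  lexicographically. Screening runs on continuous values — discretization is
  described below as a network-construction step — with a switch to screen
  on discretized codes instead.
* **Discretization.** Each feature becomes 1 iff strictly above the cohort
  median. Features with > 90% of values tied at the median are nearly
  constant after the split and are excluded with a log entry. The
  inflammation variable enters as a 3-state categorical; the BDeu score
  handles mixed arities natively.
* **BDeu scoring.** The decomposable Dirichlet marginal likelihood with
  uniform hyperparameters α_ijk = ess/(q_i r_i). Family scores are cached
  per (node, parent set), so greedy search pays only for families it has
  not yet seen; a configuration-table cap guards against oversized parent
  sets. Likelihood equivalence (identical scores across Markov-equivalent
  DAGs) holds to ~1e-13 in a 100-dataset sweep over all 25 three-node DAGs.
* **Search.** Best-move hill climbing over single-edge additions, deletions,
  and reversals, accepting only strict improvements (> 1e-10), with
  deterministic tie-breaking. Single-run greedy search reaches the 3-node
  global optimum (verified by exhaustive enumeration) in roughly 90–95% of
  random problems; every miss observed in testing was a genuine local
  optimum with no improving single-edge neighbour. Random restarts are the
  remedy: restart 1 starts from the empty DAG and each subsequent restart
  perturbs the incumbent best with 5 random valid edge operations; with 10
  restarts the global optimum is reached in 98–100 of 100 problems. The
  restart count and perturbation size are configurable; the perturbation
  scheme itself is a package choice.
* **max_parents = 4** by default: with ~40 binary observations, denser
  parent sets cannot be estimated and blow up the configuration table.
* **Bootstrap consensus.** B participant resamples (with replacement, same
  n; resamples that collapse a variable to one level are redrawn with a
  capped retry count) are each learned with R-restart hill climbing; arc
  strength is the fraction of the B undirected skeletons containing a pair,
  and B × R structures are learned in total. Desk-scale defaults are
  B = 200, R = 10; the full-scale preset B = R = 1000 (10⁶ networks) is
  available behind a flag. The consensus keeps pairs with strength ≥ the
  estimated threshold; the estimator minimizes the L1 distance between the
  empirical strength CDF and the ideal noiseless step CDF, then returns the
  smallest observed strength strictly above the optimal quantile, so that
  the ≥ rule keeps exactly the significant pairs (all-identical strengths
  return that value). Consensus edges are undirected by design: bootstrap
  agreement on a skeleton does not identify direction.
* **Imaginary sample size.** For a *given* DAG, the ESS is profiled over a
  log-spaced grid (2⁻⁵…2¹⁰, 64 points) refined by golden-section search.
  Profiling against the empty DAG is uninformative for median-split data:
  balanced binary marginals make the empty-graph score monotone increasing
  in the pseudo-count, so the optimum escapes to the grid boundary, and such
  an oversized prior demonstrably degrades structure recovery (planted
  10-node skeleton F1 drops from ≈ 0.9 to ≈ 0.4). The pipeline default
  therefore alternates structure learning and ESS profiling on the learned
  DAG until the value stabilizes (the familiar iterative ESS-selection
  scheme), typically converging in two iterations to values of order 1–10.
  A fixed ESS can be supplied instead.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults sized to the emulated study: 43 participants split 6/25/12 across
low/medium/high inflammation; 30 cytokines (the curated 10 plus 20 extras
whose censoring quantiles are drawn up to 0.6 so the ≥ 40% filter has real
work); 6 immune-cell types as logistic-normal percentages summing to 100;
200 host proteins with 7 reference replicates whose CVs straddle the 25%
filter; 82 metabolites; 19 taxa from a Dirichlet mixture
(*Lactobacillus*-heavy vs *Gardnerella*/*Prevotella*-heavy components, with
per-group dominance probabilities 1.0/0.64/0.58 and a group-dependent
*L. crispatus* concentration multiplier); 250 bacterial proteins drawn
multinomially within taxa, 55% annotated to 33 ko pathways. Planted
differential effects are parameterized as per-group log2 shifts (rank tests
make power robust to the log-normal choice): curated cytokines rise
(0/1.5/3), APCs rise, xanthine and carbohydrates rise, lactate, succinate
and adenosine fall, epithelial-barrier proteins (SCEL, IVL, SERPINB3) fall.
The planted dependence DAG has binary nodes that copy their single parent
with probability 0.9 and one isolated negative-control node.

What the generator does **not** emulate: assay-specific noise (plate and
batch effects, duplicate-well averaging), correlated censoring, realistic
taxa phylogeny or protein homology structure, or any mechanistic coupling
between layers beyond the planted group effects and DAG. Passing tests
therefore demonstrate that each algorithm recovers the structure it is
designed to recover under its own statistical assumptions — not that any
particular real-data result would be reproduced.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 100-dataset sweeps for
the 3-node score/search checks, B = 200 × R = 10 for the planted 10-node
recovery, 10,000 label permutations for rank-test calibration, and reduced
B/R for 36-node end-to-end runs. Every random operation draws from an
explicit seed (bootstraps spawn child seeds from one seed sequence), so a
pipeline re-run with the same config and seed is byte-identical, including
the exported edge lists.

## Known limitations

* Greedy hill climbing stalls in genuine local optima on a few percent of
  problems (XOR-type joints defeat any single-move, score-based search);
  restarts mitigate but do not provably eliminate this.
* With ~40 observations, median discretization and the BDeu score limit
  detectable dependencies to fairly strong ones; arc strengths for weak
  edges are noisy and the consensus threshold inherits that noise.
* Dunn adjusted p-values follow the Šidák convention and will differ in the
  third decimal from implementations using other joint corrections.
* The chi-square approximation to the Kruskal–Wallis null is approximate
  for groups of ≤ 6; the package reports it regardless, as standard
  practice does.
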