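# Methods

This note documents the statistical procedures implemented in `annosom`,
the choices made where several defensible variants exist, and what the
synthetic-data generator does and does not emulate.

## Input model

The unit of analysis is the **cluster**: the output of an upstream
over-clustering step (FlowSOM/GigaSOM-style SOM nodes or metaclusters),
summarised as the per-cluster median expression of each antibody marker.
Expression values are assumed already variance-stabilised upstream
(typically arcsinh with a cofactor); the package applies no cofactor
transform of its own. At load time each marker column is min–max rescaled
to [0, 1] over clusters. This normalisation is the scale on which
thresholds live and annotation predicates are evaluated. It is monotone, so
it changes neither the ordering of clusters within a marker nor which
partitions are achievable, and it is invertible per marker for reporting on
the raw scale. Markers constant across clusters carry no low/high
information; they are loaded, mapped to zero, flagged, and excluded from
threshold estimation with a warning.

## Threshold estimation

For each marker vector `x` (one value per cluster, on [0, 1]):

**Exact 1D two-means.** With k = 2 in one dimension the optimal clusters
are contiguous in sorted order, so the global optimum is found by scoring
all `n − 1` contiguous splits of the sorted vector with prefix sums and
taking the minimum total within-cluster SSE (leftmost split on ties). This
replaces Lloyd-style iteration deliberately: it is O(n log n), globally
optimal, and has no dependence on a random initialisation, which makes the
whole pipeline a deterministic function of its inputs. The reported
threshold is the midpoint of the two cluster means — the 2-means decision
boundary.

**Two-component Gaussian mixture.** A univariate 2-component GMM is fitted
by EM, initialised from the exact two-means partition (weights, means and
variances of the two sides), hence also deterministic. Convergence is
declared when the log-likelihood improves by less than 1e−6, with a cap of
500 iterations; component variances are floored at 1e−8 so point masses
stay finite. The threshold is the density crossing
`w₁ φ(x; μ₁, σ₁) = w₂ φ(x; μ₂, σ₂)` solved as a quadratic in `x` after
taking logs, restricted to the open interval (μ₁, μ₂) — i.e. the point
where the posterior probability of the two components is 0.5. When no real
root falls in that interval (one component dominates throughout, e.g. a
tiny narrow component under a broad one), the midpoint (μ₁+μ₂)/2 is used
as a fallback.

**Method selection.** Each candidate threshold t induces the partition
`x ≤ t` vs `x > t`; the mean silhouette width of that partition (absolute
difference distance; singleton groups contribute 0) scores the separation.
The method with the strictly higher silhouette wins; ties go to k-means as
the simpler model. The silhouette is computed on the threshold-induced
partition rather than on the methods' internal labels so that the quantity
scored is exactly the object used downstream (for both methods here the two
coincide anyway).

**Bimodality.** Sarle's sample-adjusted bimodality coefficient

    BC = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3)))

uses the bias-corrected sample skewness g₁ and excess kurtosis g₂. BC is
affine-invariant, so computing it on normalised rather than raw expression
changes nothing. Reference values: ≈ 1/3 for a normal sample, 5/9 ≈ 0.555
for a uniform sample (the conventional cutoff), → 1 for a balanced
two-point mass. A marker is flagged bimodal when BC exceeds the cutoff
(default 5/9). The comparison direction is configurable
(`bimodality_direction="lt"`) because the "below 0.555" reading also
circulates; the default follows the coefficient's literature, where larger
BC means more bimodal. The flag is advisory: thresholds are estimated for
all non-constant markers, and analysts are expected to review markers that
fail the criterion (raise the clustering resolution, exclude the marker, or
set a manual threshold).

**Manual overrides** replace the threshold, set `method="manual"`, keep the
estimation diagnostics, and survive re-estimation unless
`overwrite_manual=True`.

## Tree annotation

The annotation hierarchy is rooted at a constraint-free node named
`unassigned`. Each other node carries positive and negative marker sets
(disjoint, validated against the panel). Assignment is a single top-down
pass recomputed from scratch whenever requested: the root owns every
cluster; at each node, the clusters resting there are tested against the
children in insertion order and descend into the first child whose
constraints they satisfy. The predicate is conjunctive: strictly above
threshold for every positive marker, at or below threshold for every
negative marker. The boundary value counts as negative — one side of the
cut must be closed, and the threshold's role as the upper edge of the
negative mode makes "negative at the line" the natural closure.

Two documented consequences of this design:

* **Overlap.** Nothing forbids two siblings whose definitions both match a
  cluster. The first (earlier-inserted) sibling wins, deterministically,
  and every multiply-matching cluster is reported in an overlap list so the
  analyst can refine the definitions.
* **Leftovers.** Clusters that satisfy an internal node but none of its
  children are a phenotype in their own right, labelled
  `<name>_remaining`; clusters at the root remain `unassigned`. Terminal
  labels therefore always partition the clusters exactly.

A node's cumulative definition (union of constraints along its branch) is
exposed and validated: a marker required positive on one level and negative
on another raises a contradiction error. Deleting a node removes its
subtree; its clusters return to the parent at the next recomputation.
Saved annotation CSVs store nodes parent-before-child with `;`-separated
marker lists, and reloading a saved thresholds + annotation pair reproduces
the assignment exactly.

## Differential abundance

Counts of clusters sharing a terminal label are summed per sample and
divided by the sample total, giving per-sample phenotype proportions
(samples with zero cells are rejected rather than imputed). Proportions —
not counts, and untransformed — are the test variable. Each phenotype is
compared between every unordered pair of condition levels with a two-sided
Wilcoxon rank-sum test: exact null enumeration when the combined sample
size is ≤ 25 and tie-free, otherwise the normal approximation with tie and
continuity corrections (the usual statistical-package switchover; exact
enumeration stays cheap in that range). Adjustment methods: Bonferroni,
Holm, Hochberg, Benjamini–Hochberg, or none. The default scope adjusts
across condition pairs *within* each phenotype, mirroring R's
`pairwise.wilcox.test`; `scope="global"` pools across phenotypes as well
for analysts who want family-wide control over the whole screen. Tests are
unpaired: condition groups are modelled as independent cohorts. Selecting
any tree node aggregates its entire subtree (children plus leftovers) into
one proportion per sample, so parent-level comparisons are available
without re-annotating.

## Synthetic data generator

The generator emulates the *cluster-level* artifacts of an over-clustered
cytometry study, not the cells: per-cluster marker medians with a low
(negative) and high (positive) mode, and per-sample cluster counts.

* Each cluster is assigned round-robin to one of the generating tree's
  terminal populations — leaves, internal-node leftovers, and an
  unassigned population (leftover populations are realised by forcing each
  child's defining positive markers negative).
* Constrained markers draw from a truncated normal at the phenotype's
  required mode; unconstrained markers flip a fair coin between the modes
  per cluster (recorded in the ground truth). Defaults: modes 0.2/0.8 with
  SD 0.05 on [0, 1] — a 6σ separation, i.e. a clean, well-behaved marker
  after transformation and normalisation.
* Per-sample counts are Dirichlet-multinomial: expected phenotype
  proportions are uniform across populations, the configured fold change
  scales the effect phenotype in its condition with the rest renormalised
  (so the effect phenotype's expected proportion ratio between conditions
  equals the fold change exactly), a Dirichlet draw with concentration 100
  (inter-sample SD of a few percentage points — biological variability of
  the order seen between donors) perturbs each sample, and a multinomial
  distributes the sample's 100 000 cells, uniformly across the clusters
  within each phenotype. Defaults: 200 clusters, 10 markers, 2 conditions
  × 8 samples, two-fold B-cell enrichment in the case arm.

Everything derives from one `numpy` generator seed; identical configs give
byte-identical CSVs.

**What passing tests on this generator do and do not show.** The generator
produces cleanly separated, symmetric modes, orthogonal marker constraints
and exchangeable samples. Perfect threshold and label recovery under these
conditions validates the *machinery* (exactness of the optimisers, the
filtering semantics, calibration of the test under the null), not
robustness to the pathologies of real panels: overlapping or skewed marker
modes, continuous gradients (activation/maturation markers), batch effects,
compositional coupling beyond the simplex constraint, or markers whose
bimodality only appears at higher clustering resolution. On real data the
bimodality flag and manual-override path exist precisely because some
markers will not look like the synthetic ones.

## Numerical and degenerate-input conventions

* Ties in the two-means SSE scan → leftmost split; ties in silhouette →
  k-means. Both keep results deterministic.
* Constant markers, vectors with < 2 distinct values (two-means), < 4
  distinct values (GMM) or n < 4 (bimodality coefficient) raise a
  degenerate-marker error; `estimate_threshold` degrades gracefully (GMM
  disqualified, k-means retained).
* EM: tolerance 1e−6 on the log-likelihood, ≤ 500 iterations, variance
  floor 1e−8; the log-likelihood trace is retained and is non-decreasing.
* Proportions conserve to 1 within 1e−9 per sample; global cluster
  frequencies must sum to 1 within 1e−6 at load.
* CSV round-trips are exact: floats are written as shortest round-trip
  representations and re-parsed with the round-trip parser.

## Problem sizes used in the checks

The bundled acceptance script measures: the bimodality coefficient of a
100 000-point uniform sample; two-means agreement with an exhaustive oracle
on 200 random vectors (n ≤ 500); exact-Wilcoxon agreement with full rank
enumeration on 100 instances (group totals ≤ 10); threshold recovery on 20
bimodal markers of 200 clusters; annotation recovery, save/reload fidelity
and differential-abundance power on the default 200-cluster project; and
null calibration over 200 random relabelings of a fold-change-1 project.
These sizes give stable estimates (the null rate at the nominal 5% level is
estimated from 1 200 correlated p-values) while the whole script completes
in well under a minute.
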