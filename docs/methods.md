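# Methods

This note documents the models, numerical choices and limitations of the
package in one place. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and scoring

Input is a wide-format response table: one row per subject, one column per
item, cells coded `1` (correct), `0` (incorrect) or `T` (timeout). Timeouts
are scored as incorrect, but subjects with timeouts on ≥ 9 items (on the
36-item default; the threshold is a parameter, applied as *count ≥
threshold*) are excluded before any analysis — heavy timeout loads would
otherwise masquerade as item-level failure patterns. Binarization maps
correct → 1, incorrect/timeout → 0; the total score is the row sum, bounded
by the item count.

## Subject similarity and topological overlap

The primary dissimilarity is Hamming distance: the fraction of items on
which two subjects disagree. Two conversion steps precede clustering:

* **Max-rescaling.** Binary response vectors with graded ability never reach
  Hamming distance 1 (a subject with total *t₁* and one with *t₂* disagree on
  at most min(t₁+t₂, 2n−t₁−t₂) items), so raw adjacency `1 − d` has a floor
  around 0.3. Dense adjacency baselines are poison for the unsigned TOM: the
  shared-neighbour sum ℓ then rewards connection to globally central
  subjects (those in the middle of the performance gradient), to the point
  that the *within*-subgroup TOM-dissimilarity of the worst-performing
  subgroup exceeds its dissimilarity to middle subgroups. Dividing the
  distance matrix by its maximum before forming adjacency (so the least
  similar observed pair has adjacency 0) restores the contrast that the
  systems-biology applications of TOM obtain from soft-thresholding, without
  introducing a power transform.
* **TOM.** The unsigned topological overlap with zero-diagonal adjacency,
  diagonal excluded from the connectivity and shared-neighbour sums,
  TOM ii = 1. Verified against a brute-force triple loop to 1e−12.

Clustering consumes the **TOM profile distance**: the Euclidean distance
between rows of the TOM matrix, rescaled to [0, 1]. This is exactly what a
linkage routine that accepts a square matrix *as data* computes (each
subject represented by its vector of overlaps with everyone), and it is
insensitive to the overall-connectivity gradient that distorts the plain
complement `1 − TOM` on this data class: planted-subgroup recovery with
`1 − TOM` plateaus at ARI ≈ 0.3–0.65, with the profile distance at ≥ 0.9
(see the acceptance suite). The complement is still provided
(`tom_dissimilarity`) for users who want the conventional quantity.

## Ward linkage

`ward_linkage` implements the Lance–Williams Ward recurrence applied
*directly* to the supplied dissimilarity (the historical "ward.D" dialect):
after merging clusters *i, j*,

    d(ij, k) = [(nᵢ+nₖ)d(i,k) + (nⱼ+nₖ)d(j,k) − nₖ d(i,j)] / (nᵢ+nⱼ+nₖ),

merging the minimal pair at each step, ties broken by the lexicographically
lowest index pair (determinism under a fixed input ordering). The squared
dialect ("ward.D2", scipy's `linkage(..., 'ward')`) is exposed as
`variant="squared"` and cross-checked against scipy in the tests. Ward's
coefficients satisfy reducibility, so merge heights are monotone; the suite
asserts this on random inputs.

## Dynamic hybrid tree cut

The cut assigns each branch its own cut decision instead of one global
height. All criteria are evaluated on a dissimilarity matrix normalized by
its largest entry, making thresholds scale-free. A node is split into its
two children when:

* **gap**: mean cross-branch dissimilarity minus the larger child core
  scatter (mean within-branch dissimilarity) is at least `min_gap`;
* **core scatter**: neither child's core scatter exceeds
  `max_core_scatter` (a branch too diffuse to be a cluster core cannot
  force a split);
* **size**: a child below `min_cluster_size` (default 20) never becomes a
  cluster — at an otherwise accepted split it is pruned as outliers while
  recursion continues into the large child.

`deep_split` ∈ {0..4} (default 1) maps linearly to
`max_core_scatter = 0.55 + 0.05·ds` and `min_gap = 0.09 − 0.02·ds`; higher
values split more aggressively. The constants were fixed by the
planted-partition recovery suite: on the packaged fixtures, true
(between-subgroup) splits show normalized gaps ≥ 0.085 (5th percentile) and
false (within-subgroup) splits ≤ 0.008, so the default `min_gap = 0.07`
separates them with margin on both sides. When the root admits no eligible
split — e.g. all pairwise dissimilarities equal — all elements form one
cluster. Pruned elements are then assigned to the cluster with minimal mean
dissimilarity provided that mean is within the cluster's admission radius
(the largest mean-to-others dissimilarity of any member); otherwise they
stay unassigned (label 0).

In `stratify_cohort` the tree is built from the TOM profile distance while
the cut's scatter/gap/admission computations use the raw Hamming matrix:
topology from the denoised network view, split decisions on the
interpretable percent-disagreement scale, where within- vs between-subgroup
contrast is strongest.

## Rank ordering and homologous labels

Cluster labels are remapped so subgroup 1 has the lowest mean total score,
ascending to K; ties break toward the smaller original cluster index.
Cohorts are always stratified independently; cross-cohort label
correspondence comes solely from this rank ordering, never from transferring
cluster assignments.

## Item split

The identical network pipeline applied along the item axis; the tree's top
split partitions items into two sets, and the set with the higher overall
percent-correct is labelled easy. Only the top split is used — the goal is
the two major subdivisions, not a full item clustering.

## Characterization statistics

* Effect grids: Student pooled-variance *t* (Welch optional) and pooled-SD
  Cohen's *d* per (row subgroup, column subgroup) cell, sign = row minus
  column; Bonferroni at α/(K_A·K_B). Cells with a subgroup of n < 2 or zero
  pooled variance are flagged untestable, never dropped, so grid shapes are
  stable. "Controlling for a covariate" = least-squares residualization of
  scores on the covariate in the combined sample before testing.
* Item difficulty: percent correct per item within each subgroup; pairwise
  subgroup correlations (Pearson default, Spearman optional) over the easy
  or difficult subset, two-sided p, BH-FDR flags at q (default 0.05) over
  the unordered pairs. BH goes through statsmodels and is oracle-checked.
* Phenotype tests: one-way ANOVA, Kruskal–Wallis (for skewed measures such
  as trait questionnaires), or χ² on subgroup × category counts; significant
  omnibus tests get Bonferroni-corrected pairwise post-hocs. Variables with
  a subgroup below 2 usable observations are flagged untestable.

## AdaBoost.M2 with discriminant weak learners

The booster maintains a weight distribution over (example, incorrect-label)
pairs. Each round fits a weighted linear discriminant — class means and
pooled covariance under the current example weights, ridge
λ = 1e−3 · trace(Σ)/d added because binary item features make Σ singular —
whose softmax posteriors are the plausibilities h(x, y) ∈ [0, 1].
Pseudo-loss ε, β = ε/(1−ε), weight update β^{½(1+h(x,yᵢ)−h(x,y))} with
renormalization; final score Σₜ ln(1/βₜ)·hₜ(x, y), argmax prediction with
lowest-class tie-break. Early stop at ε ≥ ½ (the learner kept only if it is
the first) or ε ≈ 0; β floored at 1e−10 so learner weights stay finite.
Degenerate single-class training returns a flagged constant predictor.

The permutation test refits the entire ensemble per permutation (not a
score permutation), matching the procedure it emulates. The p-value is the
add-one estimator (k+1)/(n_perm+1) — a valid p-value that can never be 0
from finite permutations — with the raw proportion k/n_perm also reported.
Tie handling note: accuracies live on a grid of 1/n_test, and exact
observed-null ties make the estimator conservative; calibration checks
should use test sets large enough (a few hundred draws) to keep tie mass
small.

## Synthetic cohorts

Latent-class generation: subject → subgroup → independent Bernoulli item
outcomes from the subgroup's profile; optional per-subject logit-normal
ability jitter and uniform timeout injection. The default banks use a
mastery model: mastered items at p = 0.93, unmastered at p = 0.05. The low
unmastered rate encodes *consistently wrong* responding (items with
systematically attractive wrong options), which is what makes the worst
subgroup internally tight — under random guessing at the nominal 0.25
chance rate the worst subgroup would be maximally diffuse in Hamming space
(within-pair disagreement ≥ 2·0.25·0.75 ≈ 0.38 per item) and no
similarity-based method could bound it. Its *expected accuracy* still sits
at the chance level: the lowest ASC-like subgroup masters 22% of items,
giving 0.05 + 0.22·0.88 ≈ 0.25.

Mastery fractions: ASC-like (0.22, 0.40, 0.58, 0.76, 0.97) — five subgroups,
expected totals ≈ 9 → 33 of 36, near-linear; TD-like (0.50, 0.67, 0.84,
1.00) — four subgroups with a higher floor. Mastery sets are nested along a
common shuffled difficulty order (this is what produces a coherent
easy/difficult item split) with two idiosyncratic swaps per subgroup so
subgroups differ in patterning as well as level. `separation` scales the
spread of mastery fractions around the bank mean. Default sizes are 80 per
subgroup (n = 400 / 320); `simulate_cohort_pair` draws discovery and
replication cohorts with independent seeds and Dirichlet-jittered mixing
proportions.

What a green test does and does not establish: the generator realizes the
analysis's own assumption — subgroups fully characterized by item-difficulty
profiles, conditionally independent responses. Real cohorts add
within-subject dependence (fatigue, strategy shifts), ability continua
rather than discrete classes, and item-order effects; recovery results here
do not certify behaviour under those violations. The within-subgroup
dependence structure of real data is unknown; conditional independence is an
explicit modelling choice.

## Determinism and degenerate inputs

Every stage is deterministic given its inputs; seeds enter only through the
generator and the permutation stream, and are recorded in provenance and
run logs. Degenerate handling: identical response rows → K = 1; all-equal
dissimilarities → one cluster; a root smaller than `min_cluster_size` still
forms a single cluster (fallback, documented rather than erroring); zero
maximum distance skips rescaling; constant profile vectors make a
correlation pair untestable; all-identical samples give Kruskal–Wallis
H = 0 by convention (scipy rejects the input).

## Known limitations

* K is bounded above by tree structure and `min_cluster_size`; very small
  true subgroups (< min size) surface as outliers, not clusters.
* The deepSplit mapping constants are calibrated on the packaged fixtures'
  contrast regime; data with much weaker subgroup contrast may need a
  higher `deep_split` or smaller `min_cluster_size`.
* The discriminant weak learner's exact ridge differs from whatever the
  original MATLAB fit used; fidelity is behavioural (above-chance
  cross-cohort transfer), not numeric parity.
* No item-response-theory modelling (measurement invariance across
  subgroups is out of scope), no bootstrap cluster-stability machinery, no
  fuzzy assignment.
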