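# eyestrat

Unsupervised stratification of binary item-level task performance into
replicable subgroups.

Many cognitive tasks are scored as a single total, which hides structure: two
people with the same total can succeed on entirely different items. This
package implements a network-based stratification pipeline for cohorts of
subjects described by binary item outcomes (correct / incorrect, e.g. the
36-item Reading the Mind in the Eyes Test), aimed at researchers in
biostatistics and individual-differences research who want data-driven,
replicable subgroups rather than arbitrary total-score cut-points.

## The method

Given a filtered binary subjects × items matrix **X**:

1. **Subject similarity network.** Pairwise Hamming distance
   *d*<sub>ij</sub> = (# discordant items)/(# items); adjacency
   *a*<sub>ij</sub> = 1 − *d*<sub>ij</sub> after rescaling distances to full
   range; unsigned topological overlap

   TOM<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>) / (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>),  ℓ<sub>ij</sub> = Σ<sub>u≠i,j</sub> a<sub>iu</sub>a<sub>uj</sub>,  k<sub>i</sub> = Σ<sub>u≠i</sub> a<sub>iu</sub>

   so that two subjects count as similar when they agree with each other
   *and* with the same neighbours — more noise-robust than raw adjacency.
2. **Clustering.** Ward agglomerative clustering (Lance–Williams recurrence
   applied directly to the dissimilarity) of the TOM profiles, then a
   **dynamic hybrid tree cut**: each branch is cut at its own height using
   branch size, core scatter and separation-gap criteria (stringency set by
   `deep_split`, default 1), with optional nearest-cluster assignment of
   pruned outliers. The number of subgroups K is not chosen by the analyst —
   it emerges from the tree.
3. **Rank-ordered labels.** Subgroups are labelled 1..K by ascending mean
   total score, making labels comparable ("homologous") across independently
   stratified cohorts.
4. **Characterization.** ASC × TD effect-size grids (Student *t*, Cohen's
   *d*, Bonferroni over all K<sub>A</sub>×K<sub>B</sub> cells, optional
   covariate residualization), easy/difficult item split from item-axis
   clustering, per-subgroup item-difficulty profiles and their pairwise
   correlations with Benjamini–Hochberg FDR, cross-cohort subject
   dissimilarity matrices, and omnibus phenotype tests (ANOVA,
   Kruskal–Wallis, χ²).
5. **Replication test.** AdaBoost.M2 (pseudo-loss boosting over weighted
   linear-discriminant weak learners, 20 rounds) trained on one cohort's
   item responses and rank labels, evaluated on the other cohort, with
   significance from refitting under label permutations
   (p = (1 + #{null ≥ observed}) / (1 + n_perm)).

Because no public item-level dataset exists for the original design, the
package ships a latent-class generator (`eyestrat.synthetic`) whose default
banks plant 5 ASC-like / 4 TD-like subgroups with a near-linear gradient of
expected totals from chance level to ceiling; every claim in the test suite
is checked against such planted ground truth.

## Worked example

```python
from eyestrat import (binarize, make_profile_bank, simulate_cohort,
                      stratify_cohort, total_scores)

bank = make_profile_bank("asc_like", seed=0)   # 5 planted subgroups
table, planted = simulate_cohort(bank.with_seed(3))
m = binarize(table)                            # 400 subjects x 36 items
a = stratify_cohort(m)                         # the full pipeline
```

Output (see `examples/02_stratify.py`):

```
recovered K = 5 subgroups (planted: 5)
  subgroup 1: n= 80  mean total=  8.9
  subgroup 2: n= 81  mean total= 14.3
  subgroup 3: n= 81  mean total= 20.6
  subgroup 4: n= 78  mean total= 25.8
  subgroup 5: n= 80  mean total= 32.8
  unassigned outliers: 0
adjusted Rand index vs planted: 0.981
```

The cut recovered the planted partition almost exactly (ARI 0.98), with
subgroup 1 the lowest performers (mean 8.9/36, chance level) and subgroup 5
near ceiling. Training a classifier on a discovery cohort and predicting an
independent replication cohort (`examples/04_classify.py`) yields

```
5-way cross-cohort accuracy: 0.972 (chance = 0.20)
permutation test: p = 0.000999 (null accuracy range 0.064-0.408)
```

i.e. the subgroup divisions generalize across cohorts far above chance. The
other examples cover cohort simulation, subgroup characterization (effect
grids with |d| up to ~12 between the extreme subgroups, item-difficulty
correlations) and the one-call `run_full_analysis` report bundle.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the packaged analytic targets from scratch: it rebuilds each
fixture bank, draws 20 seeded replicate cohorts (ASC-like n=400, TD-like
n=320; 36 items), runs the full stratification on each, and writes the modal
number of subgroups per fixture as JSON.
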