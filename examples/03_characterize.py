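"""Characterize subgroups: effect sizes, item difficulty, item split.

Stratifies an ASC-like and a TD-like cohort, builds the ASC x TD grid of
total-score comparisons (Cohen's d with Bonferroni correction over all
cells), splits items into easy vs difficult, and correlates subgroup
item-difficulty profiles over the easy subset with BH-FDR control.
"""

import numpy as np

from eyestrat import (
    binarize,
    difficulty_correlation_grid,
    item_difficulty_profiles,
    make_profile_bank,
    pairwise_effect_grid,
    simulate_cohort,
    split_items_easy_difficult,
    stratify_cohort,
    total_scores,
)

asc_table, _ = simulate_cohort(make_profile_bank("asc_like", seed=0).with_seed(3), "ASC")
td_table, _ = simulate_cohort(make_profile_bank("td_like", seed=0).with_seed(4), "TD")
asc_m, td_m = binarize(asc_table), binarize(td_table)
asc_a, td_a = stratify_cohort(asc_m), stratify_cohort(td_m)

grid = pairwise_effect_grid(asc_a, total_scores(asc_m), td_a, total_scores(td_m))
print(f"effect grid: {grid.shape[0]} ASC x {grid.shape[1]} TD subgroups, "
      f"Bonferroni family = {grid.family_size}")
print("Cohen's d (rows = ASC subgroups 1..K, cols = TD subgroups 1..K):")
print(np.round(grid.cohens_d, 2))
print("significant after Bonferroni:")
print(grid.significant.astype(int))
# Negative d = ASC subgroup below TD subgroup. The worst ASC subgroups show
# very large deficits against every TD subgroup; the best overlap TD range.

split = split_items_easy_difficult(asc_m)
print(f"\nitem split: {len(split.easy)} easy / {len(split.difficult)} difficult")

profile = item_difficulty_profiles(asc_m, asc_a)
corr = difficulty_correlation_grid(profile, split, subset="easy", q=0.05)
print("item-difficulty correlations between ASC subgroups (easy items):")
print(np.round(corr.r, 2))
print("FDR-significant pairs (q < 0.05):", int(corr.significant.sum() // 2))
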