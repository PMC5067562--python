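"""Effect-size grids, item-difficulty analysis, FDR, phenotype tests."""

import numpy as np
import pandas as pd
import pytest

from eyestrat import (
    ItemResponseMatrix,
    ItemSplit,
    PhenotypeTable,
    bh_fdr,
    cohens_d,
    cross_cohort_dissimilarity,
    difficulty_correlation_grid,
    item_difficulty_profiles,
    pairwise_effect_grid,
    phenotype_association_tests,
    rank_order_subgroups,
)
from eyestrat.characterization import UndefinedEffectError


def assignment_from_labels(labels, scores=None):
    labels = np.asarray(labels)
    if scores is None:
        scores = labels.astype(float)  # means already ordered
    return rank_order_subgroups(labels, np.asarray(scores, dtype=float))


def bh_oracle(p, q):
    """Brute-force step-up: largest i with p_(i) <= i q / m flags all below."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    cutoff = -1
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            cutoff = rank
    if cutoff > 0:
        flags[order[:cutoff]] = True
    return flags


class TestCohensD:
    def test_identical_samples_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_hand_evaluated_shift(self):
        # pooled SD = 1, mean difference = -2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_location_invariance(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 40)
        assert cohens_d(x + 7, y + 7) == pytest.approx(cohens_d(x, y))

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d([2, 2, 2], [2, 2, 2])


class TestEffectGrid:
    def test_five_by_four_grid_family_size(self, rng):
        la = np.repeat(np.arange(1, 6), 30)
        lb = np.repeat(np.arange(1, 5), 30)
        sa = la * 3 + rng.normal(0, 1, la.size)
        sb = lb * 3 + rng.normal(0, 1, lb.size)
        grid = pairwise_effect_grid(
            assignment_from_labels(la, sa), sa, assignment_from_labels(lb, sb), sb
        )
        assert grid.shape == (5, 4)
        assert grid.family_size == 20
        assert not grid.untestable.any()

    def test_self_comparison_null(self, rng):
        labels = np.repeat([1, 2], 25)
        scores = labels * 2.0 + rng.normal(0, 1, 50)
        a = assignment_from_labels(labels, scores)
        grid = pairwise_effect_grid(a, scores, a, scores)
        assert np.allclose(np.diag(grid.cohens_d), 0.0)
        assert np.allclose(np.diag(grid.p_value), 1.0)

    def test_independent_covariate_leaves_d_stable(self):
        rng = np.random.default_rng(11)
        la = np.repeat([1, 2], 300)
        sa = np.where(la == 2, 2.0, 0.0) + rng.normal(0, 1, 600)
        lb = np.ones(400, dtype=int)
        sb = 1.0 + rng.normal(0, 1, 400)
        cov_a = rng.normal(0, 1, 600)
        cov_b = rng.normal(0, 1, 400)
        a = assignment_from_labels(la, sa)
        b = assignment_from_labels(lb, sb)
        raw = pairwise_effect_grid(a, sa, b, sb)
        adj = pairwise_effect_grid(a, sa, b, sb, covariate_a=cov_a, covariate_b=cov_b)
        assert np.abs(adj.cohens_d - raw.cohens_d).max() <= 0.1

    def test_tiny_subgroup_flagged_untestable(self):
        la = np.array([1, 2, 2, 2])
        sa = np.array([5.0, 1.0, 2.0, 3.0])
        lb = np.array([1, 1, 1])
        sb = np.array([4.0, 5.0, 6.0])
        grid = pairwise_effect_grid(
            assignment_from_labels(la, sa), sa, assignment_from_labels(lb, sb), sb
        )
        # the singleton subgroup has the higher mean score -> rank label 2
        assert grid.untestable[1, 0]
        assert not grid.untestable[0, 0]


class TestDifficultyProfiles:
    def _matrix(self, rows):
        rows = np.asarray(rows)
        return ItemResponseMatrix(
            subject_ids=tuple(f"s{i}" for i in range(rows.shape[0])),
            group=("ASC",) * rows.shape[0],
            cohort=("d",) * rows.shape[0],
            item_ids=tuple(f"i{j}" for j in range(rows.shape[1])),
            matrix=rows,
        )

    def test_hand_counted_percentages(self):
        m = self._matrix([[1, 1], [1, 0], [1, 0], [0, 0]])
        a = assignment_from_labels([1, 1, 1, 1])
        prof = item_difficulty_profiles(m, a)
        assert prof.loc[1, "i0"] == pytest.approx(75.0)
        assert prof.loc[1, "i1"] == pytest.approx(25.0)

    def test_ceiling_subgroup(self):
        m = self._matrix(np.ones((5, 3), dtype=int))
        prof = item_difficulty_profiles(m, assignment_from_labels([1] * 5))
        assert (prof.to_numpy() == 100.0).all()

    def test_profiles_track_planted_probabilities(self, asc_cohort, asc_bank):
        m, planted = asc_cohort
        a = assignment_from_labels(planted)
        prof = item_difficulty_profiles(m, a).to_numpy() / 100.0
        for g in range(asc_bank.n_subgroups):
            p = asc_bank.profiles[g]
            n = (planted == g + 1).sum()
            se = np.sqrt(p * (1 - p) / n)
            assert (np.abs(prof[g] - p) <= 3 * se + 1e-9).mean() >= 0.95


class TestBhFdr:
    def test_step_up_hand_example(self):
        flags = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_null_and_extreme_cases(self):
        assert not bh_fdr([1.0, 1.0, 1.0]).any()
        assert bh_fdr([0.0, 0.0, 0.0]).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            q = float(rng.choice([0.01, 0.05, 0.1]))
            assert (bh_fdr(p, q) == bh_oracle(p, q)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCorrelationGrid:
    def _profile(self, rows, items=None):
        rows = np.asarray(rows, dtype=float)
        cols = items or [f"i{j}" for j in range(rows.shape[1])]
        return pd.DataFrame(rows, index=range(1, rows.shape[0] + 1), columns=cols)

    def test_identical_profiles_correlate_perfectly(self):
        prof = self._profile([[10, 50, 90, 30], [10, 50, 90, 30]])
        split = ItemSplit(easy=("i0", "i1", "i2", "i3"), difficult=())
        grid = difficulty_correlation_grid(prof, split, subset="easy")
        assert grid.r[0, 1] == pytest.approx(1.0)

    def test_grid_symmetric_unit_diagonal(self, rng):
        prof = self._profile(rng.random((4, 8)) * 100)
        split = ItemSplit(easy=tuple(f"i{j}" for j in range(8)), difficult=())
        grid = difficulty_correlation_grid(prof, split, subset="easy")
        assert np.allclose(grid.r, grid.r.T, equal_nan=True)
        assert np.allclose(np.diag(grid.r), 1.0)

    def test_null_profiles_rarely_flagged(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            prof = self._profile(rng.normal(50, 10, (3, 20)))
            split = ItemSplit(easy=tuple(f"i{j}" for j in range(20)), difficult=())
            grid = difficulty_correlation_grid(prof, split, subset="easy")
            if grid.significant.any():
                hits += 1
        assert hits <= 10  # no flags in >= 90% of null simulations

    def test_constant_profile_untestable(self):
        prof = self._profile([[50, 50, 50, 50], [10, 20, 30, 40]])
        split = ItemSplit(easy=("i0", "i1", "i2", "i3"), difficult=())
        grid = difficulty_correlation_grid(prof, split, subset="easy")
        assert grid.untestable[0, 1]


class TestCrossCohortDissimilarity:
    def _matrix(self, rows, cohort="d"):
        rows = np.asarray(rows)
        return ItemResponseMatrix(
            subject_ids=tuple(f"{cohort}s{i}" for i in range(rows.shape[0])),
            group=("ASC",) * rows.shape[0],
            cohort=(cohort,) * rows.shape[0],
            item_ids=tuple(f"i{j}" for j in range(rows.shape[1])),
            matrix=rows,
        )

    def test_identical_rows_zero_block(self):
        m = self._matrix(np.tile([1, 0, 1, 1], (5, 1)))
        a = assignment_from_labels([1] * 5)
        dis, blocks = cross_cohort_dissimilarity([(m, a)], m.item_ids)
        assert np.allclose(dis, 0.0)
        assert blocks[0]["stop"] == 5

    def test_row_count_conserved_and_rank_ordered(self, rng):
        m1 = self._matrix(rng.integers(0, 2, (8, 4)), cohort="d")
        m2 = self._matrix(rng.integers(0, 2, (6, 4)), cohort="r")
        a1 = assignment_from_labels([1, 1, 2, 2, 1, 2, 1, 2])
        a2 = assignment_from_labels([2, 1, 2, 1, 1, 2])
        dis, blocks = cross_cohort_dissimilarity([(m1, a1), (m2, a2)], m1.item_ids)
        assert dis.shape == (14, 14)
        assert [b["subgroup"] for b in blocks] == [1, 2, 1, 2]

    def test_within_pole_tighter_than_between_extremes(self, asc_cohort):
        m, planted = asc_cohort
        a = assignment_from_labels(planted)
        dis, blocks = cross_cohort_dissimilarity([(m, a)], m.item_ids)
        first = next(b for b in blocks if b["subgroup"] == 1)
        last = next(b for b in blocks if b["subgroup"] == a.n_subgroups)
        w = dis[first["start"]:first["stop"], first["start"]:first["stop"]]
        between = dis[first["start"]:first["stop"], last["start"]:last["stop"]]
        assert w[np.triu_indices_from(w, k=1)].mean() < between.mean()

    def test_missing_item_rejected(self, rng):
        m = self._matrix(rng.integers(0, 2, (4, 3)))
        a = assignment_from_labels([1, 1, 1, 1])
        with pytest.raises(ValueError):
            cross_cohort_dissimilarity([(m, a)], ["nope"])


class TestPhenotypeTests:
    def _pheno(self, frame):
        return PhenotypeTable(frame=frame.set_index("subject_id"))

    def test_balanced_sex_counts_give_zero_chi_square(self):
        ids = [f"s{i}" for i in range(12)]
        frame = pd.DataFrame(
            {"subject_id": ids, "sex": ["M", "F"] * 6}
        )
        labels = np.repeat([1, 2, 3], 4)
        a = assignment_from_labels(labels)
        a = rank_order_subgroups(labels, labels.astype(float), subject_ids=ids)
        res = phenotype_association_tests(
            self._pheno(frame), a, {"sex": "chi_square"}
        )
        assert res.loc[0, "statistic"] == pytest.approx(0.0)

    def test_anova_hand_example(self):
        ids = [f"s{i}" for i in range(9)]
        vals = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        frame = pd.DataFrame({"subject_id": ids, "VIQ": vals})
        labels = np.repeat([1, 2, 3], 3)
        a = rank_order_subgroups(labels, labels.astype(float), subject_ids=ids)
        res = phenotype_association_tests(self._pheno(frame), a, {"VIQ": "anova"})
        assert res.loc[0, "statistic"] == pytest.approx(3.0)
        assert res.loc[0, "df"] == (2, 6)

    def test_identical_groups_kruskal_zero(self):
        ids = [f"s{i}" for i in range(9)]
        frame = pd.DataFrame({"subject_id": ids, "AQ": [30.0] * 9})
        labels = np.repeat([1, 2, 3], 3)
        a = rank_order_subgroups(labels, labels.astype(float), subject_ids=ids)
        res = phenotype_association_tests(
            self._pheno(frame), a, {"AQ": "kruskal_wallis"}
        )
        assert res.loc[0, "statistic"] == pytest.approx(0.0)

    def test_sparse_variable_flagged_untestable(self):
        ids = [f"s{i}" for i in range(6)]
        frame = pd.DataFrame(
            {"subject_id": ids, "BDI": [np.nan, np.nan, 4, 5, 6, 7]}
        )
        labels = np.repeat([1, 2], 3)
        a = rank_order_subgroups(labels, labels.astype(float), subject_ids=ids)
        res = phenotype_association_tests(self._pheno(frame), a, {"BDI": "anova"})
        assert bool(res.loc[0, "untestable"])
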