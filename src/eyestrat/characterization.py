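"""Subgroup characterization statistics.

Once each cohort is stratified, subgroups are characterized by (a) pairwise
effect-size grids of total scores between the subgroups of two diagnostic
groups (Student t-tests with Bonferroni correction over the full grid, Cohen's
d in pooled-SD units, optionally after residualizing scores on a covariate
such as verbal IQ), (b) item-difficulty profiles (percent correct per item per
subgroup) and their pairwise correlations over easy or difficult item subsets
with Benjamini-Hochberg FDR control, (c) a concatenated cross-cohort subject
dissimilarity matrix for descriptive inspection of within/between subgroup
similarity, and (d) omnibus phenotype association tests across subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ItemSplit, SubgroupAssignment
from .data_model import ItemResponseMatrix, PhenotypeTable, ValidationError


class UndefinedEffectError(ValueError):
    """Effect size undefined (zero pooled variance)."""


def cohens_d(x, y) -> float:
    """Standardized mean difference ``(mean(x) - mean(y)) / s_pooled``.

    ``s_pooled**2 = [(n_x-1) s_x**2 + (n_y-1) s_y**2] / (n_x + n_y - 2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("cohens_d needs at least 2 observations per sample")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise UndefinedEffectError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


@dataclass(frozen=True)
class EffectSizeGrid:
    """K_A x K_B grid of pairwise two-sample comparisons.

    Row subgroup minus column subgroup throughout (mean difference and d
    share the sign convention). ``significant`` applies Bonferroni at
    ``alpha / family_size`` with ``family_size = K_A * K_B``.
    """

    mean_diff: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    cohens_d: np.ndarray
    significant: np.ndarray
    untestable: np.ndarray
    family_size: int
    alpha: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_diff.shape


def _residualize(scores: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(covariate)), covariate])
    beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
    return scores - X @ beta


def pairwise_effect_grid(
    a: SubgroupAssignment,
    scores_a: np.ndarray,
    b: SubgroupAssignment,
    scores_b: np.ndarray,
    covariate_a: np.ndarray | None = None,
    covariate_b: np.ndarray | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> EffectSizeGrid:
    """Total-score comparisons for every (a-subgroup, b-subgroup) pair.

    One pooled-variance Student t-test (Welch optional) and Cohen's d per
    cell; significance by Bonferroni over the K_A x K_B family. When
    covariates are given, scores of both cohorts are first residualized on
    the covariate by least squares in the combined sample — the
    "controlling for the covariate" re-analysis. Cells with a subgroup of
    size < 2 are flagged untestable, never dropped.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if (covariate_a is None) != (covariate_b is None):
        raise ValueError("covariate must be given for both sides or neither")
    if covariate_a is not None:
        cov = np.concatenate([np.asarray(covariate_a, float), np.asarray(covariate_b, float)])
        combined = _residualize(np.concatenate([scores_a, scores_b]), cov)
        scores_a = combined[: len(scores_a)]
        scores_b = combined[len(scores_a):]
    ka, kb = a.n_subgroups, b.n_subgroups
    family = ka * kb
    shape = (ka, kb)
    md = np.full(shape, np.nan)
    t = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    d = np.full(shape, np.nan)
    unt = np.zeros(shape, dtype=bool)
    for i in range(ka):
        xi = scores_a[a.labels == i + 1]
        for j in range(kb):
            yj = scores_b[b.labels == j + 1]
            if len(xi) < 2 or len(yj) < 2:
                unt[i, j] = True
                continue
            md[i, j] = xi.mean() - yj.mean()
            try:
                d[i, j] = cohens_d(xi, yj)
            except UndefinedEffectError:
                unt[i, j] = True
                continue
            res = stats.ttest_ind(xi, yj, equal_var=not welch)
            t[i, j], p[i, j] = res.statistic, res.pvalue
    sig = np.zeros(shape, dtype=bool)
    tested = ~unt & ~np.isnan(p)
    sig[tested] = p[tested] < alpha / family
    return EffectSizeGrid(
        mean_diff=md,
        t_stat=t,
        p_value=p,
        cohens_d=d,
        significant=sig,
        untestable=unt,
        family_size=family,
        alpha=alpha,
    )


def item_difficulty_profiles(
    m: ItemResponseMatrix, a: SubgroupAssignment
) -> pd.DataFrame:
    """Percent of each subgroup answering each item correctly (0-100).

    Rows are subgroup labels 1..K, columns are item IDs; unassigned
    subjects are excluded.
    """
    if len(a.labels) != m.n_subjects:
        raise ValidationError("assignment does not cover the matrix subjects")
    rows = {}
    for k in range(1, a.n_subgroups + 1):
        mask = a.labels == k
        if not mask.any():
            raise ValueError(f"subgroup {k} is empty")
        rows[k] = 100.0 * m.matrix[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(m.item_ids))


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass(frozen=True)
class CorrelationGrid:
    """Symmetric K x K grid of subgroup item-difficulty correlations."""

    r: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    untestable: np.ndarray
    q: float
    subset: str


def difficulty_correlation_grid(
    profile: pd.DataFrame,
    items: ItemSplit,
    subset: str = "easy",
    q: float = 0.05,
    method: str = "pearson",
) -> CorrelationGrid:
    """Pairwise subgroup correlations of item difficulty over one item subset.

    Pearson (default) or Spearman correlation between every unordered pair
    of subgroup difficulty vectors restricted to the easy or difficult item
    set; two-sided p-values, BH-FDR flags over the unordered pairs.
    Constant profile vectors make a pair untestable.
    """
    if subset not in ("easy", "difficult"):
        raise ValueError("subset must be 'easy' or 'difficult'")
    cols = list(items.easy if subset == "easy" else items.difficult)
    if len(cols) < 3:
        raise ValueError("need at least 3 items in the subset")
    sub = profile[cols].to_numpy(dtype=float)
    k = sub.shape[0]
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.eye(k)
    p = np.zeros((k, k))
    unt = np.zeros((k, k), dtype=bool)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    pair_p = []
    for i, j in pairs:
        if np.std(sub[i]) == 0 or np.std(sub[j]) == 0:
            unt[i, j] = unt[j, i] = True
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            pair_p.append(np.nan)
            continue
        res = corr(sub[i], sub[j])
        r[i, j] = r[j, i] = res.statistic
        p[i, j] = p[j, i] = res.pvalue
        pair_p.append(res.pvalue)
    sig = np.zeros((k, k), dtype=bool)
    testable = [idx for idx, v in enumerate(pair_p) if not np.isnan(v)]
    if testable:
        flags = bh_fdr([pair_p[idx] for idx in testable], q=q)
        for flag, idx in zip(flags, testable):
            i, j = pairs[idx]
            sig[i, j] = sig[j, i] = bool(flag)
    return CorrelationGrid(r=r, p_value=p, significant=sig, untestable=unt, q=q, subset=subset)


def cross_cohort_dissimilarity(
    cohorts: list[tuple[ItemResponseMatrix, SubgroupAssignment]],
    item_subset,
) -> tuple[np.ndarray, list[dict]]:
    """Concatenated subject Hamming matrix ordered by subgroup rank.

    Subjects are ordered by subgroup label (1..K, then unassigned) within
    each cohort, cohorts adjacent; the Hamming matrix is computed over the
    given item subset. Returns the matrix and a block index of
    (cohort, subgroup, start, stop) records for plotting or summary.
    """
    item_subset = list(item_subset)
    rows = []
    blocks = []
    start = 0
    for m, a in cohorts:
        missing = set(item_subset) - set(m.item_ids)
        if missing:
            raise ValidationError(f"cohort lacks items: {sorted(missing)[:5]}")
        idx = [m.item_ids.index(i) for i in item_subset]
        cohort_tag = m.cohort[0] if m.cohort else ""
        for k in list(range(1, a.n_subgroups + 1)) + [0]:
            sel = np.flatnonzero(a.labels == k)
            if len(sel) == 0:
                continue
            rows.append(m.matrix[np.ix_(sel, idx)])
            blocks.append(
                {
                    "cohort": cohort_tag,
                    "subgroup": k,
                    "start": start,
                    "stop": start + len(sel),
                }
            )
            start += len(sel)
    stacked = np.vstack(rows).astype(float)
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(stacked, metric="hamming")), blocks


def phenotype_association_tests(
    pheno: PhenotypeTable,
    a: SubgroupAssignment,
    test_spec: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Omnibus tests of phenotype differences across subgroups.

    ``test_spec`` maps variable name to one of ``anova`` (one-way F),
    ``kruskal_wallis`` (for skewed measures) or ``chi_square`` (categorical
    counts vs expected). Significant omnibus tests are followed by
    Bonferroni-corrected pairwise post-hocs (t-tests for ANOVA variables,
    rank-sum for Kruskal-Wallis). Variables with any subgroup holding fewer
    than 2 usable observations are flagged untestable rather than dropped.
    """
    frame = pheno.aligned_to(a.subject_ids)
    records = []
    for var, kind in test_spec.items():
        if kind not in ("anova", "kruskal_wallis", "chi_square"):
            raise ValueError(f"unknown test {kind!r} for variable {var!r}")
        if var not in frame.columns:
            raise ValidationError(f"phenotype variable {var!r} missing")
        rec = {"variable": var, "test": kind, "untestable": False,
               "statistic": np.nan, "df": np.nan, "p_value": np.nan,
               "posthoc": None}
        if kind == "chi_square":
            mask = a.labels > 0
            table = pd.crosstab(a.labels[mask], frame[var].to_numpy()[mask])
            if table.shape[0] < 2 or table.shape[1] < 2:
                rec["untestable"] = True
            else:
                chi2, p, dof, _ = stats.chi2_contingency(table)
                rec.update(statistic=chi2, df=dof, p_value=p)
            records.append(rec)
            continue
        groups = []
        for k in range(1, a.n_subgroups + 1):
            vals = frame[var].to_numpy(dtype=float)[a.labels == k]
            groups.append(vals[~np.isnan(vals)])
        if any(len(g) < 2 for g in groups):
            rec["untestable"] = True
            records.append(rec)
            continue
        if kind == "anova":
            stat, p = stats.f_oneway(*groups)
            rec.update(statistic=stat, p_value=p,
                       df=(len(groups) - 1, sum(len(g) for g in groups) - len(groups)))
        else:
            if np.ptp(np.concatenate(groups)) == 0:
                stat, p = 0.0, 1.0  # scipy rejects all-identical samples
            else:
                stat, p = stats.kruskal(*groups)
            rec.update(statistic=stat, df=len(groups) - 1, p_value=p)
        if rec["p_value"] is not None and not np.isnan(rec["p_value"]) and rec["p_value"] < alpha:
            pairs = {}
            n_pairs = len(groups) * (len(groups) - 1) // 2
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if kind == "anova":
                        _, pp = stats.ttest_ind(groups[i], groups[j])
                    else:
                        _, pp = stats.mannwhitneyu(
                            groups[i], groups[j], alternative="two-sided"
                        )
                    pairs[(i + 1, j + 1)] = {
                        "p_raw": float(pp),
                        "p_bonferroni": float(min(1.0, pp * n_pairs)),
                    }
            rec["posthoc"] = pairs
        records.append(rec)
    return pd.DataFrame.from_records(records)
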