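"""End-to-end orchestration of the stratification analysis.

A :class:`RunConfig` describes one full run — either simulated cohorts (the
default, since no public item-level data exist for the original design) or
response tables loaded from disk — together with every stage parameter.
:func:`run_full_analysis` executes filter -> binarize -> stratify (per group,
per cohort) -> effect grids -> item split -> difficulty analysis ->
cross-cohort dissimilarity -> classification with permutation test ->
phenotype tests (when a phenotype table is given), writes all stage outputs
under the configured directory, and returns the summary dictionary. Reruns
with the same config are bit-identical.

Config files are flat ``key = value`` text; unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .characterization import (
    cross_cohort_dissimilarity,
    difficulty_correlation_grid,
    item_difficulty_profiles,
    pairwise_effect_grid,
    phenotype_association_tests,
)
from .classification import evaluate_predictions, permutation_null_test, predict_subgroups, train_adaboost_m2
from .clustering import split_items_easy_difficult, stratify_cohort
from .data_model import (
    RunLog,
    apply_timeout_filter,
    binarize,
    load_phenotype_table,
    load_response_table,
    total_scores,
)
from .synthetic import make_profile_bank, simulate_cohort_pair

_pkg_version = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of one full analysis run."""

    # input: either simulate (default) or load four response tables
    simulate: bool = True
    n_discovery: int = 400
    n_replication: int = 250
    td_n_discovery: int = 320
    td_n_replication: int = 200
    asc_discovery_path: str | None = None
    asc_replication_path: str | None = None
    td_discovery_path: str | None = None
    td_replication_path: str | None = None
    phenotype_path: str | None = None
    # stage parameters
    timeout_threshold: int = 9
    min_cluster_size: int = 20
    deep_split: int = 1
    assign_outliers: bool = True
    alpha: float = 0.05
    q: float = 0.05
    rounds: int = 20
    n_perm: int = 1000
    seed: int = 0
    output_dir: str = "eyestrat_run"


_BOOL_KEYS = {"simulate", "assign_outliers"}
_FLOAT_KEYS = {"alpha", "q"}
_STR_KEYS = {
    "asc_discovery_path", "asc_replication_path", "td_discovery_path",
    "td_replication_path", "phenotype_path", "output_dir",
}


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if raw.lower() in ("none", ""):
            values[key] = None
        elif key in _BOOL_KEYS:
            values[key] = raw.lower() in ("1", "true", "yes")
        elif key in _FLOAT_KEYS:
            values[key] = float(raw)
        elif key in _STR_KEYS:
            values[key] = raw
        else:
            values[key] = int(raw)
    return RunConfig(**values)


def _load_or_simulate(config: RunConfig):
    """Return dict of (group, cohort) -> RawResponseTable."""
    if config.simulate:
        asc_bank = make_profile_bank("asc_like", seed=config.seed)
        td_bank = make_profile_bank("td_like", seed=config.seed + 1)
        asc_d, _, asc_r, _ = simulate_cohort_pair(
            asc_bank, config.n_discovery, config.n_replication,
            seeds=(config.seed * 4 + 1, config.seed * 4 + 2), group_tag="ASC",
        )
        td_d, _, td_r, _ = simulate_cohort_pair(
            td_bank, config.td_n_discovery, config.td_n_replication,
            seeds=(config.seed * 4 + 3, config.seed * 4 + 4), group_tag="TD",
        )
        return {
            ("ASC", "discovery"): asc_d,
            ("ASC", "replication"): asc_r,
            ("TD", "discovery"): td_d,
            ("TD", "replication"): td_r,
        }
    paths = {
        ("ASC", "discovery"): config.asc_discovery_path,
        ("ASC", "replication"): config.asc_replication_path,
        ("TD", "discovery"): config.td_discovery_path,
        ("TD", "replication"): config.td_replication_path,
    }
    tables = {}
    for key, p in paths.items():
        if p is None or not Path(p).exists():
            raise FileNotFoundError(
                f"stage input: missing response table for {key}: {p!r}"
            )
        tables[key] = load_response_table(p)
    return tables


def _grid_to_frame(grid, row_prefix: str, col_prefix: str) -> pd.DataFrame:
    ka, kb = grid.shape
    rows = []
    for i in range(ka):
        for j in range(kb):
            rows.append(
                {
                    "row_subgroup": f"{row_prefix}{i + 1}",
                    "col_subgroup": f"{col_prefix}{j + 1}",
                    "mean_diff": grid.mean_diff[i, j],
                    "t": grid.t_stat[i, j],
                    "p": grid.p_value[i, j],
                    "cohens_d": grid.cohens_d[i, j],
                    "significant": bool(grid.significant[i, j]),
                    "untestable": bool(grid.untestable[i, j]),
                }
            )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run every pipeline stage and write the report bundle.

    Returns the JSON-serializable summary that is also written to
    ``<output_dir>/summary.json``. Deterministic for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    log.record("package_version", _pkg_version)
    for key, value in asdict(config).items():
        log.record(f"config.{key}", value)

    tables = _load_or_simulate(config)
    summary: dict = {"config": asdict(config), "groups": {}}
    manifest: list[str] = []

    matrices = {}
    assignments = {}
    for (group, cohort), raw in tables.items():
        filtered, excluded = apply_timeout_filter(raw, config.timeout_threshold)
        log.record(f"excluded.{group}.{cohort}", excluded)
        m = binarize(filtered)
        matrices[(group, cohort)] = m
        a = stratify_cohort(
            m,
            min_cluster_size=config.min_cluster_size,
            deep_split=config.deep_split,
            assign_outliers=config.assign_outliers,
            seed=config.seed,
        )
        assignments[(group, cohort)] = a
        frame = pd.DataFrame(
            {
                "subject_id": m.subject_ids,
                "group": m.group,
                "cohort": m.cohort,
                "subgroup": a.labels,
                "total_score": total_scores(m),
            }
        )
        path = out / f"assignment_{group}_{cohort}.csv"
        frame.to_csv(path, index=False)
        manifest.append(path.name)
        summary["groups"].setdefault(group, {})[cohort] = {
            "n_subjects": m.n_subjects,
            "n_excluded": len(excluded),
            "n_subgroups": a.n_subgroups,
            "subgroup_mean_scores": [round(v, 6) for v in a.subgroup_mean_scores],
            "subgroup_sizes": [int((a.labels == k).sum()) for k in range(1, a.n_subgroups + 1)],
            "n_unassigned": int((a.labels == 0).sum()),
        }

    # ASC vs TD effect-size grids per cohort
    summary["effect_grids"] = {}
    for cohort in ("discovery", "replication"):
        asc_m, td_m = matrices[("ASC", cohort)], matrices[("TD", cohort)]
        grid = pairwise_effect_grid(
            assignments[("ASC", cohort)], total_scores(asc_m),
            assignments[("TD", cohort)], total_scores(td_m),
            alpha=config.alpha,
        )
        frame = _grid_to_frame(grid, "ASC", "TD")
        path = out / f"effect_grid_{cohort}.csv"
        frame.to_csv(path, index=False)
        manifest.append(path.name)
        summary["effect_grids"][cohort] = {
            "family_size": grid.family_size,
            "n_significant": int(grid.significant.sum()),
            "d_min": round(float(np.nanmin(grid.cohens_d)), 6),
            "d_max": round(float(np.nanmax(grid.cohens_d)), 6),
        }

    # item split + difficulty analysis on the ASC discovery cohort
    split = split_items_easy_difficult(matrices[("ASC", "discovery")])
    summary["item_split"] = {
        "easy": list(split.easy),
        "difficult": list(split.difficult),
    }
    summary["difficulty_correlations"] = {}
    for cohort in ("discovery", "replication"):
        m = matrices[("ASC", cohort)]
        a = assignments[("ASC", cohort)]
        profile = item_difficulty_profiles(m, a)
        path = out / f"difficulty_profile_ASC_{cohort}.csv"
        profile.to_csv(path)
        manifest.append(path.name)
        cohort_summary = {}
        for subset in ("easy", "difficult"):
            grid = difficulty_correlation_grid(profile, split, subset=subset, q=config.q)
            cohort_summary[subset] = {
                "n_significant_pairs": int(grid.significant.sum() // 2),
                "mean_offdiag_r": round(
                    float(np.nanmean(grid.r[~np.eye(len(grid.r), dtype=bool)])), 6
                ),
            }
        summary["difficulty_correlations"][cohort] = cohort_summary

    # cross-cohort dissimilarity (ASC, easy items)
    dis, blocks = cross_cohort_dissimilarity(
        [
            (matrices[("ASC", "discovery")], assignments[("ASC", "discovery")]),
            (matrices[("ASC", "replication")], assignments[("ASC", "replication")]),
        ],
        split.easy,
    )
    summary["cross_cohort_dissimilarity"] = {
        "n_subjects": int(dis.shape[0]),
        "n_blocks": len(blocks),
        "mean_distance": round(float(dis[np.triu_indices_from(dis, k=1)].mean()), 6),
    }

    # discovery -> replication classification per group, with permutation test
    summary["classification"] = {}
    for group in ("ASC", "TD"):
        tr_m, tr_a = matrices[(group, "discovery")], assignments[(group, "discovery")]
        te_m, te_a = matrices[(group, "replication")], assignments[(group, "replication")]
        tr_mask, te_mask = tr_a.labels > 0, te_a.labels > 0
        Xtr, ytr = tr_m.matrix[tr_mask], tr_a.labels[tr_mask]
        Xte, yte = te_m.matrix[te_mask], te_a.labels[te_mask]
        model = train_adaboost_m2(Xtr, ytr, rounds=config.rounds, seed=config.seed)
        pred = predict_subgroups(model, Xte)
        k = max(tr_a.n_subgroups, te_a.n_subgroups)
        merges = []
        if k >= 3:
            merges.append([set(range(1, k // 2 + 1)), set(range(k // 2 + 1, k + 1))])
        if k >= 4:
            merges.append([set(range(1, k // 2 + 2)), set(range(k // 2 + 2, k + 1))])
        evaluation = evaluate_predictions(
            yte, pred, class_labels=np.arange(1, k + 1), merges=merges
        )
        perm = permutation_null_test(
            (Xtr, ytr), (Xte, yte), rounds=config.rounds,
            n_perm=config.n_perm, seed=config.seed,
        )
        conf = pd.DataFrame(
            evaluation["confusion"],
            index=[f"actual_{i}" for i in range(1, k + 1)],
            columns=[f"predicted_{i}" for i in range(1, k + 1)],
        )
        path = out / f"confusion_{group}.csv"
        conf.to_csv(path)
        manifest.append(path.name)
        null_path = out / f"null_accuracies_{group}.csv"
        pd.DataFrame({"null_accuracy": perm.null_accuracies}).to_csv(null_path, index=False)
        manifest.append(null_path.name)
        summary["classification"][group] = {
            "accuracy": round(evaluation["accuracy"], 6),
            "merged": [
                {"merge": [list(map(int, g)) for g in m_["merge"]],
                 "accuracy": round(m_["accuracy"], 6)}
                for m_ in evaluation["merged"]
            ],
            "n_permutations": perm.n_permutations,
            "p_value": round(perm.p_value, 8),
            "p_raw": round(perm.p_raw, 8),
        }

    # phenotype association tests (optional)
    if config.phenotype_path is not None:
        pheno = load_phenotype_table(config.phenotype_path)
        spec = {}
        numeric = pheno.frame.select_dtypes("number").columns
        for var in pheno.frame.columns:
            if var in ("AQ", "EQ"):
                spec[var] = "kruskal_wallis"
            elif var in numeric:
                spec[var] = "anova"
            else:
                spec[var] = "chi_square"
        stats_table = phenotype_association_tests(
            pheno, assignments[("ASC", "discovery")], spec, alpha=config.alpha
        )
        path = out / "phenotype_tests.csv"
        stats_table.drop(columns=["posthoc"]).to_csv(path, index=False)
        manifest.append(path.name)
        summary["phenotypes"] = {
            r["variable"]: {
                "test": r["test"],
                "p": None if pd.isna(r["p_value"]) else round(float(r["p_value"]), 8),
                "untestable": bool(r["untestable"]),
            }
            for r in stats_table.to_dict("records")
        }

    summary["manifest"] = sorted(manifest + ["summary.json", "run.log"])
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.record("manifest", summary["manifest"])
    log.write(out / "run.log")
    return summary
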