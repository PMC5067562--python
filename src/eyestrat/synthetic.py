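"""Latent-class synthetic cohorts of binary item responses.

The study design this emulates has no deposited item-level data, so every
stage of the pipeline is exercised on simulated cohorts: K latent subgroups,
each characterized by a vector of per-item success probabilities, with
subjects drawn as conditionally independent Bernoulli trials given their
subgroup.

The default profile banks are built from a mastery model: each subgroup has
*mastered* a fraction of the items (success probability near ceiling) and
answers the remainder consistently wrongly (success probability near zero —
on a task whose distractors are systematically attractive, non-masters do
not guess at the nominal chance rate but converge on the same wrong answer).
Mastery sets are nested along a common item-difficulty order, with a few
idiosyncratic swaps per subgroup so that subgroups differ in patterning and
not only in level. This reproduces the qualitative structure the analysis
expects: subgroup expected totals ascending near-linearly from the
4-alternative chance-level total to near ceiling, tight within-subgroup
similarity at both poles of the performance hierarchy, and an easy/difficult
item subdivision shared across subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_model import CORRECT, INCORRECT, TIMEOUT, RawResponseTable

# Mastered fractions of the planted subgroups. The ASC-like bank spans
# near-chance expected totals to near-ceiling (5 subgroups); the TD-like
# bank has a higher floor (4 subgroups), mirroring a comparison population
# whose worst performers are still well above chance. With the default
# success rates below, the lowest ASC-like subgroup's expected accuracy sits
# at the 4-alternative chance rate of 0.25.
_ASC_MASTERY = (0.22, 0.40, 0.58, 0.76, 0.97)
_TD_MASTERY = (0.50, 0.67, 0.84, 1.00)

_P_MASTERED = 0.93  # success rate on mastered items
_P_UNMASTERED = 0.05  # consistent-wrong rate on unmastered items

# idiosyncratic mastered/unmastered item swaps per subgroup (patterning)
_N_SWAPS = 2

_DEFAULT_SUBGROUP_SIZE = 80


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a latent-class cohort."""

    profiles: np.ndarray  # (K, n_items) success probabilities
    sizes: tuple[int, ...]
    chance_floor: float = 0.25
    ability_jitter: float = 0.0  # per-subject logit-scale SD
    timeout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles, dtype=float)
        object.__setattr__(self, "profiles", p)
        if p.ndim != 2:
            raise ValueError("profiles must be a (K, n_items) array")
        if len(self.sizes) != p.shape[0]:
            raise ValueError("one size per profile required")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("subgroup sizes must be positive")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("profiles must lie in [0, 1]")
        if not 0 <= self.timeout_rate < 1:
            raise ValueError("timeout_rate must be in [0, 1)")

    @property
    def n_subgroups(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_items(self) -> int:
        return self.profiles.shape[1]

    @property
    def n_subjects(self) -> int:
        return int(sum(self.sizes))

    def expected_totals(self) -> np.ndarray:
        """Expected total score of a subject from each subgroup."""
        return self.profiles.sum(axis=1)

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def make_profile_bank(
    kind: str,
    n_items: int = 36,
    separation: float = 1.0,
    seed: int = 0,
    sizes: Sequence[int] | None = None,
    chance_floor: float = 0.25,
    p_mastered: float = _P_MASTERED,
    p_unmastered: float = _P_UNMASTERED,
) -> CohortSpec:
    """Build a default profile bank: ``asc_like`` (5 profiles) or ``td_like`` (4).

    Each profile masters a fraction of the items (success ``p_mastered``,
    the rest at ``p_unmastered``); mastery sets are nested along a common
    shuffled difficulty order with a couple of idiosyncratic swaps per
    subgroup so subgroups differ in patterning, not only in level.
    ``separation`` scales the spread of the mastery fractions around the
    bank mean; 1.0 is the stated default structure. Expected totals are
    strictly increasing by construction and, for the default ``asc_like``
    bank, run from the chance-level total to near ceiling.
    """
    if n_items < 4:
        raise ValueError("n_items must be >= 4")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if kind == "asc_like":
        base = np.array(_ASC_MASTERY)
    elif kind == "td_like":
        base = np.array(_TD_MASTERY)
    else:
        raise ValueError(f"unknown bank kind {kind!r}")
    k = len(base)
    fracs = np.clip(base.mean() + separation * (base - base.mean()), 0.0, 1.0)
    counts = np.round(fracs * n_items).astype(int)
    if not np.all(np.diff(counts) > 0):
        raise ValueError("separation too small: mastery counts not distinct")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)  # common difficulty order
    profiles = np.full((k, n_items), float(p_unmastered))
    for g in range(k):
        mastered = list(order[: counts[g]])
        unmastered = list(order[counts[g]:])
        for _ in range(min(_N_SWAPS, len(mastered), len(unmastered))):
            i = mastered.pop(int(rng.integers(len(mastered))))
            j = unmastered.pop(int(rng.integers(len(unmastered))))
            unmastered.append(i)
            mastered.append(j)
        profiles[g, mastered] = p_mastered
    totals = profiles.sum(axis=1)
    if not np.all(np.diff(totals) > 0):
        raise ValueError("bank construction failed to order expected totals")
    if sizes is None:
        sizes = (_DEFAULT_SUBGROUP_SIZE,) * k
    return CohortSpec(
        profiles=profiles,
        sizes=tuple(int(s) for s in sizes),
        chance_floor=chance_floor,
        seed=seed,
    )


def simulate_cohort(
    spec: CohortSpec, group_tag: str = "ASC", cohort_tag: str = "discovery"
) -> tuple[RawResponseTable, np.ndarray]:
    """Draw one cohort from a spec; returns the table and the planted labels.

    Subjects are independent Bernoulli draws from their subgroup's profile
    (optionally with per-subject logit-scale ability jitter); timeout codes
    replace the drawn code independently at ``timeout_rate``. Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    planted = []
    for g, size in enumerate(spec.sizes):
        p = spec.profiles[g]
        for _ in range(size):
            if spec.ability_jitter > 0:
                shift = rng.normal(0.0, spec.ability_jitter)
                logit = np.log(p / (1 - p)) + shift
                pj = 1.0 / (1.0 + np.exp(-logit))
            else:
                pj = p
            correct = rng.random(spec.n_items) < pj
            codes = np.where(correct, CORRECT, INCORRECT).astype(object)
            if spec.timeout_rate > 0:
                t_mask = rng.random(spec.n_items) < spec.timeout_rate
                codes[t_mask] = TIMEOUT
            rows.append(codes)
            planted.append(g + 1)
    responses = np.array(rows, dtype=object)
    n = len(rows)
    item_ids = tuple(f"item{j + 1:02d}" for j in range(spec.n_items))
    subject_ids = tuple(f"{cohort_tag}_{group_tag}_{i + 1:04d}" for i in range(n))
    table = RawResponseTable(
        subject_ids=subject_ids,
        group=(group_tag,) * n,
        cohort=(cohort_tag,) * n,
        item_ids=item_ids,
        responses=responses,
    )
    return table, np.array(planted)


def simulate_cohort_pair(
    bank: CohortSpec,
    n_discovery: int,
    n_replication: int,
    seeds: tuple[int, int] = (1, 2),
    group_tag: str = "ASC",
) -> tuple[RawResponseTable, np.ndarray, RawResponseTable, np.ndarray]:
    """Two independent cohorts from one profile bank.

    The two cohorts share the planted profiles but are drawn with independent
    seeds and independently jittered subgroup mixing proportions, emulating a
    discovery / replication design.
    """
    if n_discovery <= 0 or n_replication <= 0:
        raise ValueError("cohort sizes must be positive")
    out = []
    base_props = np.array(bank.sizes, dtype=float) / bank.n_subjects
    for n, seed, tag in (
        (n_discovery, seeds[0], "discovery"),
        (n_replication, seeds[1], "replication"),
    ):
        rng = np.random.default_rng(seed)
        props = rng.dirichlet(base_props * 100.0)
        sizes = np.maximum(1, np.round(props * n).astype(int))
        # adjust largest subgroup so sizes sum to n exactly
        sizes[int(np.argmax(sizes))] += n - sizes.sum()
        if sizes.min() < 1:
            raise ValueError("requested cohort too small for the bank")
        spec = replace(bank, sizes=tuple(int(s) for s in sizes), seed=seed)
        table, planted = simulate_cohort(spec, group_tag=group_tag, cohort_tag=tag)
        out.extend([table, planted])
    return tuple(out)  # type: ignore[return-value]
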