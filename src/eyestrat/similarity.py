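"""Subject (or item) similarity networks from binary response matrices.

Pairwise Hamming distance — the fraction of items on which two subjects
disagree — is converted to an adjacency ``a = 1 - d`` and then to the
unsigned topological overlap (TOM) similarity used in weighted-network
analysis. TOM augments the direct adjacency between two nodes with the
agreement of their shared neighbourhood, which makes the downstream
clustering less sensitive to item-level noise than raw Hamming similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_model import ItemResponseMatrix, ValidationError


@dataclass(frozen=True)
class SubjectDistanceMatrix:
    """Square symmetric distance matrix with axis IDs; entries in [0, 1]."""

    values: np.ndarray
    ids: tuple[str, ...]
    axis: str  # "subjects" or "items"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValidationError("axis IDs do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TopologicalOverlapMatrix:
    """TOM similarity plus the adjacency and connectivities it came from."""

    values: np.ndarray
    ids: tuple[str, ...]
    axis: str
    adjacency: np.ndarray  # a_ij = 1 - d_ij, zero diagonal
    connectivity: np.ndarray  # k_i = sum_{u != i} a_iu

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("TOM must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValidationError("TOM must have unit diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValidationError("TOM entries must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def hamming_distance_matrix(
    m: ItemResponseMatrix,
    axis: str = "subjects",
    item_subset: Sequence[str] | None = None,
) -> SubjectDistanceMatrix:
    """Pairwise Hamming distances between subjects (rows) or items (columns).

    ``item_subset`` restricts subject-wise distances to the named items.
    """
    if axis not in ("subjects", "items"):
        raise ValueError(f"axis must be 'subjects' or 'items', got {axis!r}")
    mat = m.matrix.astype(float)
    if item_subset is not None:
        if len(item_subset) == 0:
            raise ValueError("item_subset must be nonempty")
        missing = set(item_subset) - set(m.item_ids)
        if missing:
            raise ValueError(f"unknown item IDs in subset: {sorted(missing)}")
        idx = [m.item_ids.index(i) for i in item_subset]
        mat = mat[:, idx]
    if axis == "items":
        mat = mat.T
        ids = m.item_ids
    else:
        ids = m.subject_ids
    d = squareform(pdist(mat, metric="hamming"))
    return SubjectDistanceMatrix(values=d, ids=tuple(ids), axis=axis)


def topological_overlap_from_distance(
    d: SubjectDistanceMatrix,
) -> TopologicalOverlapMatrix:
    """Unsigned topological overlap of the adjacency ``a = 1 - d``.

    With zero-diagonal adjacency ``a``, connectivity ``k_i = sum_u a_iu`` and
    shared-neighbour sum ``l_ij = sum_{u != i,j} a_iu a_uj``::

        TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)   (i != j)
        TOM_ii = 1

    The diagonal is excluded from both sums.
    """
    a = 1.0 - d.values
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # full product includes u = i and u = j terms; subtract them off.
    prod = a @ a
    l = prod - a * np.diag(a)[None, :] - np.diag(a)[:, None] * a
    # diag(a) is zero so l here equals sum over u != i, j already; kept
    # explicit for clarity when adjacency conventions change.
    numer = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TopologicalOverlapMatrix(
        values=tom,
        ids=d.ids,
        axis=d.axis,
        adjacency=a,
        connectivity=k,
    )


def tom_dissimilarity(t: TopologicalOverlapMatrix) -> SubjectDistanceMatrix:
    """Complement ``1 - TOM``; the standard TOM-based dissimilarity."""
    v = 1.0 - t.values
    np.fill_diagonal(v, 0.0)
    return SubjectDistanceMatrix(values=v, ids=t.ids, axis=t.axis)


def rescale_distance(d: SubjectDistanceMatrix) -> SubjectDistanceMatrix:
    """Rescale distances by their maximum so the least similar pair is at 1.

    Applied before adjacency conversion in the stratification pipeline:
    binary Hamming distances rarely exceed ~0.7 even for maximally dissimilar
    subjects, which leaves every adjacency ``1 - d`` above ~0.3 and lets
    globally central subjects dominate the shared-neighbour sums of the
    topological overlap. Stretching to full range restores the contrast the
    overlap computation needs. Degenerate all-zero matrices pass unchanged.
    """
    mx = d.values.max()
    if mx <= 0:
        return d
    return SubjectDistanceMatrix(values=d.values / mx, ids=d.ids, axis=d.axis)


def tom_profile_distance(t: TopologicalOverlapMatrix) -> SubjectDistanceMatrix:
    """Euclidean distances between rows of the TOM, rescaled to [0, 1].

    Two nodes are close when their overlap similarities *to every other
    node* agree — the clustering view obtained by handing the square TOM
    matrix itself to a linkage routine that treats rows as observations.
    This profile view is insensitive to overall-connectivity gradients that
    distort the direct complement ``1 - TOM``.
    """
    v = squareform(pdist(t.values, metric="euclidean"))
    mx = v.max()
    if mx > 0:
        v = v / mx
    return SubjectDistanceMatrix(values=v, ids=t.ids, axis=t.axis)
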