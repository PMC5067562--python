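"""Domain types and I/O for item-level binary task data.

The entry point of the pipeline is a wide-format response table: one row per
subject, one column per item, cells coded ``1`` (correct), ``0`` (incorrect)
or ``T`` (timeout, i.e. no response within the task's time limit). Subjects
carry a diagnostic group tag (e.g. ASC / TD) and a cohort tag (e.g. discovery
/ replication). Timeouts are scored as incorrect, but subjects who time out
on too many items are excluded outright before any analysis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CORRECT = "CORRECT"
INCORRECT = "INCORRECT"
TIMEOUT = "TIMEOUT"

VALID_CODES = (CORRECT, INCORRECT, TIMEOUT)

# wide-format cell codes <-> response codes
_CELL_TO_CODE = {"1": CORRECT, "0": INCORRECT, "T": TIMEOUT}
_CODE_TO_CELL = {v: k for k, v in _CELL_TO_CODE.items()}

_META_COLUMNS = ("subject_id", "group", "cohort")


class FormatError(ValueError):
    """A file does not have the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """Data content violates a table invariant."""


@dataclass(frozen=True)
class RawResponseTable:
    """Per-subject trichotomous item responses plus subject metadata.

    ``responses`` is a (n_subjects, n_items) array of code strings drawn from
    ``{CORRECT, INCORRECT, TIMEOUT}``; every subject has a code for every
    item, item order is shared, subject IDs are unique.
    """

    subject_ids: tuple[str, ...]
    group: tuple[str, ...]
    cohort: tuple[str, ...]
    item_ids: tuple[str, ...]
    responses: np.ndarray

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses, dtype=object)
        object.__setattr__(self, "responses", resp)
        n, m = len(self.subject_ids), len(self.item_ids)
        if resp.shape != (n, m):
            raise ValidationError(
                f"responses shape {resp.shape} does not match "
                f"{n} subjects x {m} items"
            )
        if len(self.group) != n or len(self.cohort) != n:
            raise ValidationError("group/cohort length does not match subjects")
        if len(set(self.subject_ids)) != n:
            dupes = sorted(
                s for s in set(self.subject_ids)
                if list(self.subject_ids).count(s) > 1
            )
            raise ValidationError(f"duplicate subject_id(s): {dupes}")
        for i in range(n):
            for j in range(m):
                if resp[i, j] not in VALID_CODES:
                    raise ValidationError(
                        f"unknown response code {resp[i, j]!r} at subject "
                        f"{self.subject_ids[i]!r}, item {self.item_ids[j]!r}"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def timeout_counts(self) -> np.ndarray:
        """Per-subject number of TIMEOUT codes."""
        return (self.responses == TIMEOUT).sum(axis=1)


@dataclass(frozen=True)
class ItemResponseMatrix:
    """Filtered binary subjects x items matrix; 1 = correct, 0 = incorrect."""

    subject_ids: tuple[str, ...]
    group: tuple[str, ...]
    cohort: tuple[str, ...]
    item_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.int8)
        if not np.isin(mat, (0, 1)).all():
            raise ValidationError("matrix entries must be exactly 0 or 1")
        if mat.shape != (len(self.subject_ids), len(self.item_ids)):
            raise ValidationError("matrix shape does not match axis IDs")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject IDs")
        object.__setattr__(self, "matrix", mat)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def subset_items(self, item_ids: Sequence[str]) -> "ItemResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ItemResponseMatrix(
            subject_ids=self.subject_ids,
            group=self.group,
            cohort=self.cohort,
            item_ids=tuple(item_ids),
            matrix=self.matrix[:, idx],
        )


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-subject phenotype measures; missing values stay missing (NaN)."""

    frame: pd.DataFrame  # indexed by subject_id

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate subject IDs in phenotype table")

    def aligned_to(self, subject_ids: Sequence[str]) -> pd.DataFrame:
        missing = set(subject_ids) - set(self.frame.index)
        if missing:
            raise ValidationError(
                f"phenotype table lacks subjects: {sorted(missing)[:5]}"
            )
        return self.frame.loc[list(subject_ids)]


def load_response_table(path: str | Path, delimiter: str = ",") -> RawResponseTable:
    """Read a wide-format response CSV/TSV into a validated table.

    Header: ``subject_id,group,cohort,<item>,<item>,...``; cells ``1``/``0``/``T``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    item_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not item_cols:
        raise FormatError(f"no item columns found in {path}")
    cells = df[item_cols].to_numpy(dtype=str)
    responses = np.empty(cells.shape, dtype=object)
    for i in range(cells.shape[0]):
        for j in range(cells.shape[1]):
            code = _CELL_TO_CODE.get(cells[i, j].strip())
            if code is None:
                raise ValidationError(
                    f"unknown response code {cells[i, j]!r} at row "
                    f"{df['subject_id'].iloc[i]!r}, column {item_cols[j]!r}"
                )
            responses[i, j] = code
    return RawResponseTable(
        subject_ids=tuple(df["subject_id"]),
        group=tuple(df["group"]),
        cohort=tuple(df["cohort"]),
        item_ids=tuple(item_cols),
        responses=responses,
    )


def write_response_table(
    table: RawResponseTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write a table in the wide format ``load_response_table`` reads."""
    cells = np.vectorize(_CODE_TO_CELL.get)(table.responses)
    df = pd.DataFrame(cells, columns=list(table.item_ids))
    df.insert(0, "cohort", table.cohort)
    df.insert(0, "group", table.group)
    df.insert(0, "subject_id", table.subject_ids)
    df.to_csv(path, sep=delimiter, index=False)


def load_phenotype_table(path: str | Path, delimiter: str = ",") -> PhenotypeTable:
    df = pd.read_csv(path, sep=delimiter)
    if "subject_id" not in df.columns:
        raise FormatError(f"missing required column 'subject_id' in {path}")
    return PhenotypeTable(frame=df.set_index("subject_id"))


def apply_timeout_filter(
    raw: RawResponseTable, max_timeouts_exclusive: int = 9
) -> tuple[RawResponseTable, list[str]]:
    """Drop subjects who timed out on ``max_timeouts_exclusive`` or more items.

    The default of 9 on a 36-item task excludes anyone with timeouts on a
    quarter of the items or more. Returns the filtered table and the excluded
    subject IDs, in original row order.
    """
    if max_timeouts_exclusive < 1:
        raise ValueError("timeout threshold must be >= 1")
    counts = raw.timeout_counts()
    keep = counts < max_timeouts_exclusive
    excluded = [s for s, k in zip(raw.subject_ids, keep) if not k]
    filtered = RawResponseTable(
        subject_ids=tuple(s for s, k in zip(raw.subject_ids, keep) if k),
        group=tuple(g for g, k in zip(raw.group, keep) if k),
        cohort=tuple(c for c, k in zip(raw.cohort, keep) if k),
        item_ids=raw.item_ids,
        responses=raw.responses[keep],
    )
    return filtered, excluded


def binarize(raw: RawResponseTable) -> ItemResponseMatrix:
    """Score responses: CORRECT -> 1; INCORRECT and TIMEOUT -> 0."""
    return ItemResponseMatrix(
        subject_ids=raw.subject_ids,
        group=raw.group,
        cohort=raw.cohort,
        item_ids=raw.item_ids,
        matrix=(raw.responses == CORRECT).astype(np.int8),
    )


def total_scores(m: ItemResponseMatrix) -> np.ndarray:
    """Per-subject total score: the row sum of the binary matrix."""
    return m.matrix.sum(axis=1).astype(int)


@dataclass
class RunLog:
    """Plain-text run log capturing seeds, parameters and input digests."""

    lines: list[str] = field(default_factory=list)

    def record(self, key: str, value) -> None:
        self.lines.append(f"{key} = {value!r}")

    def record_file(self, label: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.lines.append(f"{label} = {Path(path).name} sha256:{digest}")

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.lines) + "\n")
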