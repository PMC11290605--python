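"""Domain types and I/O for the source-monitoring task.

The behavioural unit of analysis is one test-phase trial: an object that was
previously shown in the upper or lower half of the screen (or is new) receives
an old/new judgment, and — only if judged old — an up/down source judgment.
Trials are tabulated into a 3x3 frequency table (trial type x response
category) that all downstream multinomial-processing-tree (MPT) machinery
consumes.

Trial CSV dialect (UTF-8, comma-separated, header required), columns in order:
``participant_id, group, block, item_id, true_position, item_response,
source_response, rt_item, rt_source``.  Absent reaction times and
``source_response=none`` are written as the empty string.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Group",
    "Position",
    "ItemResponse",
    "SourceResponse",
    "TrialRecord",
    "FrequencyTable",
    "CohortTable",
    "TrialValidationError",
    "TrialParseError",
    "TREES",
    "CATEGORIES",
    "read_trials",
    "write_trials",
    "tabulate",
]


class Group(str, Enum):
    YOUNG = "young"
    OLDER = "older"


class Position(str, Enum):
    """True item position: shown up, shown down, or a new distractor."""

    UP = "up"
    DOWN = "down"
    NEW = "new"


class ItemResponse(str, Enum):
    OLD = "old"
    NEW = "new"
    MISS = "miss"


class SourceResponse(str, Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


#: Row order of every 3x3 table: trial type (the MPT "tree").
TREES = (Position.UP, Position.DOWN, Position.NEW)
#: Column order: the three possible answers.
CATEGORIES = ("old_up", "old_down", "new")

TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "block",
    "item_id",
    "true_position",
    "item_response",
    "source_response",
    "rt_item",
    "rt_source",
)


class TrialValidationError(ValueError):
    """A trial violates the task's response contingency invariants."""


class TrialParseError(ValueError):
    """A CSV row could not be parsed; carries row and column context."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column '{column}': {message}")


@dataclass(frozen=True)
class TrialRecord:
    """One test-phase trial.

    The source prompt only ever follows an "old" answer, so
    ``source_response`` is ``NONE`` exactly when ``item_response`` is not
    ``OLD``; a missed trial carries no reaction times.
    """

    participant_id: str
    group: Group
    block: int
    item_id: str
    true_position: Position
    item_response: ItemResponse
    source_response: SourceResponse
    rt_item: float | None = None
    rt_source: float | None = None

    def __post_init__(self):
        if not 1 <= self.block <= 8:
            raise TrialValidationError(f"block must be in 1..8, got {self.block}")
        has_source = self.source_response != SourceResponse.NONE
        if has_source != (self.item_response == ItemResponse.OLD):
            raise TrialValidationError(
                "source_response must be given iff item_response is 'old' "
                f"(got item_response={self.item_response.value}, "
                f"source_response={self.source_response.value})"
            )
        if self.item_response == ItemResponse.MISS and self.rt_item is not None:
            raise TrialValidationError("missed trials cannot carry rt_item")
        for name, rt in (("rt_item", self.rt_item), ("rt_source", self.rt_source)):
            if rt is not None and rt < 0:
                raise TrialValidationError(f"{name} must be >= 0, got {rt}")

    @property
    def category(self) -> str | None:
        """Response category, or None for a missed trial."""
        if self.item_response == ItemResponse.MISS:
            return None
        if self.item_response == ItemResponse.NEW:
            return "new"
        return "old_up" if self.source_response == SourceResponse.UP else "old_down"


@dataclass
class FrequencyTable:
    """3x3 response counts (tree x category) plus per-tree missed trials.

    ``counts[i, j]`` is the number of answered trials of type ``TREES[i]``
    that received answer ``CATEGORIES[j]``.  Missed trials are excluded from
    ``counts`` and tallied per tree in ``miss_counts`` (the model has no
    no-response branch; misses are analysed separately).
    """

    counts: np.ndarray
    miss_counts: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.miss_counts = np.asarray(self.miss_counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {self.counts.shape}")
        if self.miss_counts.shape != (3,):
            raise ValueError("miss_counts must have length 3")
        if (self.counts < 0).any() or (self.miss_counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_miss(self) -> int:
        """Total number of missed (unanswered) trials."""
        return int(self.miss_counts.sum())

    @property
    def tree_totals(self) -> np.ndarray:
        """Answered trials per tree (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def presented_totals(self) -> np.ndarray:
        """Presented trials per tree, misses included."""
        return self.tree_totals + self.miss_counts

    def __add__(self, other: "FrequencyTable") -> "FrequencyTable":
        return FrequencyTable(self.counts + other.counts,
                              self.miss_counts + other.miss_counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return (np.array_equal(self.counts, other.counts)
                and np.array_equal(self.miss_counts, other.miss_counts))


@dataclass
class CohortTable:
    """Per-participant frequency tables with group labels and covariates."""

    participant_ids: list[str]
    groups: list[Group]
    tables: list[FrequencyTable]
    covariates: np.ndarray | None = None  # per participant, e.g. sex in {0, 1}

    def __post_init__(self):
        n = len(self.participant_ids)
        if not (len(self.groups) == len(self.tables) == n):
            raise ValueError("participant_ids, groups and tables must align")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape != (n,):
                raise ValueError("covariates must have one value per participant")

    def __len__(self) -> int:
        return len(self.participant_ids)

    def subset(self, group: Group) -> "CohortTable":
        idx = [i for i, g in enumerate(self.groups) if g == group]
        return CohortTable(
            [self.participant_ids[i] for i in idx],
            [self.groups[i] for i in idx],
            [self.tables[i] for i in idx],
            None if self.covariates is None else self.covariates[idx],
        )

    @classmethod
    def from_trials(cls, trials: Sequence[TrialRecord],
                    covariates: dict[str, float] | None = None) -> "CohortTable":
        """Group trials by participant (first-appearance order) and tabulate."""
        by_pid: dict[str, list[TrialRecord]] = {}
        for t in trials:
            by_pid.setdefault(t.participant_id, []).append(t)
        pids = list(by_pid)
        groups = [by_pid[p][0].group for p in pids]
        tables = [tabulate(by_pid[p]) for p in pids]
        cov = None
        if covariates is not None:
            cov = np.array([covariates[p] for p in pids], dtype=float)
        return cls(pids, groups, tables, cov)


def _parse_field(raw: str, row: int, column: str, enum_cls):
    try:
        return enum_cls(raw)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise TrialParseError(row, column, f"unknown value {raw!r} (expected one of: {valid})")


def _parse_rt(raw: str, row: int, column: str) -> float | None:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise TrialParseError(row, column, f"not a number: {raw!r}")


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trial CSV; every row is parsed or rejected with its row number."""
    path = Path(path)
    records: list[TrialRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != TRIAL_COLUMNS:
            raise TrialParseError(1, "header",
                                  f"expected columns {', '.join(TRIAL_COLUMNS)}")
        for i, row in enumerate(reader, start=2):
            if len(row) != len(TRIAL_COLUMNS):
                raise TrialParseError(i, "row", f"expected {len(TRIAL_COLUMNS)} fields, got {len(row)}")
            (pid, group, block, item, pos, item_resp, src_resp, rt_i, rt_s) = row
            try:
                block_no = int(block)
            except ValueError:
                raise TrialParseError(i, "block", f"not an integer: {block!r}")
            try:
                rec = TrialRecord(
                    participant_id=pid,
                    group=_parse_field(group, i, "group", Group),
                    block=block_no,
                    item_id=item,
                    true_position=_parse_field(pos, i, "true_position", Position),
                    item_response=_parse_field(item_resp, i, "item_response", ItemResponse),
                    source_response=(SourceResponse.NONE if src_resp == "" else
                                     _parse_field(src_resp, i, "source_response", SourceResponse)),
                    rt_item=_parse_rt(rt_i, i, "rt_item"),
                    rt_source=_parse_rt(rt_s, i, "rt_source"),
                )
            except TrialValidationError as exc:
                raise TrialValidationError(f"row {i}: {exc}") from exc
            records.append(rec)
    return records


def write_trials(trials: Iterable[TrialRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for t in trials:
            writer.writerow([
                t.participant_id,
                t.group.value,
                t.block,
                t.item_id,
                t.true_position.value,
                t.item_response.value,
                t.source_response.value if t.source_response != SourceResponse.NONE else "",
                "" if t.rt_item is None else repr(t.rt_item),
                "" if t.rt_source is None else repr(t.rt_source),
            ])


def tabulate(trials: Sequence[TrialRecord]) -> FrequencyTable:
    """Tabulate one participant's trials into a FrequencyTable.

    Each answered trial increments exactly one cell (row from the true
    position, column from the response); missed trials increment the per-tree
    miss counter only.
    """
    pids = {t.participant_id for t in trials}
    if len(pids) > 1:
        raise ValueError(f"trials from multiple participants: {sorted(pids)}")
    counts = np.zeros((3, 3), dtype=int)
    misses = np.zeros(3, dtype=int)
    tree_idx = {p: i for i, p in enumerate(TREES)}
    cat_idx = {c: j for j, c in enumerate(CATEGORIES)}
    for t in trials:
        i = tree_idx[t.true_position]
        cat = t.category
        if cat is None:
            misses[i] += 1
        else:
            counts[i, cat_idx[cat]] += 1
    return FrequencyTable(counts, misses)
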