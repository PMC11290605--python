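"""Discrimination statistics for item and spatial (source) memory.

Item memory is scored with the Snodgrass & Corwin discrimination index
Pr = hit rate - false-alarm rate.  Spatial memory uses a source Pr that
normalises by the number of source trials a perfect item-memory performer
would face (160 = 8 blocks x 20 re-presented objects), which removes the
dependence of the source-trial count on item-memory performance.

Rates are computed with *presented* trials in the denominator, so missed
trials lower the hit rate but never inflate it (hence FA + CR < 100% is
possible for a participant with misses on new items).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_data import CohortTable, FrequencyTable, Group

__all__ = [
    "N_BLOCKS",
    "OLD_ITEMS_PER_BLOCK",
    "SOURCE_TRIALS_TOTAL",
    "PrStats",
    "item_pr",
    "source_pr",
    "participant_stats",
    "group_summary",
    "false_alarm_vma",
]

#: Experimental design constants: blocks per session and re-presented (old)
#: objects per test phase.  Their product is the fixed source-Pr denominator.
N_BLOCKS = 8
OLD_ITEMS_PER_BLOCK = 20
SOURCE_TRIALS_TOTAL = N_BLOCKS * OLD_ITEMS_PER_BLOCK  # 160


@dataclass(frozen=True)
class PrStats:
    """Per-participant rates and discrimination indices."""

    hit_rate: float
    fa_rate: float
    cr_rate: float
    item_pr: float
    source_correct: int
    source_incorrect: int
    source_pr: float


def item_pr(hit_rate: float, fa_rate: float) -> float:
    """Item discrimination index: hits minus false alarms."""
    for name, v in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return hit_rate - fa_rate


def source_pr(correct: int, incorrect: int,
              denominator: int = SOURCE_TRIALS_TOTAL) -> float:
    """Source discrimination index: (correct - incorrect) / fixed denominator."""
    if correct < 0 or incorrect < 0:
        raise ValueError("counts must be non-negative")
    if correct + incorrect > denominator:
        raise ValueError(
            f"correct + incorrect = {correct + incorrect} exceeds denominator {denominator}")
    return (correct - incorrect) / denominator


def participant_stats(table: FrequencyTable,
                      source_denominator: int = SOURCE_TRIALS_TOTAL) -> PrStats:
    """Rates and Pr indices for one participant's frequency table.

    Denominators are presented trials (answered + missed) of the relevant
    type; source correct/incorrect counts come only from true-old trials
    answered "old" with a source judgment.
    """
    c = table.counts
    presented = table.presented_totals  # per tree, misses included
    n_old = presented[0] + presented[1]
    n_new = presented[2]
    if n_old == 0 or n_new == 0:
        raise ValueError("participant has no old or no new trials")
    hits = c[0, 0] + c[0, 1] + c[1, 0] + c[1, 1]
    fas = c[2, 0] + c[2, 1]
    crs = c[2, 2]
    correct = int(c[0, 0] + c[1, 1])    # up answered up, down answered down
    incorrect = int(c[0, 1] + c[1, 0])
    hit_rate = hits / n_old
    fa_rate = fas / n_new
    return PrStats(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        cr_rate=crs / n_new,
        item_pr=item_pr(hit_rate, fa_rate),
        source_correct=correct,
        source_incorrect=incorrect,
        source_pr=source_pr(correct, incorrect, source_denominator),
    )


def group_summary(cohort: CohortTable,
                  source_denominator: int = SOURCE_TRIALS_TOTAL) -> pd.DataFrame:
    """Group mean +/- SD of hit/FA/CR rates and Pr indices (Table-1 style).

    Returns one row per group with columns ``group, n, <stat>_mean, <stat>_sd``
    for hit, fa, cr, item_pr, source_pr.  SDs use the n-1 (sample) convention.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for group in (Group.YOUNG, Group.OLDER):
        sub = cohort.subset(group)
        if len(sub) == 0:
            continue
        stats = [participant_stats(t, source_denominator) for t in sub.tables]
        row: dict[str, object] = {"group": group.value, "n": len(sub)}
        for stat in ("hit_rate", "fa_rate", "cr_rate", "item_pr", "source_pr"):
            vals = np.array([getattr(s, stat) for s in stats])
            key = stat.removesuffix("_rate")
            row[f"{key}_mean"] = vals.mean()
            row[f"{key}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    if not rows:
        raise ValueError("no non-empty groups in cohort")
    return pd.DataFrame(rows)


def false_alarm_vma(fa_up: int, fa_down: int) -> float | None:
    """Vertical-meridian-asymmetry index applied to false-alarm source choices.

    ``(fa_down - fa_up) / mean(fa_down, fa_up) * 100``; positive means a bias
    toward attributing never-seen items to the lower field.  Returns None
    (undefined) when both counts are zero.
    """
    if fa_up < 0 or fa_down < 0:
        raise ValueError("counts must be non-negative")
    if fa_up == 0 and fa_down == 0:
        return None
    return (fa_down - fa_up) / ((fa_down + fa_up) / 2) * 100
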