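"""Fixation detection and Fujii 2/4 fixation-stability classification.

Gaze streams (nominally 1000 Hz, positions in degrees of visual angle) are
segmented into fixations with a velocity-threshold algorithm: sample
velocities from symmetric differences, a robust median-based dispersion
estimate per axis, and an elliptic threshold at ``lambda`` dispersions.
Maximal runs of sub-threshold samples become fixations; fixations shorter
than 100 ms are discarded.

Stability is then graded with the 2/4 method: the percentages of fixation
centroids within 2 degrees and 4 degrees of the fixation target give the
Fujii categories stable / relatively unstable / unstable, and a participant
is excluded when fewer than 75% of fixation points fall inside the 4-degree
circle.  Distances exactly on a circle count as inside, and exactly 75%
meets the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fixation",
    "StabilityCategory",
    "StabilityReport",
    "detect_fixations",
    "fujii_classify",
    "read_gaze",
    "qc_report",
]


@dataclass(frozen=True)
class Fixation:
    onset: float    # ms
    offset: float   # ms
    cx: float       # centroid, degrees
    cy: float

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("fixation duration must be positive")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


class StabilityCategory(str, Enum):
    STABLE = "stable"
    RELATIVELY_UNSTABLE = "relatively_unstable"
    UNSTABLE = "unstable"


@dataclass(frozen=True)
class StabilityReport:
    pct_within_2deg: float
    pct_within_4deg: float
    category: StabilityCategory
    excluded: bool


def _robust_sd(v: np.ndarray) -> float:
    """Median-based velocity dispersion (median of squares minus squared median)."""
    sd2 = np.median(v**2) - np.median(v) ** 2
    return float(np.sqrt(max(sd2, 1e-12)))


def detect_fixations(t: Sequence[float], x: Sequence[float], y: Sequence[float],
                     lam: float = 6.0, min_dur: float = 100.0) -> list[Fixation]:
    """Segment a gaze stream into fixations.

    Parameters
    ----------
    t, x, y : time in ms (strictly increasing) and gaze position in degrees.
    lam : velocity-threshold multiplier on the robust dispersion estimate.
    min_dur : minimum fixation duration in ms; shorter fixations are dropped.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    # symmetric-difference velocities (one-sided at the ends), deg/ms
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    sx = _robust_sd(vx)
    sy = _robust_sd(vy)
    # elliptic combination of the per-axis thresholds
    saccade = (vx / (lam * sx)) ** 2 + (vy / (lam * sy)) ** 2 > 1.0

    fixations: list[Fixation] = []
    n = t.size
    i = 0
    while i < n:
        if saccade[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not saccade[j + 1]:
            j += 1
        if t[j] > t[i]:
            fix = Fixation(onset=float(t[i]), offset=float(t[j]),
                           cx=float(x[i:j + 1].mean()), cy=float(y[i:j + 1].mean()))
            if fix.duration >= min_dur:
                fixations.append(fix)
        i = j + 1
    return fixations


def fujii_classify(fixations: Sequence[Fixation],
                   center: tuple[float, float] = (0.0, 0.0)) -> StabilityReport:
    """Grade fixation stability from fixation centroids by the 2/4 method."""
    if len(fixations) == 0:
        raise ValueError("cannot assess stability without fixations")
    cx = np.array([f.cx for f in fixations])
    cy = np.array([f.cy for f in fixations])
    d = np.hypot(cx - center[0], cy - center[1])
    pct2 = float((d <= 2.0).mean() * 100)
    pct4 = float((d <= 4.0).mean() * 100)
    if pct4 < 75.0:
        category = StabilityCategory.UNSTABLE
    elif pct2 >= 75.0:
        category = StabilityCategory.STABLE
    else:
        category = StabilityCategory.RELATIVELY_UNSTABLE
    return StabilityReport(
        pct_within_2deg=pct2,
        pct_within_4deg=pct4,
        category=category,
        excluded=category == StabilityCategory.UNSTABLE,
    )


GAZE_COLUMNS = ("participant_id", "block", "t_ms", "x_deg", "y_deg")


def read_gaze(path: str | Path) -> pd.DataFrame:
    """Read a gaze CSV (participant_id, block, t_ms, x_deg, y_deg)."""
    df = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    return df


def qc_report(gaze: pd.DataFrame, lam: float = 6.0, min_dur: float = 100.0,
              center: tuple[float, float] = (0.0, 0.0)) -> pd.DataFrame:
    """Per-participant stability report from a multi-block gaze table.

    Fixations are detected per block (streams are only continuous within a
    block) and centroids pooled across blocks per participant before
    classification.
    """
    rows = []
    for pid, part in gaze.groupby("participant_id", sort=False):
        fixations: list[Fixation] = []
        for _, blk in part.groupby("block", sort=True):
            fixations.extend(detect_fixations(
                blk["t_ms"].to_numpy(), blk["x_deg"].to_numpy(),
                blk["y_deg"].to_numpy(), lam=lam, min_dur=min_dur))
        report = fujii_classify(fixations, center)
        rows.append({
            "participant_id": pid,
            "n_fixations": len(fixations),
            "pct_2deg": report.pct_within_2deg,
            "pct_4deg": report.pct_within_4deg,
            "category": report.category.value,
            "excluded": report.excluded,
        })
    return pd.DataFrame(rows)
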