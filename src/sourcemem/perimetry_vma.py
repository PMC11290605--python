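"""Kinetic-perimetry isopter geometry and the vertical meridian asymmetry.

An isopter is a closed contour of equal sensitivity charted in polar
coordinates (meridian angle, eccentricity in degrees).  The contour is
closed into a polygon by linear interpolation between sampled meridians,
split along the horizontal meridian (y = 0), and the upper/lower hemifield
areas are measured in squared degrees.  The vertical meridian asymmetry
index is

    VMA = (lower_area - upper_area) / mean(lower_area, upper_area) * 100

so positive values indicate a larger lower visual field.  VMA is bounded in
[-200, 200] and invariant to uniform scaling of the chart.

Angles follow the perimetric convention: 0 degrees is the right horizontal
meridian, angles increase counter-clockwise, so the upper visual field spans
(0, 180) and the lower field (180, 360).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.validation import explain_validity

__all__ = [
    "Eye",
    "IsopterLabel",
    "IsopterChart",
    "VmaResult",
    "hemifield_areas",
    "vma_index",
    "chart_vma",
    "read_isopters",
    "vma_table",
    "VMA_ISOPTERS",
]


class Eye(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class IsopterLabel(str, Enum):
    V1E = "V1e"
    III1E = "III1e"
    II1E = "II1e"
    I1E = "I1e"


#: Isopters entering the VMA analysis (the smallest, I1e, is charted but
#: excluded by default).
VMA_ISOPTERS = (IsopterLabel.V1E, IsopterLabel.III1E, IsopterLabel.II1E)


@dataclass
class IsopterChart:
    """One isopter for one eye: polar points (angle deg in [0, 360), radius deg)."""

    eye: Eye
    isopter: IsopterLabel
    points: np.ndarray  # (n, 2): angle, radius

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (angle, radius)")
        if self.points.shape[0] < 3:
            raise ValueError("an isopter needs at least 3 points")
        ang = np.mod(self.points[:, 0], 360.0)
        if len(np.unique(ang)) != len(ang):
            raise ValueError("duplicate meridian angles in isopter")
        if (self.points[:, 1] < 0).any():
            raise ValueError("radii must be non-negative")

    def polygon(self) -> Polygon:
        """Close the contour into a polygon, vertices sorted by angle."""
        ang = np.mod(self.points[:, 0], 360.0)
        order = np.argsort(ang)
        theta = np.deg2rad(ang[order])
        r = self.points[order, 1]
        poly = Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        if not poly.is_valid:
            raise ValueError(f"self-intersecting isopter contour: {explain_validity(poly)}")
        return poly


@dataclass(frozen=True)
class VmaResult:
    upper_area: float  # deg^2
    lower_area: float
    vma: float | None  # None when both areas are zero


def hemifield_areas(chart: IsopterChart) -> tuple[float, float]:
    """(upper, lower) hemifield areas in squared degrees.

    The isopter polygon is clipped against the half-planes above and below
    the horizontal meridian; intersection points on y = 0 are inserted by the
    clipping, and each part's area is the shoelace area of the resulting
    polygon.
    """
    poly = chart.polygon()
    r_max = float(chart.points[:, 1].max()) + 1.0
    upper = poly.intersection(box(-r_max, 0.0, r_max, r_max))
    lower = poly.intersection(box(-r_max, -r_max, r_max, 0.0))
    return float(upper.area), float(lower.area)


def vma_index(upper_area: float, lower_area: float) -> float | None:
    """Percent-scaled normalised lower-minus-upper asymmetry; None if both zero."""
    if upper_area < 0 or lower_area < 0:
        raise ValueError("areas must be non-negative")
    if upper_area == 0 and lower_area == 0:
        return None
    return (lower_area - upper_area) / ((lower_area + upper_area) / 2) * 100


def chart_vma(chart: IsopterChart) -> VmaResult:
    upper, lower = hemifield_areas(chart)
    return VmaResult(upper, lower, vma_index(upper, lower))


ISOPTER_COLUMNS = ("participant_id", "eye", "isopter", "angle_deg", "radius_deg")


def read_isopters(path: str | Path) -> dict[tuple[str, Eye, IsopterLabel], IsopterChart]:
    """Read an isopter CSV into charts keyed by (participant, eye, isopter)."""
    df = pd.read_csv(path)
    missing = set(ISOPTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"isopter CSV missing columns: {sorted(missing)}")
    charts = {}
    for (pid, eye, iso), grp in df.groupby(["participant_id", "eye", "isopter"], sort=False):
        chart = IsopterChart(Eye(eye), IsopterLabel(iso),
                             grp[["angle_deg", "radius_deg"]].to_numpy())
        charts[(pid, chart.eye, chart.isopter)] = chart
    return charts


def vma_table(charts: dict[tuple[str, Eye, IsopterLabel], IsopterChart],
              include_i1e: bool = False, average_eyes: bool = False) -> pd.DataFrame:
    """Per participant/eye/isopter VMA rows; I1e excluded unless requested.

    With ``average_eyes`` the two eyes' VMA values are averaged per
    participant and isopter.
    """
    rows = []
    for (pid, eye, iso), chart in charts.items():
        if iso == IsopterLabel.I1E and not include_i1e:
            continue
        res = chart_vma(chart)
        rows.append({
            "participant_id": pid, "eye": eye.value, "isopter": iso.value,
            "upper_area": res.upper_area, "lower_area": res.lower_area,
            "vma": res.vma,
        })
    df = pd.DataFrame(rows)
    if average_eyes and not df.empty:
        df = (df.groupby(["participant_id", "isopter"], as_index=False)
                .agg(upper_area=("upper_area", "mean"),
                     lower_area=("lower_area", "mean"),
                     vma=("vma", "mean")))
    return df
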