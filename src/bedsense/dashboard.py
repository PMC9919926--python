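"""The five-index wellbeing dashboard and its overall rating.

Per resident-day the dashboard grades five indices into levels 1 (best) to 4:

* **TB** — signed difference of total in-bed time vs the two-week norm (h):
  |d| <= 1 -> L1, (1, 2] -> L2, (2, 3] -> L3, > 3 -> L4.
* **CC** — Pearson correlation of the day's on/off-bed pattern with the norm:
  >= 0.7 -> L1, [0.5, 0.7) -> L2, [0.3, 0.5) -> L3, < 0.3 -> L4.
* **ST** — signed difference of total sleep time vs the norm (h): TB bands.
* **SE** — sleep efficiency (%), graded with the Pittsburgh Sleep Quality
  Index bands: >= 85 -> L1, [75, 85) -> L2, [65, 75) -> L3, < 65 -> L4.
* **PP** — maximum continuous pressure time over all areas (h):
  <= 1 -> L1, (1, 2] -> L2, (2, 4] -> L3, > 4 -> L4; graded only when total
  in-bed time exceeds 12 h.

The stated bands overlap at their edges; they are resolved here as the
half-open intervals above, the better level winning at a tie. The overall
rating takes the worst present level: all L1 -> Great (green), all within
L1-L2 -> Normal (blue), any L3 -> Attention (red), any L4 -> Abnormal
(purple); a day with no index values at all is Off-Bed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

INDEX_NAMES = ("TB", "CC", "ST", "SE", "PP")

#: Total in-bed time above which the PP index applies (ties -> not applicable).
PP_MIN_IN_BED_H = 12.0

#: Summary-table differences larger than this are flagged red.
SUMMARY_FLAG_H = 2.0

RATING_COLORS = {"Great": "green", "Normal": "blue", "Attention": "red",
                 "Abnormal": "purple", "Off-Bed": "none"}


def time_diff_level(diff_h: Optional[float]) -> Optional[int]:
    """TB/ST level from a signed difference in hours (None passes through)."""
    if diff_h is None:
        return None
    d = abs(diff_h)
    if d <= 1.0:
        return 1
    if d <= 2.0:
        return 2
    if d <= 3.0:
        return 3
    return 4


def correlation_level(cc: Optional[float]) -> Optional[int]:
    if cc is None:
        return None
    if cc >= 0.7:
        return 1
    if cc >= 0.5:
        return 2
    if cc >= 0.3:
        return 3
    return 4


def sleep_efficiency_level(se_pct: Optional[float]) -> Optional[int]:
    if se_pct is None:
        return None
    if se_pct >= 85.0:
        return 1
    if se_pct >= 75.0:
        return 2
    if se_pct >= 65.0:
        return 3
    return 4


def pressure_level(pp_h: Optional[float],
                   total_in_bed_h: Optional[float]) -> Optional[int]:
    """PP level; not applicable (None) unless total in-bed time exceeds 12 h."""
    if pp_h is None or total_in_bed_h is None or total_in_bed_h <= PP_MIN_IN_BED_H:
        return None
    if pp_h <= 1.0:
        return 1
    if pp_h <= 2.0:
        return 2
    if pp_h <= 4.0:
        return 3
    return 4


@dataclass
class WellbeingIndices:
    """Raw index values and their assigned levels for one resident-day."""

    tb_diff_h: Optional[float]
    cc: Optional[float]
    st_diff_h: Optional[float]
    se_pct: Optional[float]
    pp_h: Optional[float]
    total_in_bed_h: Optional[float]
    levels: dict

    @property
    def present_levels(self) -> list[int]:
        return [lv for lv in self.levels.values() if lv is not None]


def index_levels(tb_diff_h: Optional[float], cc: Optional[float],
                 st_diff_h: Optional[float], se_pct: Optional[float],
                 pp_h: Optional[float],
                 total_in_bed_h: Optional[float]) -> WellbeingIndices:
    """Grade the five dashboard indices; missing inputs yield missing levels."""
    levels = {
        "TB": time_diff_level(tb_diff_h),
        "CC": correlation_level(cc),
        "ST": time_diff_level(st_diff_h),
        "SE": sleep_efficiency_level(se_pct),
        "PP": pressure_level(pp_h, total_in_bed_h),
    }
    return WellbeingIndices(tb_diff_h=tb_diff_h, cc=cc, st_diff_h=st_diff_h,
                            se_pct=se_pct, pp_h=pp_h,
                            total_in_bed_h=total_in_bed_h, levels=levels)


@dataclass(frozen=True)
class OverallRating:
    rating: str
    color: str


def overall_rating(indices: WellbeingIndices) -> OverallRating:
    """Collapse the five levels to the color-coded overall rating.

    Precedence Abnormal > Attention > Normal > Great over the present levels;
    Off-Bed only when every index is missing.
    """
    present = indices.present_levels
    if not present:
        return OverallRating("Off-Bed", RATING_COLORS["Off-Bed"])
    worst = max(present)
    rating = {1: "Great", 2: "Normal", 3: "Attention", 4: "Abnormal"}[worst]
    return OverallRating(rating, RATING_COLORS[rating])


def summary_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Cohort summary for one day, one row per resident.

    Each input mapping supplies ``resident_id``, ``pattern`` (living-pattern
    name), ``total_in_bed_h``, ``total_sleep_h``, ``tb_diff_h``, ``st_diff_h``.
    Differences with magnitude above 2 h get a red flag column, mirroring the
    caregiver list view.
    """
    df = pd.DataFrame(list(rows))
    required = ["resident_id", "pattern", "total_in_bed_h", "total_sleep_h",
                "tb_diff_h", "st_diff_h"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"summary rows lack columns: {missing}")
    df = df[required].copy()
    for col, flag in (("tb_diff_h", "tb_flag_red"), ("st_diff_h", "st_flag_red")):
        vals = pd.to_numeric(df[col], errors="coerce")
        df[flag] = vals.abs().gt(SUMMARY_FLAG_H).fillna(False)
    return df


def weekly_view(daily_ratings: Iterable[OverallRating]) -> pd.DataFrame:
    """Seven (or fewer) daily ratings as a small table — a pure aggregation."""
    ratings = list(daily_ratings)
    return pd.DataFrame({
        "day": np.arange(1, len(ratings) + 1),
        "rating": [r.rating for r in ratings],
        "color": [r.color for r in ratings],
    })
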