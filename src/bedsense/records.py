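"""Daily in-bed/off-bed records, the two-week norm, and day-vs-norm comparison.

A care day runs 08:00 to 08:00 the next day so one overnight sleep stays on a
single chart. The day is summarised as 144 ten-minute slots, each in-bed or
off-bed; totals are kept at 1 s resolution. Fourteen daily records make a
norm: per-slot in-bed proportions, "regular" flags (in bed, or off bed, on at
least 10 of the 14 days), and the norm score — the percentage of the 144
slots that are regular either way. A single day is compared against the norm
via the Pearson correlation of its binary slot vector with the norm's
proportions, plus signed differences in total in-bed and total sleep time.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from typing import Optional, Sequence, Union

import numpy as np

from .frames import FrameStream, occupancy_series
from .simulate import SECONDS_PER_DAY, day_start

#: Ten-minute slots per care day.
N_SLOTS = 144
SLOT_S = 600

#: A slot is "regularly in-bed" at >= 10 of 14 days, "regularly off-bed"
#: at <= 4 of 14 (the symmetric rule).
NORM_DAYS = 14
REGULAR_IN_DAYS = 10
REGULAR_OFF_DAYS = 4

REGULAR_IN, REGULAR_OFF, IRREGULAR = "regular_in", "regular_off", "irregular"


class InsufficientDataError(ValueError):
    """Raised when a norm is requested from fewer than 14 daily records."""


@dataclass
class DailyRecord:
    """One care day: 144 binary slots plus second-resolution totals.

    ``slots[k]`` covers [08:00 + 10k min, 08:00 + 10(k+1) min) and is True
    when the resident was in bed for more than half of the slot's seconds.
    ``coverage`` is the fraction of the day's 86 400 seconds with data.
    """

    date: _date
    slots: np.ndarray
    total_in_bed_s: int
    total_sleep_s: Optional[int] = None
    coverage: float = 1.0

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=bool)
        if self.slots.shape != (N_SLOTS,):
            raise ValueError(f"a daily record has exactly {N_SLOTS} slots")
        if not 0 <= self.total_in_bed_s <= SECONDS_PER_DAY:
            raise ValueError("total in-bed time must lie within one day")

    @property
    def total_in_bed_h(self) -> float:
        return self.total_in_bed_s / 3600.0

    @property
    def total_sleep_h(self) -> Optional[float]:
        return None if self.total_sleep_s is None else self.total_sleep_s / 3600.0


def _occupancy_for_day(source: Union[FrameStream, np.ndarray, Sequence[str]],
                       date: _date) -> tuple[np.ndarray, np.ndarray]:
    """(occupied, present) boolean second arrays aligned to the 08:00 day."""
    if isinstance(source, FrameStream):
        t0 = np.datetime64(day_start(date), "s")
        offsets = (source.timestamps - t0).astype("int64")
        in_day = (offsets >= 0) & (offsets < SECONDS_PER_DAY)
        occupied = np.zeros(SECONDS_PER_DAY, dtype=bool)
        present = np.zeros(SECONDS_PER_DAY, dtype=bool)
        occ = occupancy_series(source)
        present[offsets[in_day]] = True
        occupied[offsets[in_day]] = occ[in_day]
        return occupied, present
    arr = np.asarray(source)
    if arr.dtype.kind in "OUS":  # posture labels
        occupied = arr != "empty"
    else:
        occupied = arr.astype(bool)
    if occupied.shape != (SECONDS_PER_DAY,):
        raise ValueError(f"expected {SECONDS_PER_DAY} per-second values")
    return occupied, np.ones(SECONDS_PER_DAY, dtype=bool)


def daily_record(source: Union[FrameStream, np.ndarray, Sequence[str]],
                 date: _date,
                 total_sleep_s: Optional[int] = None) -> DailyRecord:
    """Build the daily record from one 08:00-to-08:00 day of data.

    ``source`` is a frame stream, a per-second occupancy array, or per-second
    posture labels (``empty`` = off bed). Missing seconds count as off-bed and
    lower ``coverage``. A slot is in-bed iff occupied more than 50% of its
    600 seconds; totals are computed at 1 s resolution.
    """
    occupied, present = _occupancy_for_day(source, date)
    per_slot = occupied.reshape(N_SLOTS, SLOT_S).sum(axis=1)
    return DailyRecord(
        date=date,
        slots=per_slot > SLOT_S // 2,
        total_in_bed_s=int(occupied.sum()),
        total_sleep_s=total_sleep_s,
        coverage=float(present.mean()),
    )


@dataclass
class NormProfile:
    """Two-week norm: per-slot proportions, regular flags, and averages."""

    proportions: np.ndarray        # (144,) in-bed proportion over the window
    flags: np.ndarray              # (144,) REGULAR_IN / REGULAR_OFF / IRREGULAR
    norm_score: float              # percent of slots regular either way
    avg_in_bed_s: float
    avg_sleep_s: Optional[float]
    effective_from: Optional[_date] = None

    @property
    def avg_in_bed_h(self) -> float:
        return self.avg_in_bed_s / 3600.0

    @property
    def avg_sleep_h(self) -> Optional[float]:
        return None if self.avg_sleep_s is None else self.avg_sleep_s / 3600.0


def compute_norm(records: Sequence[DailyRecord],
                 effective_from: Optional[_date] = None) -> NormProfile:
    """Fold exactly 14 daily records into a :class:`NormProfile`.

    The result is invariant to the order of the records. Raises
    :class:`InsufficientDataError` when fewer than 14 records are supplied.
    """
    if len(records) < NORM_DAYS:
        raise InsufficientDataError(
            f"a norm needs {NORM_DAYS} daily records, got {len(records)}")
    if len(records) > NORM_DAYS:
        raise ValueError(f"a norm is computed over exactly {NORM_DAYS} records")
    slot_matrix = np.stack([r.slots for r in records])        # (14, 144)
    in_days = slot_matrix.sum(axis=0)
    flags = np.full(N_SLOTS, IRREGULAR, dtype=object)
    flags[in_days >= REGULAR_IN_DAYS] = REGULAR_IN
    flags[in_days <= REGULAR_OFF_DAYS] = REGULAR_OFF
    score = float(np.sum(flags != IRREGULAR)) / N_SLOTS * 100.0
    sleeps = [r.total_sleep_s for r in records if r.total_sleep_s is not None]
    return NormProfile(
        proportions=in_days / NORM_DAYS,
        flags=flags,
        norm_score=score,
        avg_in_bed_s=float(np.mean([r.total_in_bed_s for r in records])),
        avg_sleep_s=float(np.mean(sleeps)) if sleeps else None,
        effective_from=effective_from,
    )


@dataclass
class NormComparison:
    """A single day held against the two-week norm."""

    correlation: Optional[float]    # None when either vector has zero variance
    tb_diff_s: float                # day total in-bed minus norm average
    st_diff_s: Optional[float]      # likewise for sleep; None when unavailable

    @property
    def tb_diff_h(self) -> float:
        return self.tb_diff_s / 3600.0

    @property
    def st_diff_h(self) -> Optional[float]:
        return None if self.st_diff_s is None else self.st_diff_s / 3600.0


def daily_vs_norm(day: DailyRecord, norm: NormProfile) -> NormComparison:
    """Correlation and signed time differences of one day against the norm.

    The correlation operands are the day's 144 binary slot values and the
    norm's 144 in-bed proportions; it is reported as missing (None), not
    zero, when either vector is constant.
    """
    x = day.slots.astype(float)
    y = norm.proportions.astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        corr = None
    else:
        corr = float(np.corrcoef(x, y)[0, 1])
    st_diff: Optional[float] = None
    if day.total_sleep_s is not None and norm.avg_sleep_s is not None:
        st_diff = float(day.total_sleep_s - norm.avg_sleep_s)
    return NormComparison(
        correlation=corr,
        tb_diff_s=float(day.total_in_bed_s - norm.avg_in_bed_s),
        st_diff_s=st_diff,
    )


def rolling_norm_records(records: Sequence[DailyRecord], end_index: int,
                         min_coverage: float = 0.8,
                         max_lookback: int = 21) -> list[DailyRecord]:
    """Select the 14 most recent well-covered days ending before ``end_index``.

    Days with under ``min_coverage`` frame coverage are skipped and the window
    extended backward, up to ``max_lookback`` days. Raises
    :class:`InsufficientDataError` if 14 usable days cannot be found.
    """
    chosen: list[DailyRecord] = []
    lookback = 0
    i = end_index - 1
    while i >= 0 and lookback < max_lookback and len(chosen) < NORM_DAYS:
        if records[i].coverage >= min_coverage:
            chosen.append(records[i])
        i -= 1
        lookback += 1
    if len(chosen) < NORM_DAYS:
        raise InsufficientDataError(
            f"only {len(chosen)} usable days in the last {lookback} before "
            f"index {end_index}")
    return list(reversed(chosen))


def plot_daily_record(record: DailyRecord, ax=None):
    """Unstyled bar chart of a day's in-bed/off-bed slots (plotting helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 1.5))
    hours = 8.0 + np.arange(N_SLOTS) / 6.0
    ax.bar(hours, np.where(record.slots, 1.0, 0.4), width=1 / 6.0, align="edge")
    ax.set_xlim(8, 32)
    ax.set_yticks([])
    ax.set_xlabel("hour of care day (08:00 -> 08:00)")
    ax.set_title(f"{record.date}  in bed {record.total_in_bed_h:.1f} h")
    return ax
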