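"""Synthetic resident simulator.

The field data behind this kind of system (nursing-home pressure-mattress
streams) are not publicly available, so this module generates everything the
analytics layers consume, with ground truth attached:

* labeled posture frames for four classes (lying, sitting on the bed, sitting
  on the edge of the bed, empty bed) with between-subject variability,
* full 24 h frame streams (08:00 to 08:00 next day, 1 Hz) driven by archetype
  schedules, a two-state sleep/wake process, and a per-second movement process,
* overnight movement-count series for training the sleep/wake classifier,
* multi-week cohorts of residents across the four living-pattern archetypes
  (regular, free, bedridden, leave-home).

Movement model: within an in-bed epoch the chance of a body movement in any
one second is ``rate / 30`` where ``rate`` is the expected number of
state-changes per 30 s for the current sleep/wake state. A movement displaces
the body slightly, modelled as exactly one sensing area deviating from the
posture template until the next movement; consecutive movements deviate
different areas, so each movement changes the frame in exactly one second and
the downstream movement counter can be validated by brute force.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from datetime import date as _date, datetime, timedelta
from typing import Iterator, Optional, Sequence

import numpy as np

from .frames import DEFAULT_GRID, N_AREAS, FrameStream, SensorGrid

SECONDS_PER_DAY = 86_400
EPOCH_S = 30
EPOCHS_PER_DAY = SECONDS_PER_DAY // EPOCH_S
DAY_START_HOUR = 8  # the care day runs 08:00 -> 08:00 next day

# posture codes
LYING, SITTING_ON_BED, SITTING_ON_EDGE, EMPTY = 0, 1, 2, 3
POSTURES = ("lying", "sitting_on_bed", "sitting_on_edge", "empty")
OCCUPIED_POSTURES = POSTURES[:3]

# sleep-truth codes (per 30 s epoch)
SLEEP, AWAKE, OFF_BED = 0, 1, 2

ARCHETYPES = ("regular", "free", "bedridden", "leave_home")

_TRANSITION_STEP_S = 5  # seconds spent in each intermediate posture at entry/exit


@dataclass(frozen=True)
class PostureTemplate:
    """Canonical on/off pattern for one posture class.

    ``jitter_rate`` is the per-area probability of flipping a state in a
    generated example (sensor noise plus small postural variation);
    ``shift_range`` is the number of grid rows a participant's body may be
    translated by, emulating different heights and positions.
    """

    posture: str
    base_pattern: np.ndarray  # (30,) bool
    jitter_rate: float = 0.05
    shift_range: int = 1

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        pat = np.asarray(self.base_pattern, dtype=bool)
        if pat.shape != (N_AREAS,):
            raise ValueError("base_pattern must have 30 states")
        object.__setattr__(self, "base_pattern", pat)
        if not (0.0 <= self.jitter_rate < 0.5):
            raise ValueError("jitter_rate must lie in [0, 0.5)")
        if self.posture == "empty" and pat.any():
            raise ValueError("empty template must have all states off")


def _rect(grid: SensorGrid, rows: slice, cols: slice) -> np.ndarray:
    m = np.zeros((grid.rows, grid.cols), dtype=bool)
    m[rows, cols] = True
    return m.ravel()


def default_templates(grid: SensorGrid = DEFAULT_GRID,
                      jitter_rate: float = 0.05) -> dict[str, PostureTemplate]:
    """Posture templates on the default 10x3 grid.

    Lying covers most of the mattress length; sitting on the bed concentrates
    pressure from the hips down; sitting on the edge loads a few areas on one
    side near the foot; an empty bed presses nothing. The empty template has
    zero jitter: unloaded threshold sensors read off.
    """
    if grid.rows < 9 or grid.cols < 2:
        raise ValueError("default templates need a grid of at least 9x2")
    r = grid.rows
    return {
        "lying": PostureTemplate(
            "lying", _rect(grid, slice(0, r - 2), slice(None)), jitter_rate),
        "sitting_on_bed": PostureTemplate(
            "sitting_on_bed", _rect(grid, slice(r - 6, r - 1), slice(None)), jitter_rate),
        "sitting_on_edge": PostureTemplate(
            "sitting_on_edge", _rect(grid, slice(r - 5, r - 2), slice(0, 2)), jitter_rate),
        "empty": PostureTemplate(
            "empty", np.zeros(N_AREAS, bool), 0.0),
    }


def _shift_pattern(pattern: np.ndarray, grid: SensorGrid,
                   row_shift: int, mirror: bool) -> np.ndarray:
    """Translate a pattern by whole rows (zero fill) and optionally mirror
    left/right, emulating body size and position on the mattress."""
    m = pattern.reshape(grid.rows, grid.cols)
    out = np.zeros_like(m)
    if row_shift >= 0:
        out[row_shift:] = m[: grid.rows - row_shift] if row_shift else m
    else:
        out[:row_shift] = m[-row_shift:]
    if mirror:
        out = out[:, ::-1]
    return out.ravel()


def _participant_patterns(templates: dict[str, PostureTemplate],
                          grid: SensorGrid, row_shift: int,
                          mirror: bool) -> np.ndarray:
    """(4, 30) pattern matrix for one body, indexed by posture code."""
    pats = np.zeros((4, N_AREAS), dtype=bool)
    for code, name in enumerate(POSTURES):
        pats[code] = _shift_pattern(templates[name].base_pattern, grid, row_shift, mirror)
    return pats


@dataclass
class PostureDataset:
    """Labeled posture examples: (n, 30) features, class labels, participant ids."""

    features: np.ndarray
    labels: np.ndarray
    participants: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


def generate_posture_dataset(n_participants: int, examples_each: int,
                             n_empty: int, seed: int,
                             grid: SensorGrid = DEFAULT_GRID,
                             templates: Optional[dict[str, PostureTemplate]] = None,
                             jitter_rate: Optional[float] = None) -> PostureDataset:
    """Generate the posture training set.

    Each of ``n_participants`` simulated bodies (random row shift and
    left/right mirroring) contributes ``examples_each`` occupied examples,
    balanced over the three occupied postures, plus ``n_empty`` empty-bed
    examples overall. With the default collection design (31 participants x 30
    examples + 80 empty) this yields 1010 examples. ``jitter_rate`` overrides
    the occupied templates' noise level; the empty template keeps its own.
    """
    if n_participants <= 0 or examples_each <= 0 or n_empty < 0:
        raise ValueError("counts must be positive (n_empty may be zero)")
    rng = np.random.default_rng(seed)
    if templates is None:
        templates = default_templates(grid)
    if jitter_rate is not None:
        templates = {
            name: (replace(t, jitter_rate=jitter_rate) if name != "empty" else t)
            for name, t in templates.items()
        }

    base = examples_each // 3
    rem = examples_each % 3
    per_posture = [base + (1 if i < rem else 0) for i in range(3)]

    feats: list[np.ndarray] = []
    labels: list[str] = []
    pids: list[int] = []
    for p in range(n_participants):
        shift_range = max(t.shift_range for t in templates.values())
        row_shift = int(rng.integers(-shift_range, shift_range + 1))
        mirror = bool(rng.integers(0, 2))
        pats = _participant_patterns(templates, grid, row_shift, mirror)
        for code, name in enumerate(OCCUPIED_POSTURES):
            jr = templates[name].jitter_rate
            n = per_posture[code]
            x = np.broadcast_to(pats[code], (n, N_AREAS)).copy()
            if jr > 0:
                x ^= rng.random((n, N_AREAS)) < jr
            feats.append(x)
            labels.extend([name] * n)
            pids.extend([p] * n)
    if n_empty:
        jr = templates["empty"].jitter_rate
        x = np.zeros((n_empty, N_AREAS), dtype=bool)
        if jr > 0:
            x ^= rng.random((n_empty, N_AREAS)) < jr
        feats.append(x)
        labels.extend(["empty"] * n_empty)
        pids.extend([-1] * n_empty)
    return PostureDataset(
        features=np.concatenate(feats, axis=0),
        labels=np.array(labels),
        participants=np.array(pids),
    )


@dataclass(frozen=True)
class ResidentProfile:
    """Behavioural parameters for one simulated resident.

    Times are in hours on the care-day axis (0 = 08:00, 24 = 08:00 next day)
    so an overnight sleep is a single contiguous interval. Movement rates are
    expected frame state-changes per 30 s epoch.
    """

    resident_id: str
    archetype: str
    bed_time_h: float = 13.0          # 21:00
    rise_time_h: float = 23.0         # 07:00
    meal_breaks: tuple[tuple[float, float], ...] = ()  # (start_h, duration_min)
    day_visit_probability: float = 0.0
    max_day_visits: int = 2
    absence_probability: float = 0.0
    sleep_movement_rate: float = 1.0
    wake_movement_rate: float = 6.0
    sleep_bout_mean_min: float = 40.0
    wake_bout_mean_min: float = 5.0
    schedule_jitter_min: float = 15.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if not self.sleep_movement_rate < self.wake_movement_rate:
            raise ValueError("sleep movement rate must be below wake movement rate")


def make_profile(archetype: str, resident_id: Optional[str] = None,
                 **overrides) -> ResidentProfile:
    """Build a profile with the archetype's default schedule.

    regular
        Wheelchair user put to bed 21:00 and risen 07:00 on a fixed schedule.
    free
        Independent resident: shorter night (23:00-06:30) plus spontaneous
        daytime bed visits.
    bedridden
        In bed around the clock except brief assisted meal breaks at 06:00,
        11:00 and 16:00; more than 18 h in bed per day in expectation.
    leave_home
        A regular-like night schedule, but with probability
        ``absence_probability`` (default 0.3) the resident is away for the
        whole care day and the bed stays empty.
    """
    presets: dict[str, dict] = {
        "regular": dict(bed_time_h=13.0, rise_time_h=23.0),
        "free": dict(bed_time_h=15.0, rise_time_h=22.5,
                     day_visit_probability=0.8, schedule_jitter_min=30.0),
        "bedridden": dict(meal_breaks=((22.0, 40.0), (3.0, 40.0), (8.0, 40.0))),
        "leave_home": dict(bed_time_h=14.0, rise_time_h=23.0,
                           absence_probability=0.3),
    }
    if archetype not in presets:
        raise ValueError(f"unknown archetype {archetype!r}")
    kwargs = dict(presets[archetype])
    kwargs.update(overrides)
    if resident_id is None:
        resident_id = archetype
    return ResidentProfile(resident_id=resident_id, archetype=archetype, **kwargs)


def _jitter(rng: np.random.Generator, hours: float, jitter_min: float) -> float:
    if jitter_min <= 0:
        return hours
    return hours + float(rng.uniform(-jitter_min, jitter_min)) / 60.0


def _schedule_intervals(profile: ResidentProfile,
                        rng: np.random.Generator) -> list[tuple[int, int]]:
    """In-bed intervals in seconds on the care-day axis, sorted and merged."""
    j = profile.schedule_jitter_min
    intervals: list[tuple[float, float]] = []
    if profile.archetype == "bedridden":
        breaks = sorted(
            (_jitter(rng, start, j), dur) for start, dur in profile.meal_breaks)
        t = 0.0
        for start, dur_min in breaks:
            start = min(max(start, 0.0), 24.0)
            end = min(start + dur_min / 60.0, 24.0)
            if start > t:
                intervals.append((t, start))
            t = max(t, end)
        if t < 24.0:
            intervals.append((t, 24.0))
    else:
        if profile.absence_probability > 0 and rng.random() < profile.absence_probability:
            return []  # away for the whole care day; the bed stays empty
        bed = _jitter(rng, profile.bed_time_h, j)
        rise = _jitter(rng, profile.rise_time_h, j)
        if rise > bed:
            intervals.append((bed, rise))
        if profile.day_visit_probability > 0 and rng.random() < profile.day_visit_probability:
            n_visits = int(rng.integers(1, profile.max_day_visits + 1))
            for _ in range(n_visits):
                start = float(rng.uniform(1.0, 12.0))  # 09:00-20:00
                dur = float(rng.uniform(40.0, 90.0)) / 60.0
                intervals.append((start, min(start + dur, profile.bed_time_h)))
    # to seconds; clip, drop degenerate, merge overlaps / near-touching gaps
    secs = []
    for a, b in intervals:
        a_s = max(0, int(round(a * 3600)))
        b_s = min(SECONDS_PER_DAY, int(round(b * 3600)))
        if b_s - a_s >= 120:
            secs.append((a_s, b_s))
    secs.sort()
    merged: list[tuple[int, int]] = []
    for a_s, b_s in secs:
        if merged and a_s <= merged[-1][1] + 60:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b_s))
        else:
            merged.append((a_s, b_s))
    return merged


def _posture_codes(intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    """Per-second posture, with entry passing empty->edge->sitting->lying and
    exit the reverse."""
    codes = np.full(SECONDS_PER_DAY, EMPTY, dtype=np.int8)
    s = _TRANSITION_STEP_S
    for a, b in intervals:
        codes[a:b] = LYING
        codes[a:a + s] = SITTING_ON_EDGE
        codes[a + s:a + 2 * s] = SITTING_ON_BED
        codes[b - 2 * s:b - s] = SITTING_ON_BED
        codes[b - s:b] = SITTING_ON_EDGE
    return codes


def _sleep_chain(in_bed_epoch: np.ndarray, profile: ResidentProfile,
                 rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov chain over in-bed epochs; awake on bed entry.

    Dwell times are geometric with the configured means (defaults: sleep bouts
    40 min, wake bouts 5 min), giving roughly 89% of in-bed time asleep.
    """
    n = len(in_bed_epoch)
    out = np.full(n, OFF_BED, dtype=np.int8)
    p_s2w = min(1.0, EPOCH_S / (profile.sleep_bout_mean_min * 60.0))
    p_w2s = min(1.0, EPOCH_S / (profile.wake_bout_mean_min * 60.0))
    u = rng.random(n)
    state = AWAKE
    prev_in = False
    for i in range(n):
        if not in_bed_epoch[i]:
            prev_in = False
            continue
        if not prev_in:
            state = AWAKE  # a resident is awake when entering bed
        elif state == SLEEP and u[i] < p_s2w:
            state = AWAKE
        elif state == AWAKE and u[i] < p_w2s:
            state = SLEEP
        out[i] = state
        prev_in = True
    return out


def _movement_overlay(frames: np.ndarray, intervals: Sequence[tuple[int, int]],
                      event_mask: np.ndarray, rng: np.random.Generator) -> None:
    """Apply movement events in place: at each event second a new single area
    deviates from the template (and the previous deviation is restored), so
    consecutive frames differ exactly at event seconds."""
    ev_idx = np.flatnonzero(event_mask)
    if len(ev_idx) == 0:
        return
    first = int(rng.integers(0, N_AREAS))
    steps = rng.integers(1, N_AREAS, size=len(ev_idx))
    areas = (first + np.cumsum(steps)) % N_AREAS  # never repeats consecutively
    for a, b in intervals:
        lo = np.searchsorted(ev_idx, a)
        hi = np.searchsorted(ev_idx, b)
        if hi <= lo:
            continue
        ev = ev_idx[lo:hi]
        ar = areas[lo:hi]
        sec = np.arange(ev[0], b)
        pos = np.searchsorted(ev, sec, side="right") - 1
        frames[sec, ar[pos]] ^= True


@dataclass
class DayData:
    """One simulated care day with ground truth attached."""

    resident_id: str
    date: _date
    day_label: str                      # the resident's archetype
    stream: Optional[FrameStream]       # None when frames were not materialised
    posture_truth: np.ndarray           # (86400,) posture codes
    sleep_truth: np.ndarray             # (2880,) SLEEP / AWAKE / OFF_BED
    intervals: list[tuple[int, int]]    # in-bed intervals, seconds from 08:00
    absent: bool = False

    @property
    def in_bed_seconds(self) -> int:
        return int(sum(b - a for a, b in self.intervals))

    @property
    def occupancy_truth(self) -> np.ndarray:
        """(86400,) ground-truth in-bed indicator per second."""
        return self.posture_truth != EMPTY


def day_start(date: _date) -> datetime:
    """The 08:00 instant opening the care day labelled ``date``."""
    return datetime.combine(date, datetime.min.time()) + timedelta(hours=DAY_START_HOUR)


def _resident_body(resident_id: str) -> tuple[int, bool]:
    """Stable per-resident template variation derived from the id."""
    h = zlib.crc32(resident_id.encode())
    return (h % 3) - 1, bool((h >> 2) & 1)


def simulate_day(profile: ResidentProfile, date: _date,
                 seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None,
                 grid: SensorGrid = DEFAULT_GRID,
                 templates: Optional[dict[str, PostureTemplate]] = None,
                 with_frames: bool = True) -> DayData:
    """Simulate one 08:00-to-08:00 care day at 1 Hz.

    Returns the frame stream plus per-second posture ground truth and
    per-epoch sleep/awake/off-bed ground truth. ``with_frames=False`` skips
    frame materialisation (schedule and labels only), which is cheap enough
    for counting experiments over large cohorts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if templates is None:
        templates = default_templates(grid)
    intervals = _schedule_intervals(profile, rng)
    codes = _posture_codes(intervals)
    in_bed_sec = codes != EMPTY
    in_bed_epoch = in_bed_sec.reshape(EPOCHS_PER_DAY, EPOCH_S).sum(axis=1) > EPOCH_S // 2
    sleep_truth = _sleep_chain(in_bed_epoch, profile, rng)

    # per-second movement probability from the epoch's sleep/wake state
    rate = np.zeros(EPOCHS_PER_DAY)
    rate[sleep_truth == SLEEP] = profile.sleep_movement_rate
    rate[sleep_truth == AWAKE] = profile.wake_movement_rate
    p_sec = np.repeat(rate / EPOCH_S, EPOCH_S)
    events = (rng.random(SECONDS_PER_DAY) < p_sec) & in_bed_sec

    stream = None
    if with_frames:
        row_shift, mirror = _resident_body(profile.resident_id)
        pats = _participant_patterns(templates, grid, row_shift, mirror)
        states = pats[codes]
        _movement_overlay(states, intervals, events, rng)
        t0 = np.datetime64(day_start(date), "s")
        timestamps = t0 + np.arange(SECONDS_PER_DAY, dtype="timedelta64[s]")
        stream = FrameStream(profile.resident_id, timestamps, states)

    return DayData(
        resident_id=profile.resident_id,
        date=date,
        day_label=profile.archetype,
        stream=stream,
        posture_truth=codes,
        sleep_truth=sleep_truth,
        intervals=intervals,
        absent=not intervals,
    )


@dataclass
class NightData:
    """One simulated overnight in-bed recording (movement counts + truth)."""

    counts: np.ndarray       # (n_epochs,) movement counts 0..30
    stages: np.ndarray       # (n_epochs,) SLEEP / AWAKE


def simulate_night(hours: float = 8.0, seed: Optional[int] = None,
                   sleep_movement_rate: float = 1.0,
                   wake_movement_rate: float = 6.0,
                   sleep_bout_mean_min: float = 40.0,
                   wake_bout_mean_min: float = 5.0,
                   grid: SensorGrid = DEFAULT_GRID) -> NightData:
    """Simulate a continuous in-bed night and recount its movements.

    The resident lies in bed for ``hours``; sleep/wake alternates via the
    two-state chain and movement events perturb the frames. Counts are then
    recovered from the frames by the same comparison rule the analytics use,
    so the training data exercise the full measurement path.
    """
    from .sleep import movement_counts  # local import: sleep is downstream

    rng = np.random.default_rng(seed)
    n_sec = int(hours * 3600) // EPOCH_S * EPOCH_S
    n_ep = n_sec // EPOCH_S
    profile = make_profile(
        "regular",
        sleep_movement_rate=sleep_movement_rate,
        wake_movement_rate=wake_movement_rate,
        sleep_bout_mean_min=sleep_bout_mean_min,
        wake_bout_mean_min=wake_bout_mean_min,
    )
    stages = _sleep_chain(np.ones(n_ep, bool), profile, rng)
    rate = np.where(stages == SLEEP, sleep_movement_rate, wake_movement_rate)
    events = rng.random(n_sec) < np.repeat(rate / EPOCH_S, EPOCH_S)
    pats = _participant_patterns(default_templates(grid), grid, 0, False)
    states = np.broadcast_to(pats[LYING], (n_sec, N_AREAS)).copy()
    _movement_overlay(states, [(0, n_sec)], events, rng)
    counts = movement_counts(states)
    return NightData(counts=counts, stages=stages)


def simulate_cohort(profiles: Sequence[ResidentProfile], n_days: int, seed: int,
                    start_date: _date = _date(2021, 8, 2),
                    with_frames: bool = True,
                    grid: SensorGrid = DEFAULT_GRID) -> Iterator[DayData]:
    """Yield ``n_days`` consecutive simulated days for each resident.

    Days are generated lazily (a 24-resident, 12-week cohort holds far too
    many frames to keep in memory at once). Seeding is per resident-day, so
    any slice of the cohort is reproducible independently.
    """
    if not profiles:
        raise ValueError("simulate_cohort needs at least one profile")
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    for r_idx, profile in enumerate(profiles):
        for d_idx in range(n_days):
            rng = np.random.default_rng(np.random.SeedSequence([seed, r_idx, d_idx]))
            yield simulate_day(
                profile, start_date + timedelta(days=d_idx),
                rng=rng, grid=grid, with_frames=with_frames,
            )


def default_cohort(n_residents: int = 24) -> list[ResidentProfile]:
    """Archetype-balanced cohort: residents cycle through the four archetypes."""
    profiles = []
    for i in range(n_residents):
        arch = ARCHETYPES[i % len(ARCHETYPES)]
        profiles.append(make_profile(arch, resident_id=f"R{i + 1:02d}"))
    return profiles
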