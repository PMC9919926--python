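"""Daily records, the two-week norm, and day-vs-norm comparison."""

from datetime import date, timedelta

import numpy as np
import pytest
from scipy.stats import binom

import bedsense as bs
from bedsense.records import (IRREGULAR, REGULAR_IN, REGULAR_OFF,
                              InsufficientDataError, rolling_norm_records)

DAY = date(2021, 8, 2)


def occupancy_for(intervals_h):
    """Per-second occupancy from (start_h, end_h) day-axis intervals."""
    occ = np.zeros(86400, bool)
    for a, b in intervals_h:
        occ[int(a * 3600):int(b * 3600)] = True
    return occ


def record_from(intervals_h, d=DAY, sleep_s=None):
    return bs.daily_record(occupancy_for(intervals_h), d, total_sleep_s=sleep_s)


class TestDailyRecord:
    def test_schedule_identity(self):
        # in bed 22:00-07:00 = day-axis hours 14..23 -> 54 slots, 9 h
        rec = record_from([(14, 23)])
        assert rec.slots.sum() == 54
        assert rec.total_in_bed_s == 9 * 3600

    def test_never_in_bed(self):
        rec = record_from([])
        assert rec.slots.sum() == 0 and rec.total_in_bed_s == 0

    def test_slot_threshold_is_majority_of_600_seconds(self):
        occ = np.zeros(86400, bool)
        occ[:301] = True          # 301/600 occupied -> in bed
        occ[600:900] = True       # 300/600 occupied -> off bed
        rec = bs.daily_record(occ, DAY)
        assert rec.slots[0] and not rec.slots[1]
        assert rec.total_in_bed_s == 601  # totals at 1 s resolution

    def test_posture_labels_accepted(self):
        labels = np.full(86400, "empty", dtype=object)
        labels[:7200] = "lying"
        rec = bs.daily_record(labels, DAY)
        assert rec.total_in_bed_s == 7200

    def test_stream_alignment_and_coverage(self):
        day = bs.simulate_day(bs.make_profile("regular"), DAY, seed=0)
        rec = bs.daily_record(day.stream, DAY)
        assert rec.coverage == 1.0
        assert rec.total_in_bed_s == day.in_bed_seconds


class TestNorm:
    def test_fourteen_identical_days_score_100(self):
        records = [record_from([(14, 23)], DAY + timedelta(days=i))
                   for i in range(14)]
        norm = bs.compute_norm(records)
        assert norm.norm_score == 100.0
        assert set(np.unique(norm.flags)) <= {REGULAR_IN, REGULAR_OFF}
        assert norm.avg_in_bed_h == pytest.approx(9.0)

    def test_exactly_ten_irregular_slots_score_93_1(self):
        # 7 of 14 days extend bedtime by 100 min -> 10 slots at 7/14 in-bed
        records = []
        for i in range(14):
            start = 14.0 - (10 / 6.0 if i < 7 else 0.0)
            records.append(record_from([(start, 23)], DAY + timedelta(days=i)))
        norm = bs.compute_norm(records)
        assert int(np.sum(norm.flags == IRREGULAR)) == 10
        assert norm.norm_score == pytest.approx(134 / 144 * 100, abs=1e-9)
        assert f"{norm.norm_score:.1f}" == "93.1"

    def test_fewer_than_fourteen_days_rejected(self):
        records = [record_from([(14, 23)]) for _ in range(13)]
        with pytest.raises(InsufficientDataError):
            bs.compute_norm(records)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        records = [bs.daily_record(rng.random(86400) < 0.4, DAY)
                   for _ in range(14)]
        n1 = bs.compute_norm(records)
        n2 = bs.compute_norm(records[::-1])
        assert n1.norm_score == n2.norm_score
        assert np.array_equal(n1.proportions, n2.proportions)

    def test_fair_coin_slots_match_exact_binomial_expectation(self):
        # E[score] = 100 * (P(X>=10) + P(X<=4)), X ~ Bin(14, 1/2) = 17.9565%
        exact = 100 * (binom.sf(9, 14, 0.5) + binom.cdf(4, 14, 0.5))
        assert exact == pytest.approx(17.9565, abs=1e-3)
        rng = np.random.default_rng(7)
        scores = []
        for _ in range(40):
            records = [bs.DailyRecord(DAY, rng.random(144) < 0.5, 0)
                       for _ in range(14)]
            scores.append(bs.compute_norm(records).norm_score)
        assert np.mean(scores) == pytest.approx(exact, abs=1.5)

    def test_score_bounds(self):
        rng = np.random.default_rng(1)
        records = [bs.DailyRecord(DAY, rng.random(144) < 0.5, 0) for _ in range(14)]
        assert 0.0 <= bs.compute_norm(records).norm_score <= 100.0


class TestDailyVsNorm:
    def test_identical_day_correlates_perfectly(self):
        records = [record_from([(14, 23)]) for _ in range(14)]
        norm = bs.compute_norm(records)
        cmpn = bs.daily_vs_norm(records[0], norm)
        assert cmpn.correlation == pytest.approx(1.0)
        assert cmpn.tb_diff_s == 0.0

    def test_complement_day_anticorrelates(self):
        records = [record_from([(14, 23)]) for _ in range(14)]
        norm = bs.compute_norm(records)
        flipped = bs.DailyRecord(DAY, ~records[0].slots, 15 * 3600)
        assert bs.daily_vs_norm(flipped, norm).correlation == pytest.approx(-1.0)

    def test_tb_difference_of_the_worked_example(self):
        # day 7 h 38 min in bed vs norm average 7 h 04 min -> +34 min
        day = bs.DailyRecord(DAY, occupancy_for([(14, 21.5)])[::600][:144],
                             total_in_bed_s=7 * 3600 + 38 * 60)
        norm = bs.NormProfile(
            proportions=np.linspace(0, 1, 144), flags=np.full(144, IRREGULAR),
            norm_score=50.0, avg_in_bed_s=7 * 3600 + 4 * 60, avg_sleep_s=None)
        cmpn = bs.daily_vs_norm(day, norm)
        assert cmpn.tb_diff_s == 34 * 60
        assert abs(cmpn.tb_diff_h) < 1.0  # lands in dashboard level 1

    def test_zero_variance_reports_missing_not_zero(self):
        norm = bs.NormProfile(
            proportions=np.full(144, 1.0), flags=np.full(144, REGULAR_IN),
            norm_score=100.0, avg_in_bed_s=86400.0, avg_sleep_s=None)
        day = bs.DailyRecord(DAY, np.ones(144, bool), 86400)
        assert bs.daily_vs_norm(day, norm).correlation is None

    def test_consistent_slot_relabeling_preserves_correlation(self):
        rng = np.random.default_rng(3)
        day = bs.DailyRecord(DAY, rng.random(144) < 0.5, 40000)
        norm = bs.NormProfile(
            proportions=rng.random(144), flags=np.full(144, IRREGULAR),
            norm_score=0.0, avg_in_bed_s=40000.0, avg_sleep_s=None)
        base = bs.daily_vs_norm(day, norm).correlation
        perm = rng.permutation(144)
        day2 = bs.DailyRecord(DAY, day.slots[perm], 40000)
        norm2 = bs.NormProfile(
            proportions=norm.proportions[perm], flags=norm.flags[perm],
            norm_score=0.0, avg_in_bed_s=40000.0, avg_sleep_s=None)
        assert bs.daily_vs_norm(day2, norm2).correlation == pytest.approx(base)


def test_rolling_norm_skips_low_coverage_days():
    good = [bs.DailyRecord(DAY + timedelta(days=i), np.zeros(144, bool), 0,
                           coverage=1.0) for i in range(16)]
    good[10] = bs.DailyRecord(DAY + timedelta(days=10), np.zeros(144, bool), 0,
                              coverage=0.5)
    chosen = rolling_norm_records(good, end_index=16)
    assert len(chosen) == 14
    assert all(r.coverage >= 0.8 for r in chosen)
    with pytest.raises(InsufficientDataError):
        rolling_norm_records(good[:14], end_index=14, max_lookback=14)
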