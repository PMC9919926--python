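"""Two-week norm, norm score, and the five-index wellbeing dashboard.

Builds 15 simulated days for one resident: the first 14 form the norm, the
15th is graded against it.
"""

import bedsense as bs

profile = bs.make_profile("regular", resident_id="R01")
days = list(bs.simulate_cohort([profile], 15, seed=2, with_frames=False))
records = [bs.daily_record(d.occupancy_truth, d.date) for d in days]

norm = bs.compute_norm(records[:14])
print(f"norm score {norm.norm_score:.1f} "
      f"(percent of 144 ten-minute slots regularly in- or off-bed)")
print(f"norm averages: in bed {norm.avg_in_bed_h:.2f} h/day")

today = records[14]
cmp = bs.daily_vs_norm(today, norm)
print(f"day 15: in bed {today.total_in_bed_h:.2f} h, "
      f"correlation with norm {cmp.correlation:.3f}, "
      f"in-bed difference {cmp.tb_diff_h * 60:+.0f} min")

indices = bs.index_levels(cmp.tb_diff_h, cmp.correlation, st_diff_h=None,
                          se_pct=88.0, pp_h=0.8,
                          total_in_bed_h=today.total_in_bed_h)
rating = bs.overall_rating(indices)
print(f"index levels: {indices.levels}")
print(f"overall rating: {rating.rating} ({rating.color})")
# Level 1 is best. TB/ST compare the day against the norm in hours, CC is
# the pattern correlation, SE uses the PSQI sleep-efficiency bands, and PP
# (prolonged pressure) only applies when the day exceeds 12 h in bed.
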