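# Methods

This note records the models behind each analysis layer, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and geometry

The input is a 1 Hz stream of 30 binary pressure states. The physical
arrangement of the 30 areas is configurable (`SensorGrid`); the default
convention is 10 rows (head→foot) × 3 columns (left/centre/right), area ids
row-major 1..30. Only the simulator's posture templates depend on this
convention — every analysis layer treats the frame as an unordered 30-bit
vector or uses per-area run lengths.

Streams are stored as one CSV row per second (ISO-8601 timestamp + 30
`0`/`1` fields), chosen for diff-ability. Missing seconds are permitted:
they count as off-bed in daily records and lower the record's `coverage`,
and movement counting treats a gap as "frame unchanged".

## Posture identification (layer 2)

A multilayer perceptron (one hidden layer of 16 units, adam, no early
stopping, seed-fixed) maps the 30 binary features to four classes. The
feature map is the identity on the frame's states, so the classifier is as
small as the problem. Two hard rules sit outside the learned model:

- an all-off frame is *empty* by definition (prevents pathological learned
  behaviour on the one input whose label is not statistical);
- full-day classification compresses consecutive identical frames and
  classifies each run once, which is exact and keeps a 86 400-frame day
  cheap.

Training reports stratified 10-fold cross-validated accuracy and per-class
precision/recall; the final model is refit on all data. On noiseless
template data the classifier coincides with a nearest-template rule (tested).

## Bed-exit alerts

The alert state machine consumes the 1 Hz posture sequence. A posture change
is accepted only after it persists for the debounce window (default 3 s), so
any flicker shorter than the window can never trigger an alert. Within an
exit episode (established by lying) the milestones *sitting on the bed* → 1,
*sitting at the edge* → 2, *empty* → 3 each fire at most once and only in
increasing order; skipped milestones are not back-filled (a direct
lying→empty transition emits only stage 3 — the alert describes what
happened, not a fabricated intermediate). Returning to lying resets the
episode. After a completed exit a refractory period (default 60 s) mutes new
alerts to avoid storms. Which stages are enabled is per-resident
configuration; the presets high = {1,2,3}, medium = {2,3}, low = {3} are
suggestions, not claims about any deployed system.

## Movement counting and sleep staging (layer 4a)

A second counts as movement iff its frame differs in ≥1 area from its
predecessor; counts accumulate per 30 s epoch (0..30). The first frame of an
epoch compares against the last frame of the previous epoch; the first frame
ever counts as no movement. The per-10-minute movement percentage is the sum
of 20 epoch counts divided by 600 s.

The sleep/awake classifier is a multilayer perceptron (one hidden layer of
8 units, standardised inputs, seed-fixed) over trailing 240 s windows —
8 epochs of counts — labelling each window's last epoch. Within an in-bed
bout the first 7 epochs reuse the first full window's label; bouts shorter
than 8 epochs are left-padded with their first count. Off-bed epochs are
excluded from the classifier entirely. Epochs spanning a bed entry/exit are
assigned by majority occupancy within the epoch. Accuracy and the awake
class's sensitivity (recall) are reported per epoch from cross-validated
predictions; awake epochs are the minority of a night, so their recall is
the informative number.

Sleep efficiency = total sleep / total in-bed × 100, both at epoch
resolution, so sleep + awake = in-bed exactly.

## Daily records and the two-week norm (layers 3 and 5)

A care day runs 08:00→08:00 so one overnight sleep stays on one chart. A
ten-minute slot is in-bed iff occupied for more than 50% of its 600 seconds
(the binarisation threshold is a convention; totals are always kept at 1 s
resolution so the threshold does not bias them). A norm folds exactly 14
records: per-slot in-bed proportion; *regularly in-bed* at ≥10/14 days,
*regularly off-bed* at ≤4/14 (the symmetric reading of "more than 70%", via
10/14 ≈ 71.4%); norm score = percent of the 144 slots regular either way.
The day-vs-norm correlation is Pearson's r between the day's binary slot
vector and the norm's proportions — reported as missing, never zero, when
either vector is constant. In production use the norm refreshes weekly over
the 14 preceding complete days; days with under 80% frame coverage are
skipped and the window extended backward up to 21 days
(`rolling_norm_records`). The pipeline refreshes every
`norm_refresh_days` (default 7) from day 14.

## Prolonged pressure (layer 4b)

Per area and day: longest continuous on-run and accumulated on-time at 1 s
resolution. A single off-second breaks a run: no tolerance gap is applied,
because with binary sensors any gap length would be a free parameter with no
data to set it, and the accumulated figure is unaffected either way. Flags:
orange above 1 h continuous, red above
2 h, matching the two-hour repositioning interval of common care practice.
Runs spanning the 08:00 boundary are split there; each day reports its own
portion. The dashboard's PP index uses the per-area maximum continuous time
(the record is area-based), not whole-body occupancy.

## Wellbeing dashboard

Bands, with overlapping printed edges resolved as half-open intervals
(better level wins at a tie):

| index | L1 | L2 | L3 | L4 | unit |
|---|---|---|---|---|---|
| TB, ST (abs. day − norm) | ≤1 | (1,2] | (2,3] | >3 | h |
| CC | ≥0.7 | [0.5,0.7) | [0.3,0.5) | <0.3 | r |
| SE (PSQI bands) | ≥85 | [75,85) | [65,75) | <65 | % |
| PP (max continuous) | ≤1 | (1,2] | (2,4] | >4 | h |

SE level 2 is implemented as [75, 85) so that 84.5% grades level 2, matching
the PSQI intent behind the printed "75%–84%". PP applies only when total
in-bed time exceeds 12 h; exactly 12 h counts as not applicable. The overall
rating is the worst present level (Great/Normal/Attention/Abnormal); indices
without values are ignored unless *all* are missing, which rates Off-Bed.
This makes the rating monotone: worsening any one level can never improve
it. The cohort summary list red-flags |differences| above 2 h.

## Living patterns (layer 6)

Each day is one sample — the 144 binary slots, unscaled, under Euclidean
distance — because pattern switching is a day-level phenomenon. k-means with
k = 4, k-means++ initialisation, 10 restarts, seed-fixed. Cluster naming is
statistical (a field deployment would confirm names with caregivers, which a
library cannot): Bedridden = largest centroid mean in-bed time, Leave-home =
smallest, and of the remaining two, Regular = the centroid concentrating
more of its in-bed mass in 21:00–07:00 (a typical lights-out window); free
residents' daytime bed visits dilute their night concentration, which is
what the discriminator keys on.

A pattern change is confirmed when a new type persists for the full change
window (default 3 days, the smallest window robust to one-day blips); the
event is dated at the window's last day and carries old → new types.

## The synthetic resident simulator

The generator defines the study conditions; its defaults are fixed and the
tests run against them.

**Posture dataset.** Three occupied templates on the 10×3 grid (lying: rows
1–8 full width; sitting on the bed: pressure from the hips down, rows 5–9;
sitting on the edge: rows 6–8 on one side) plus the all-off empty bed. Each
simulated participant gets a row shift in {−1, 0, +1} and a random
left/right mirroring (body size and position); each occupied example flips
each area independently with the template's jitter rate (default 0.05).
Empty-bed examples are noise-free: an unloaded threshold sensor reads off.
The default collection is 31 participants × 30 examples balanced over the
three occupied postures, plus 80 empty frames (1010 total).

**Days.** Archetype schedules on the 08:00 day axis, each boundary jittered
±15 min uniformly (configurable to zero for exact tests):

- *regular* — put to bed 21:00, risen 07:00 (wheelchair user, fixed routine);
- *free* — night 23:00–06:30 plus, with probability 0.8, one or two
  spontaneous daytime bed visits of 40–90 min;
- *bedridden* — in bed around the clock except 40 min assisted meal breaks
  at 06:00, 11:00 and 16:00 (≈22 h/day in bed, >18 h in expectation);
- *leave-home* — a regular-like night (22:00–07:00) but with probability 0.3
  the resident is away the whole care day and the bed stays empty.

Bed entries pass empty→edge→sitting→lying over 5 s steps; exits reverse.

**Sleep/wake and movement.** Within in-bed time a two-state Markov chain at
30 s resolution alternates sleep and wake (geometric dwell times, means
40 min and 5 min → ≈89% of in-bed time asleep); the resident is awake on bed
entry. Each second carries a movement event with probability rate/30, where
the rate is 1.0 state-changes per 30 s asleep and 6.0 awake — actigraphy-like
orders of magnitude with a clear but overlapping separation. A movement
deviates exactly one (new) sensing area from the posture template until the
next movement, so each event changes the frame in exactly one second: the
movement counter can be validated by brute force, and generated counts equal
event counts by construction.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: pressure magnitude, ballistocardiography and
breathing, realistic within-night posture rolling (movements perturb one
area rather than shifting the body), sensor dropout and drift, correlated
multi-area movement, or behaviourally realistic variation between residents
of the same archetype beyond schedule jitter and template shifts. Classifier
accuracies measured on this generator characterise the implementation, not
expected field performance.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; cohort simulation seeds
each resident-day independently (`SeedSequence([seed, resident, day])`), so
any slice is reproducible in isolation and pipeline re-runs are
byte-identical. The test suite and acceptance script use the collection
design's own sizes where stated (1010 posture examples; five ~8 h nights
giving ≈4765 windows; 50 bedridden days; a 24-resident × 84-day cohort for
the end-to-end run) — these are the study conditions, not tuned quantities.

## Known limitations

- The posture and sleep models are trained and evaluated on synthetic data;
  no claim transfers to a physical mattress without recalibration.
- The norm requires 14 complete days; a new resident has no dashboard TB/CC/
  ST indices for their first two weeks.
- Cluster naming assumes all four archetypes are present in the fitted data;
  on a cohort lacking one, the names remain a permutation of the four and
  should be reviewed.
- The movement model makes prolonged-pressure runs shorter for restless
  residents than a real body-shift model would; PP statistics from the
  simulator are illustrative only.
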