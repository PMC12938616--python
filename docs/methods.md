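# Methods

## Scoring model

The feedback chain is deliberately literal.  For each regulation TR the raw
ROI mean is referenced to the arithmetic mean of the block's own preceding
baseline window (8 TRs), converted to percent signal change, rescaled so
the participant's localizer maximum sits at 100, and clipped to [0, 100].
Negative excursions clip to 0: the display is bounded, and a bar below its
floor carries no extra information.  The categorical display maps S(t) to
faces with left-closed boundaries at exactly 10 / 40 / 70; values below 10
show the neutral face (level 0), which is also the baseline stimulus.

Two hit rules are first class.  The default, `met_or_exceeded`, counts a TR
as a hit when S(t) reaches the cued level's lower boundary — this is the
rule the block-level success criterion states, and it means overshooting a
low cue still counts.  The alternative, `within_range`, requires S(t) to
lie inside the cued range and is the semantics the continuous occupancy and
distance-to-range metrics always use, independent of the classification
rule.  Reports record which rule produced them.  The success threshold is
`ceil(hit_fraction × regulation TRs)` = 6 of 12 under the defaults.

No hemodynamic-lag compensation is applied in the scoring engine: feedback
for a TR uses that TR's value, as a real-time system would.  The simulator's
HRF supplies the realistic 2–3 TR rise, so even a perfectly calibrated
noise-free participant scores 9–10 hits out of 12, not 12.  A configurable
number of initial "grace" TRs can be excluded from hit counting; the
default of 0 keeps the literal 12-TR rule.  If a TR's value is invalid
(non-positive baseline), the display holds the last valid state and the
held value still counts toward classification.

## Session layout

A run is an 8-TR stabilization period followed by 27 back-to-back blocks of
8 baseline + 12 regulation + 2 outcome TRs (602 TRs at TR = 2 s).  The
block order is a uniform shuffle of the fully crossed modality × level cell
multiset with three repeats — 27 = 3 × 3 × 3, which also fixes 9 blocks per
modality per run and 18 per modality per participant over a two-run
session.  TR indexing is 0-based with half-open windows; the stabilization
period plus the block windows tile the run exactly, and stabilization TRs
are never scored.  The numeric level cue is modelled as instantaneous at
the first regulation TR, since the design allocates no separate cue TRs.

The localizer is ten 5-TR task blocks between eleven 10-TR rest periods
(160 TRs).  The total length follows from the stated block structure; no
attempt is made to pad it to a separately quoted wall-clock duration.

Per-(participant, run) randomness comes from one generator stream each,
derived from the master seed by CRC-hashing the labels into the seed
sequence, so cohorts are reproducible and independent of generation order.

## Synthetic cohort

The generator emulates the study population: nine participants, six
assigned to a 3T scanner and three to 7T, with sustained-tapping response
amplitudes (`gain`) drawn from 1.5–4.5 %ΔBOLD — the range reported for
sensorimotor hand-area ROIs.  BOLD is the effort trace times `gain`,
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1/6, unit area at the TR sampling — so a sustained unit input
plateaus at exactly `gain`), plus linear drift and AR(1) noise
(innovation SD 0.1–0.2 %ΔBOLD, φ 0.2–0.4).

Behaviour is a set-point controller.  A participant's internal aim for a
cued level is the level's display midpoint plus a **shared display-to-effort
mapping error** per modality (mean −0.25, SD 0.14 in display fraction —
participants start systematically under-driving the targets) plus a small
fixed per-cell quirk (SD 0.08), perturbed block-to-block by control noise.
During regulation the effort is corrected each TR against the perceived
display error: proportionally for the thermometer (rate 0.03–0.06), via the
coarse level difference for the face display (0.02–0.05), and not at all
without feedback.  Learning fires only on successful blocks: the modality's
control noise shrinks multiplicatively and the shared mapping error relaxes
toward the miscalibration the successful block exposed (its corrected
late-block effort), with rate 0.12–0.22 for cFB and 0 for aFB/noFB.
Because the mapping error is shared across levels, one success recalibrates
the whole modality, which is what lets the learning effect span a session
rather than saturating within the first blocks.

These constants were chosen once to place the cohort in the study's regime:
first-run success mid-range rather than at floor or ceiling, a
continuous-feedback learning gain of roughly +15 percentage points between
runs, and flat categorical/no-feedback conditions.  Under the defaults a
cohort averages ≈50% success overall and the cFB RUN2 − RUN1 delta is the
largest of the three modalities in ≈97% of replicates.

What the generator does **not** model: physiological (cardiac/respiratory)
noise, motion, scanner drift nonlinearity, strategy switching, fatigue, or
any difference between 3T and 7T signal quality (field strength only routes
the latency tail).  Passing tests therefore show the analysis stack is
correct and the learning signature is recoverable under this forward model
— not that real participants behave like the controller.

Latency logs are lognormal transfer times (median 454 ms, σ = 0.35) with a
per-volume probability (default 0.0036, 7T only) of replacement by a
heavy-tail event above 2000 ms, plus zero-truncated normal processing times
(300 ± 73 ms).

## Localizer GLM and ROI

The streaming GLM accumulates X'X, X'y and y'y per volume; estimates at any
point equal batch least squares on the volumes seen (verified to 1e-8
relative).  The design is the HRF-convolved task boxcar, an intercept and a
linear trend; the contrast is the task coefficient.  Residual variance is
floored at 1e-12 so noise-free synthetic fixtures yield large finite t
rather than infinities.  ROI selection thresholds the t-map and takes the
face-connected (6-neighbour) cluster containing the global peak —
"most significant" is read as peak height, not extent — with ties broken by
cluster size then lexicographic peak coordinate.  Sizes are book-kept at
0.012 cm³ per voxel (2 × 2 × 3 mm³).  The anatomical constraint of the
original procedure is replaced by an optional prior mask, since synthetic
grids have no anatomy.

Calibration takes the **maximum block-averaged** %ΔBOLD across localizer
task blocks, each referenced to its preceding rest block.  A block mean is
used instead of a single-TR peak so that the 100% display point is not set
by a noise spike; the original system's exact definition of "maximum
activation level" is not specified, and this is the package's reading.

## Inference

The paired Wilcoxon signed-rank test discards zero differences (the
original procedure, rather than Pratt's), mid-ranks ties, takes
W = min(W⁺, W⁻), and computes the two-sided p exactly as
min(1, 2·P(W ≤ w_obs)) under the enumeration null over all 2ⁿ sign
assignments — evaluated by subset-sum convolution on the doubled-rank
lattice, which is identical to explicit enumeration but O(n·Σranks).
Beyond n = 20 a normal approximation with tie and continuity corrections
takes over.  Cohen's d_z is the mean difference over the (n−1) SD of
differences; it is undefined (an error) for zero-variance differences.
The Friedman statistic uses within-subject mid-ranks with the standard tie
correction and a χ²(k−1) reference distribution.

The binomial GLMM used alongside these tests in the original analysis is an
off-the-shelf mixed-model fit and is out of scope; the learning analysis
here rests on the paired exact tests and the Friedman check.

## Performance metrics

Occupancy is the fraction of regulation TRs inside the cued range;
distance-to-range is 0 inside and the absolute distance to the nearest
boundary outside, summarized per block by median (precision) and n−1 SD
(stability).  The top level's range is [70, 100] on the clipped scale, so
its upper boundary never contributes distance.  Percentages are kept at
full precision and rounded only for display (one decimal for rates, two for
small percentages).

## Latency QC

Summaries report mean, SD, median, quartiles (linear interpolation),
range, a normal-theory 99% CI for the mean (adequate at n ≈ 12,000,
documented as approximate), threshold exceedance counts, and the end-to-end
mean as the sum of the transfer and processing means.  Tail outliers are
strictly above 2000 ms — the truncation point used when plotting such
distributions — and TR exceedance is a separate flag at the TR duration.

## Worked-example fixtures

`nfbloop.fixtures` builds two deterministic tables used by tests and the
acceptance script.  The outcome table fixes per-(participant, run,
modality) success counts whose margins reproduce the emulated study's
group summary: 216/486 successes overall (44.4%), cFB run means
39.5% → 54.3% (Δ +14.8 pp), aFB +3.7 pp, noFB −3.7 pp, one 5-success run
(18.5%) and one 20-success run (74.1%).  The latency fixture has 12,276
volumes — 9 participants × (2 × 602 run TRs + 160 localizer TRs) — with
exactly 44 volumes above 2000 ms (all 7T, 41 from one participant), range
pinned at 164–12,004 ms, and component means pinned at 497.78 and
296.83 ms by an additive adjustment of the free (non-extreme) values, so
the end-to-end mean is 794.61 ms.  These are synthetic reconstructions of
printed summary structure, not participant data.

## Problem sizes

The default test suite runs the full cohort closed loop (9 × 2 × 602 TRs)
in well under a second per replicate; the parameter-recovery check uses 200
cohort replicates and 1000 statistic-level null replicates, and the
localizer type-I check uses 500 null grids of 64 voxels × 80 TRs.  These
sizes give Monte-Carlo error comfortably inside the asserted bands.

## Known limitations

- The behavioural controller is a two-timescale linear set-point model; it
  reproduces the qualitative learning structure but none of the richness of
  real motor strategy adaptation.
- Calibration noise is inherited by all of a participant's feedback values;
  no cross-session or cross-site harmonization is modelled.
- The exact Wilcoxon assumes exchangeability of signs under the null; with
  n = 9 its discreteness makes it conservative, which the type-I check
  verifies but does not correct.
- `run_study` simulates latency logs independently of the feedback stream;
  delayed-volume effects on the display (hold-last-state) are modelled in
  the scoring engine but not coupled to the latency generator.
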