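# Methods

This note documents the models, parameters and design decisions behind
`activecommute`: what the pipeline computes, what the synthetic cohort
generator emulates (and deliberately does not), and the numerical choices a
maintainer would want stated.

## 1. Accelerometer reduction

Counts arrive (or are generated) at epoch level; the pipeline never touches
raw accelerations. All cut-points are expressed in counts per minute (cpm)
and scaled to the epoch by `epoch_s / 60`.

* **Reintegration** sums fine epochs into coarser ones. Output timestamps
  align to target-epoch boundaries from the first input timestamp; a
  trailing partial window is dropped (and logged) rather than emitted as an
  under-count. Total counts over full windows are conserved exactly
  (integer arithmetic throughout).
* **Non-wear** is a maximal run of zero-count epochs lasting ≥ 20 min
  (configurable). The run criterion is *continuous*: a single positive
  count terminates a run and there is no spike-tolerance allowance. Runs
  are detected on the full calendar day **before** windowing, so a run
  straddling 06:00 still counts its whole length toward the threshold.
* **Intensity.** MVPA is counts > 1952 cpm and sedentary is counts
  < 100 cpm, both strict: 1952 cpm itself is light, as is 100 cpm.
  Classification happens at the working epoch length; for streams whose
  counts are uniform within each minute it is invariant to epoch length
  (property-tested).
* **Daily summaries** restrict to [06:00, 24:00) — an epoch belongs to the
  window iff its *start* does — remove non-wear, and compute wear minutes,
  `mean cpm = Σ counts / wear minutes`, and MVPA / sedentary / light
  minutes (which partition wear time exactly). A day is valid with
  ≥ 600 wear minutes; zero wear yields `mean_cpm = NaN` with
  `valid = False`, never a division error. The cpm denominator is wear
  minutes (standard practice; the alternative window-minutes denominator
  would be a one-line change in `_summarise_arrays`). Days are naive local
  calendar dates; Saturday and Sunday are the weekend.

## 2. Journey segmentation

* **Merging.** The accelerometer stream is the spine: every epoch is kept
  and paired with the nearest GPS fix within 5 s of the epoch start, else
  flagged position-missing; fixes that match no epoch are discarded with a
  logged count. Merging is insensitive to input ordering.
* **Segmentation** replaces the manual map-inspection step used in field
  studies with an explicit algorithm: inside each commute window
  (06:00–10:00 and 16:00–20:00 by default), position-bearing epochs are
  split into runs wherever consecutive fixes are > 5 min apart; a run
  yields a journey when it can start inside one 100-m anchor geofence and
  end inside the other. The longest anchor-to-anchor span wins; ties break
  to the earlier start; direction is the starting anchor (never the
  diary — the diary is used only for mode classification). The defaults
  (100 m, 5 min) tolerate urban GPS error and brief signal loss and are
  exposed as configuration, since "near-continuous" has no canonical
  operationalisation. The algorithm is verified equivalent to an
  exhaustive search over all candidate anchor-to-anchor spans.
* **Detours.** A mid-route stationary stop (e.g. a shop) is retained inside
  the journey and flagged when the trace dwells ≥ 3 min within a 30-m
  cluster outside both geofences. A dwell criterion is used instead of an
  instantaneous-speed threshold because 5-m per-fix jitter at 10-s spacing
  makes adjacent-fix speeds indistinguishable from slow walking.
* **Journey summaries**: duration (first to last epoch, inclusive), mean
  cpm over the journey, MVPA minutes by epoch classification — so a
  stationary detour adds duration and dilutes cpm but adds ≈ 0 MVPA.
* **Commute contribution**: per participant, over valid weekdays with at
  least one segmented journey, mean daily journey MVPA over mean daily
  total MVPA. The cohort aggregate is reported both as the ratio of cohort
  means (the headline form, matching how such shares are printed alongside
  their numerator and denominator) and as the mean of per-participant
  ratios.

## 3. Cohort classification

Only diary days with the same non-missing mode both ways are classifiable.
The usual mode is the most frequent classifiable mode; a tie has no
principled winner and maps to mixed/other (logged). The questionnaire
fallback applies only when *zero* diary days are classifiable. Usual
cyclists are excluded because waist-worn devices under-record cycling;
mixed/other is excluded as unanalysable; remaining walkers and drivers need
≥ 1 valid wear day. The flow report partitions the input exactly
(`classified = analysed + Σ exclusions`, asserted at run time).

For the adjusted models, covariates are dichotomised: degree-level
education vs not; income > £30,000 vs ≤ (undisclosed income is treated as
the reference level, a choice the source instruments leave open); sedentary
vs all active occupation classes; full- vs part-time. Reference levels:
male, no degree, ≤ £30k, sedentary, part-time, car.

## 4. Statistics

Group differences use one-way ANOVA (two-group F equals the squared
equal-variance t, property-tested); weekday–weekend contrasts use paired t
on per-participant means; a zero-variance non-zero difference is reported
as (±inf, p = 0) with a warning rather than crashing. Regressions are OLS
on one row per participant (valid-weekday means) — day-level rows would
require clustered errors that the single-wear-time-covariate design does
not contemplate. Rank deficiency raises an error naming the collinear
terms; a model with fewer rows than parameters refuses to fit. Normality is
assumed; p-values are two-sided; no multiple-testing correction is applied.

## 5. The synthetic cohort generator

The generator produces the study conditions the pipeline expects, with
every injected event recorded in a ground-truth sidecar.

* **Background activity.** Each waking minute is sedentary, light or an
  MVPA bout, drawn independently with hour-of-day probabilities derived
  from a target mean-cpm profile `m(h)`:
  `p_MVPA = a_i (m(h) − 40) / 4580`, `p_light = 2 p_MVPA`, where `a_i` is a
  per-participant activity multiplier (sd 0.2) and the constants come from
  the state intensities (sedentary ≈ 40 cpm Poisson, light ≈ 700 cpm,
  bouts ≈ 3300 cpm). Weekday profiles peak near 370 cpm mid-day; weekend
  profiles are flatter and slightly higher, so weekday group differences
  vanish at the weekend. These defaults give car commuters ≈ 360 weekday
  cpm, ≈ 50 MVPA min and ≈ 580 sedentary min on ≈ 750 wear min — the
  magnitudes reported for adult commuter samples.
* **Commutes.** Single-trip durations are truncated normals, 19.7 ± 8.3 min
  on foot and 10.7 ± 7.6 min by car (the reported self-report means);
  departures near 08:15 and 17:05 so journeys sit inside the commute
  windows. Walking epochs draw ≈ 4000 ± 900 cpm (brisk walking), car
  epochs ≈ 150 cpm, cycling ≈ 450 cpm. With probability 0.35 the homeward
  walk includes a 7 ± 2-min stationary sub-sedentary stop at a mid-route
  point — reproducing the observation that longer homeward journeys need
  not add MVPA.
* **Wear.** The device covers a ~07:10–21:40 wake window (counts are zero
  outside it) with ~2.2 injected non-wear runs/day of 15–90 min placed away
  from commutes. Short runs (< 20 min) are deliberately included: they are
  *not* detectable by design and test the boundary.
* **GPS.** Fixes every 10 s along a waypoint polyline between home and the
  route-end work anchor, at the speed implied by the drawn duration, with
  isotropic 5-m Gaussian jitter and 2% fix dropout (first and last fixes
  always kept so every trace touches both anchors); no fixes outside
  commutes, as receivers were worn only for the journey. Routes are gentle
  polylines, not street networks.
* **Diaries and demographics.** Day modes equal the participant's usual
  mode with probability 0.92 (mixed/other participants mix); 2% of entries
  lose a leg to "missing", 2% mismatch legs, 5% of participants return no
  diary (exercising the questionnaire fallback, itself present for 90%).
  Demographics are drawn from the marginal distributions of a typical
  urban employed sample (age 36.3 ± 11.7, 57% female, 80% sedentary
  occupations, ~70% degree-educated).
* **Reproducibility.** One global seed; participant *i* draws from
  `SeedSequence([seed, i+1])`, so cohorts are bit-identical per seed and
  reproducible participant-by-participant. Mode composition uses
  largest-remainder allocation (then a seeded shuffle) so small cohorts
  always contain every requested group.
* **Ground truth** records per day: wake window, non-wear windows, journey
  windows with direction/mode/detour, and injected MVPA minutes — defined
  as generated wear epochs inside 06:00–24:00 exceeding the scaled
  1952-cpm cut-point, computed from the generator's own arrays so recovery
  tests compare two independent code paths.
* **Calibration knobs.** `mode_cpm_effect` adds a Poisson-distributed
  +X cpm to walkers' wear epochs and `include_commutes=False` removes the
  commute windows while keeping diaries intact. Together they create a
  cohort whose true marginal travel-mode effect is *exactly known*
  (+150 cpm in the recovery experiments) — the emergent commute effect of
  an ordinary cohort has no closed-form truth to recover. The calibration
  regression uses the generator's own mode label; diary-based recovery is
  validated separately.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: device-specific count noise and spike artefacts,
urban-canyon GPS multipath (jitter is isotropic Gaussian), street-network
routing, weather/seasonal behaviour, within-week behaviour change,
correlated demographics (covariates are drawn independently of activity,
so the adjusted and unadjusted mode effects coincide in expectation), and
cycling's true waist-count profile.

## 6. Problem sizes and runtimes

The bundled experiments use: 103 participants × 7 days for the pipeline run
(the study's sample size), 100 replicate cohorts of 50 for CI coverage,
1000 random sequences / 100 random days for the brute-force oracle checks.
The full test suite runs in ~4 minutes and `scripts/acceptance.py` in
~3 minutes on one CPU.

## 7. Known limitations

* The 10-minute-bout MVPA accounting used by activity guidelines is out of
  scope; total MVPA minutes only.
* No energy-expenditure (MET/kcal) estimation, no triaxial vector
  magnitude, no imputation of non-wear.
* Journey segmentation assumes home and work geofences do not overlap
  (anchor distance > 2 × radius is enforced) and one journey per
  anchor-to-anchor run.
* Day-level comparisons pool days without clustering by participant,
  matching the simple ANOVA design they mirror; they are descriptive, not
  inferential, under within-person correlation.
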