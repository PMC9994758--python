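# Methods

## Label space

Cotton growth is modelled on an ordered six-stage scale (RE < LD < S <
F < BD < BO).  Field observations may carry a primary and an adjacent
secondary stage; interleaving unit sets with the two orderings of each
adjacent pair yields the 16-level ordinal metaclass scale on which all
ordinal metrics operate.  Constructing a metaclass from a non-adjacent
(primary, secondary) pair raises a validation error; a separate lenient
constructor truncates to the unit metaclass and logs, which is what the
dataset readers use for flagging rather than silently repairing rows.

## Features

* **Vegetation indices.** Eleven standard VIs evaluated exactly as
  printed in the remote-sensing literature (SAVI soil factor 0.428,
  WDRVI α = 0.2, GVMI offsets 0.1/0.02).  Zero-denominator values
  become missing and are gap-filled, not clipped.
* **Growing degree days.** GDD = max(0, (Tmax + Tmin)/2 − 15.6 °C),
  the standard thermal-time definition with cotton's base temperature;
  sub-base days contribute zero rather than negative development.
* **Accumulations.** Weather variables are summed daily and VI series
  integrated by the trapezoidal rule (robust to the irregular ~5-day
  acquisition spacing), both from DoY 100 — around the earliest sowing
  date — to the element's own date, so a feature row never uses future
  data and the same rows serve after-season training and within-season
  prediction.  The eight accumulated weather features are AGDD,
  min/max surface temperature, min/max 0–10 cm soil temperature, daily
  mean soil moisture, precipitation and shortwave radiation; collapsing
  the soil-moisture min/max pair to its daily mean keeps the candidate
  vocabulary at 32 features (11 VIs + 11 integrals + 8 accumulations +
  the DoY pair) while losing essentially no information, as the two
  bounds are nearly collinear at daily resolution.
* **Calendar.** sin/cos of DoY with period 365.25 days; leap-year
  drift is negligible at seasonal scale.  The pair is forced into
  every feature set — it anchors the time frame all other features are
  interpreted against.
* **Gap filling.** Cloud-dropped acquisitions are filled by linear
  interpolation in DoY between defined neighbours, with nearest-value
  extension at the series edges; a field series with fewer than two
  defined points is rejected.  At an interpolated date itself the fill
  uses the next defined acquisition, so strict within-season equality
  of feature rows holds at observed acquisition dates (which is where
  predictions are consumed in practice).
* **Standardization.** Feature columns are z-scored with the training
  season's mean/sd and the same scaler is applied at prediction time.
  Raw scales differ by orders of magnitude (reflectance ratios vs
  degree-day sums), and Euclidean FCM distances would otherwise be
  dominated by whichever feature is largest.

## Clustering model

Standard fuzzy c-means with Euclidean distances, c = 6 (one cluster
per principal stage) and fuzzifier m = 2, the conventional choice that
keeps the partition informative without washing it out.  Fitting uses
5 seeded random-membership restarts keeping the lowest objective,
convergence at max-center-shift < 1e−6 or 300 iterations, and re-seeds
on degenerate coincident-center solutions.  Memberships of new data
are computed against frozen centers; rows always sum to 1, with
zero-distance points assigned full (or evenly split) membership.

**Cluster → stage assignment** uses phenology's arrow of time: per
field, the DoY-ordered argmax-cluster sequence is reduced to its
first-appearance order; the modal order among fields exhibiting all
six clusters maps position 1 → RE through 6 → BO (ties broken
lexicographically for determinism).  If no field exhibits all six
clusters, clusters are ordered by membership-weighted mean DoY and the
results object records that the fallback fired.  Assignment is made on
the training partition; the test season only reuses the frozen map.

**Secondary-label threshold.** Under the two-label protocol, weights
ranked third or lower can never be valid labels, so their upper tail
calibrates the smallest weight worth reporting: `th_w` is the 98th
percentile (linear-interpolation convention) of the 3rd-ranked
training weights.  At prediction time the 2nd-ranked cluster's stage
is emitted as secondary only when its weight strictly exceeds `th_w`
("above" the threshold) *and* it is adjacent to the primary; a
non-adjacent runner-up is suppressed and counted, keeping every output
inside the 16-metaclass scale.  Because rows sum to 1, a 3rd-ranked
weight is at most 1/3, so `th_w` always lies in (0, 0.5).

**Baseline.** The identical pipeline fed only {sin_doy, cos_doy}.
Phenology correlates strongly with the calendar; the baseline measures
that chance agreement, and any genuine model must beat it.

Each test element is predicted independently from features accumulated
to its own date; no temporal smoothing is applied across consecutive
predictions.

## Feature search and ensembling

A two-pass driver mirrors the search design: pass 1 samples random
feature sets per length (every set containing the DoY pair), fits one
model per set on the training season and scores Cohen's kappa and
maxdiff-1 on a field-level 70–30 validation split of the test season
(field-level, so acquisitions of one field never straddle the split);
the top 1 % by kappa (ties: maxdiff-1, then names) define the most
frequent features; pass 2 sweeps combinations of those, filters by
strict kappa/maxdiff-1 cut-offs, and the surviving models predict by
majority vote (count ties broken by summed top-rank weight, then lower
metaclass index).  Desk-scale defaults — 200 combinations per length
over a reduced pool — keep a full run in the minutes range; the scope
of each pass is plain configuration, and the default single-model
feature set shipped with the package was itself frozen from this
search run on independent simulated season pairs.

## Evaluation

* maxdiff-*o*: fraction of predictions displaced ≤ *o* on the
  16-level scale, *o* ∈ {0..3}; larger displacements bin into diff-3+.
* Cohen's kappa and linear/quadratic weighted variants, computed on
  the metaclass indices (the only ordinal scale defined; computing on
  6 principal stages instead is a documented alternative reading).
  Degenerate single-class data returns NaN with a warning.
* NDCG@2 with relevance 2 for the true primary and 1 for the true
  secondary; the ideal DCG is 2 + 1/log₂3 when a secondary exists and
  2 otherwise.
* Per-metaclass displacement: the row-normalized confusion row times
  |i − j| weights, reported for truth classes with ≥ 10 observations
  (configurable), plus a support-weighted average.
* 6×6 principal-stage confusion matrix and trace accuracy.
* Chronological order of observation: within each field's run of
  consecutive same-stage visits, runs of 3–5 mark first/last as
  early/late, runs of ≥ 6 mark the first and last two; 1–2 visit runs
  are labelled degenerately (single visit → early) and are outside the
  3–6 range the protocol anticipates.

## Synthetic seasons

The generator emulates the study conditions end to end:

* **Schedules.** Sowing uniform on DoY 105–135; stage durations
  uniform within RE 15–30, LD 35–45, S 15–30, F 20–40, BD 25–45,
  BO 10–20 days, scaled by a field thermal factor (warm fields develop
  faster) and resampled until the cycle totals 150–200 days.
* **Weather.** Sinusoidal annual air-temperature cycle of
  Mediterranean amplitude plus AR(1) noise (sd 1.5 °C) and a field
  offset; surface/soil temperatures as damped, lagged transforms;
  solstice-peaked radiation; sparse exponential rainfall feeding a
  decaying soil-moisture reservoir.
* **Bands.** A double-logistic canopy curve (green-up keyed to the LD
  onset, senescence to the BO onset) drives NIR up and red down, with
  a maturity ramp so NIR peaks during flowering/boll development, as
  canopy does in the field.  Each reproductive phase adds its own
  spectral regime: visible bands brighten slightly under flowers and
  strongly under open bolls; SWIR follows canopy water content, which
  builds from squaring to its minimum reflectance in boll development.
  B06 (red-edge) is a red/NIR blend — a modelling convenience, not a
  radiative-transfer claim.  Gaussian noise (sd 0.015, a realistic
  field-mean reflectance error) and 10 % cloud-dropped acquisitions on
  a 5-day grid over DoY 100–300 complete the series.
* **Visits.** Every 10 days across the season.  Within ±7 days of a
  stage onset both stages are present: the secondary's prevalence
  ramps linearly from 0 at the band edges to 100 at the onset (where
  the later stage takes over as primary), and it is reported from 5 %
  prevalence.  With these defaults ~40 % of visits carry a secondary
  label.

What the simulator does **not** reproduce: radiative-transfer-grade
spectra, pest/stress anomalies, variety differences, spatially
correlated cloud fields, or annotator disagreement — ground truth is
exact by construction.  Passing recovery tests therefore demonstrate
that the pipeline identifies stage structure when the assumed
signal-generating mechanisms hold, not field-proven accuracy on real
imagery.

## Numerical choices and degenerate inputs

Percentiles use NumPy's linear interpolation between order statistics.
Exact weight ties in the ranking break by cluster index; modal-order
ties break lexicographically; vote ties as described above.  Constant
feature columns are centred but left unscaled.  Model JSON
serialization round-trips bit-exactly (verified in tests).  All file
interfaces carry a schema version and readers reject newer majors.

## Problem sizes

Recovery studies use 40 training + 40 test fields (~1 640 elements per
season at 41 acquisition dates), five independent season pairs, 5 FCM
restarts — a deliberate desk-scale design: one pair fits in a few
seconds, the full five-seed study in well under a minute, and results
at this size are stable across seeds.  Search runs default to hundreds
of candidate sets per pass for the same reason.

## Known limitations

Cluster boundaries are where FCM puts them: with features that largely
track elapsed time, cluster sizes tend toward balance while true stage
durations are unequal, so primary-stage errors concentrate near stage
onsets (exactly where two-label truth is fuzzy anyway).  The default
feature set mitigates this by mixing development-clock features (AGDD,
VI integrals) with stage-specific spectral features, but maxdiff-0
remains the weakest metric — consistent with the method's character as
an unsupervised, ordinal-scale estimator rather than a per-date
classifier.
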