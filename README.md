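# phenofcm

Unsupervised, **within-season estimation of cotton phenology** from
Sentinel-2 imagery and daily weather, for remote-sensing and
agricultural-monitoring practitioners who need field-level growth-stage
information without per-season ground-truth labels.

## The problem and the method

Cotton development is discretised into six ordered principal stages —
root establishment (RE), leaf development (LD), squaring (S), flowering
(F), boll development (BD) and boll opening (BO).  A field in
transition carries **two ranked labels** (a prevailing *primary* and an
adjacent *secondary* stage); each one- or two-label state is a
*metaclass*, and the 16 admissible metaclasses

λ₁, (λ₁,λ₂), (λ₂,λ₁), λ₂, (λ₂,λ₃), …, (λ₆,λ₅), λ₆

form an ordinal scale of their own, on which prediction error is
measured as index displacement.

The estimator is **fuzzy c-means (FCM)** with c = 6 clusters and
fuzzifier m = 2 over an element space `X ∈ R^{K×E}`: one row per field
per acquisition date, with features drawn from a 32-name vocabulary —
11 vegetation indices (NDVI, NDWI, NDMI, PSRI, SAVI, EVI, VARIgreen,
GARI, SIPI, WDRVI, GVMI) from field-mean reflectances, their 11
cumulative trapezoidal integrals from DoY 100, 8 accumulated
weather/soil variables including accumulated growing degree days
(AGDD, base 15.6 °C), and the sine/cosine DoY encoding.  After fitting
on a reference season, clusters are matched to stages by their **time
order** (modal first-appearance order of argmax clusters across
fields), and the membership weights `w_{k,l}` become a label ranking:
the top cluster's stage is the primary label, and the runner-up becomes
a secondary label when its weight exceeds the threshold `th_w` — the
98th percentile of 3rd-ranked training weights — and is stage-adjacent.
A new season is then scored *within-season*: each date uses only data
accumulated up to that date.

Evaluation covers maxdiff-*o* accuracy (displacement ≤ *o*), Cohen's
kappa with linear/quadratic weights on the 16-level scale, NDCG@2 with
relevance 2/1 for the true primary/secondary stage, per-metaclass mean
displacement, and the 6×6 principal-stage confusion matrix.  A
built-in simulator generates full seasons (stage schedules from
agronomic duration ranges, weather, stage-keyed reflectance
trajectories with noise and cloud gaps, and two-label field visits) so
the whole pipeline is testable end-to-end against known truth.

## Worked example

```python
from phenofcm import SimConfig, fit_and_evaluate, simulate_train_test

train, test = simulate_train_test(SimConfig(n_fields=40, seed=0))
out = fit_and_evaluate(train, test, seed=0)
print(out["results"].summary())
rep = out["report"]
print(f"maxdiff-0 = {rep.maxdiff[0]:.2f}   maxdiff-1 = {rep.maxdiff[1]:.2f}")
print(f"NDCG@2 = {rep.ndcg_at_2:.2f}   principal-stage accuracy = {rep.principal_accuracy:.2f}")
```

prints

```
Phenology FCM results
======================================================
clusters:            6
fuzzifier m:         2
features (10):       sin_doy, cos_doy, I_GVMI, I_NDMI, NDMI, VARIgreen, WDRVI, acc_gdd, acc_tsoil_max, acc_tsurf_min
threshold th_w:      0.1369
seed:                0
stage order fallback: no
------------------------------------------------------
cluster -> stage map (by time order):
  cluster 0 -> BO
  cluster 1 -> RE
  cluster 2 -> BD
  cluster 3 -> LD
  cluster 4 -> F
  cluster 5 -> S
------------------------------------------------------
training elements K: 1640

maxdiff-0 = 0.45   maxdiff-1 = 0.85
NDCG@2 = 0.93   principal-stage accuracy = 0.77
```

Reading the numbers: 45 % of test-season field-dates get the exact
metaclass, 85 % land within one position on the 16-level scale, the
ranked stages almost always place the true primary first (NDCG@2 0.93),
and 77 % of primary-stage calls are exact.  The same run's DoY-only
baseline — the identical pipeline fed nothing but the acquisition
calendar — reaches maxdiff-0 0.27, so the imagery and thermal-time
features carry real signal beyond the calendar.

A command-line interface mirrors the library:

```sh
phenofcm simulate --config sim.yaml --out-dir data/
phenofcm fit --train-bands data/bands.csv --train-weather data/weather.csv \
             --features default --seed 0 --out model.json
phenofcm predict --model model.json --bands data/bands.csv \
                 --weather data/weather.csv --out predictions.csv
phenofcm evaluate --pred predictions.csv --truth data/observations.csv \
                  --out report.json
```

`phenofcm search-features` runs the random feature-set search with
validation-split scoring; `phenofcm.selection` adds top-percent
selection, frequency-based feature ranking, metric filtering and
majority-vote ensembling over many fitted models.

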