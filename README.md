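# roamcount

Abundance estimation for free-roaming dogs from road-based sight surveys —
the population denominator that rabies vaccination campaigns need to judge
their coverage.

Two estimation arms are implemented and compared:

* **Chapman mark-resight.** After a vaccination round paint-marks `n1` dogs
  in a working zone, a follow-up drive-through sights `n2` dogs of which `m`
  carry marks. The bias-corrected Lincoln–Petersen (Chapman) estimator is

  `N̂ = (n1 + 1)(n2 + 1)/(m + 1) − 1`

  with Seber variance
  `var(N̂) = (n1+1)(n2+1)(n1−m)(n2−m) / [(m+1)²(m+2)]`,
  Wald confidence intervals, and study totals formed by summing zone
  estimates and variances.

* **Binned line-transect distance sampling.** Perpendicular sighting
  distances from the transect (the road) are grouped into 5 m bins centred
  on multiples of five — surveyor estimates heap on those values — and
  truncated at `w = 37.5` m. A detection function `g(x)` (uniform,
  half-normal or hazard-rate key, with optional cosine / simple-polynomial /
  Hermite adjustment series, `g(0) = 1`) is fitted by maximising the grouped
  multinomial likelihood; candidates are screened by a χ² goodness-of-fit
  test and a shape check, then selected by AIC. Density follows from the
  effective strip half-width `μ = ∫₀ʷ g(x)dx` as `D̂ = n/(2μL)`, abundance as
  `N̂ = D̂·A` over the area within 100 m of the roads, with a log-normal CI
  combining encounter-rate and detection variance.

Agreement between the arms is summarised with Lin's concordance correlation
coefficient, Pearson's r, and Bland–Altman mean differences with limits of
agreement.

A synthetic road-survey simulator (`synthetic_survey`) generates datasets
with the statistical structure both estimators assume — Poisson dog
placement in an unrolled 100 m road buffer, independent paint-marking,
distance-decaying detection, 5 m distance heaping, all-roads vs subset
routes, two repeat survey days — so every stage is testable end to end
against known truth.

## Worked example

Simulate a 26-zone study with the calibrated defaults (242 dogs/km² true
density, 100.91 km of road, 45% marking coverage, half-normal detection with
σ = 10 m) and run both arms plus the comparison:

```
$ roamcount full-study --out-dir demo --seed 1
{
  "chapman_total_day1_all_roads": {
    "estimate": 4272.38106174871,
    "ci": [3961.7737959964675, 4582.988327500952]
  },
  ...
  "distance_day1_all_roads": {
    "model": "half_normal",
    "density_per_km2": 236.40357305119454,
    "abundance": 4771.096911319209,
    "abundance_ci": [4413.947492963413, 5157.144658718388]
  },
  ...
}
```

The simulated truth for this seed is 4885 dogs (`demo/truth.csv`). The
mark-resight arm totals 4272 dogs (95% CI 3962–4583) and the distance arm
4771 dogs (95% CI 4414–5157) at a fitted density of 236 dogs/km² — the two
study-scale intervals overlap, while the per-zone comparison
(`demo/comparison.csv`) shows the much weaker zone-level concordance (CCC
≈ 0.25 for this seed) expected when each zone's estimate rests on ~23
sighted dogs.

Individual stages are available as `roamcount simulate`, `roamcount
chapman`, `roamcount distance` and `roamcount compare`, all exchanging a
flat sightings CSV; the same functionality is importable from the
`roamcount` package (`run_scenario`, `chapman_zone`, `select_model`,
`estimate_density`, `compare_methods`, ...).

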