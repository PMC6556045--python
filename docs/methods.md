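# Methods

## Problem and data model

A vaccination team works through a set of disjoint *working zones*. In each
zone, a marking round vaccinates and paint-marks `n1` dogs; subsequent
drive-through surveys record every dog sighted (mark status, estimated
perpendicular distance from the road). Each zone is surveyed four times:
along all roads and along a subset of roads, each repeated the following
day. The quantity of interest is the free-roaming dog abundance in the area
within 100 m of the road network — the band where these dogs concentrate and
where a street survey can see them.

The interchange format is a single sightings CSV (one row per sighted dog,
zone metadata repeated per row; a metadata-only row represents a surveyed
zone with zero sightings). Booleans are written `true`/`false`; distances
are metres.

## Chapman mark-resight

For counts `(n1, n2, m)` per zone survey,

    N̂ = (n1+1)(n2+1)/(m+1) − 1,
    var(N̂) = (n1+1)(n2+1)(n1−m)(n2−m) / [(m+1)²(m+2)].

Assumptions: closed population between marking and resighting, no mark loss,
equal sightability of marked and unmarked dogs. The estimator is exactly
unbiased when `n1 + n2 ≥ N` and nearly unbiased otherwise; the test suite
verifies this by exhaustive hypergeometric enumeration at small `N`.

Design choices where the method leaves room:

* **CI construction.** Wald-normal on `N̂` with the Seber variance, floored
  at zero. No lower floor at `max(n1, n2)` is imposed. Wald is the most
  common companion to Chapman; the package documents rather than guesses any
  alternative.
* **Study totals.** Zone estimates and variances are summed (zones are
  disjoint areas, treated as independent); the total CI is normal on the
  sum. Day averages use `var = (var₁+var₂)/4`.
* **`m > n1`** (possible through double counting of dogs that move during a
  survey) is accepted by the formula with a logged warning, not an error.
  `m ≤ n2` is enforced.
* **Degenerate case `n2 = 0`.** The estimate collapses to `n1` and the Seber
  variance to 0 (the `(n2−m)` factor vanishes). The zero variance is
  reported as-is; it should be read as "no usable uncertainty statement",
  not as certainty.

## Binned distance sampling

Recorded distances heap on multiples of 5 m, so the analysis is grouped from
the start: bins of width 5 m centred on multiples of five — cutpoints
`0, 2.5, 7.5, …, 37.5` with a half-width first bin centred on the transect —
half-open `[lo, hi)`, truncated at `w = 37.5` m. Because heaped values land
on bin centres, rounding to the nearest 5 m (or nearest metre) never moves a
sighting across a bin edge: the binned likelihood is exactly invariant to
the heaping process the simulator generates.

Detection function families:

* keys: uniform `1`, half-normal `exp(−x²/2σ²)`, hazard-rate
  `1 − exp(−(x/σ)^−b)` with `b > 1`;
* adjustment series `1 + Σⱼ aⱼ·basisⱼ(x/w)` with cosine `cos(jπx/w)`,
  simple polynomial `(x/w)^j`, or probabilists' Hermite `He_j(x/w)` bases,
  all scaled by the truncation distance; the product is renormalised by its
  value at 0 so `g(0) = 1`. Default orders: cosine (2, 3) for the
  half-normal key, (2) otherwise; polynomials (4, 6).

Fitting maximises the multinomial log-likelihood `Σ nᵢ log πᵢ`,
`πᵢ = ∫_binᵢ g / μ`, with bin integrals by fixed 16-point Gauss–Legendre
quadrature per bin (g is smooth; the πᵢ sum to 1 by construction and agree
with adaptive quadrature to 1e−8, which a test asserts). Free parameters are
optimised unconstrained (log σ, log(b−1), raw aⱼ) by L-BFGS-B from 5 starts
on a log-σ grid spanning 0.1w–2w; the best finite-likelihood solution wins.
The public `effective_strip_width` uses adaptive quadrature at 1e−8 m
absolute tolerance.

Model selection mirrors the conventional workflow mechanically: candidates
whose χ² goodness of fit rejects at α = 0.05 (tail bins pooled until every
expected count ≥ 5; df = bins − 1 − K, reported as undefined when ≤ 0) or
whose fitted shape leaves (0, 1] on a 1000-point grid are screened out — the
shape check is the mechanical analogue of visually inspecting the fitted
curve; if every candidate fails, all are retained with a warning. The
minimum-AIC fit is returned, ties broken by fewer parameters, then candidate
order. A fit whose adjustment terms push the ESW above `w` is rejected as
implausible at the fitting stage.

Density and abundance: `D̂ = n/(2μL)` pooled over the zones of one
(day, route) stratum; abundance `N̂ = D̂·A` with `A` the summed buffer areas.
`cv²(D̂)` adds the between-zone encounter-rate variance
`var(n) = L Σ lᵢ(nᵢ/lᵢ − n/L)²/(k−1)` (Poisson fallback `var(n) = n` with a
warning when only one transect exists) and the delta-method CV of `μ` from
the observed information at the MLE. The CI is log-normal,
`D̂·exp(±1.96√log(1+cv²))`. Per-zone abundances for the method comparison
reuse the pooled `μ`: `N̂ᵢ = nᵢAᵢ/(2μlᵢ)`. Pooling detection across zones
while stratifying the encounter rate is a deliberate choice: per-zone
samples (~23 dogs) are far too small to support zone-level detection fits.

## Agreement statistics

Lin's CCC uses population (n-denominator) moments,
`ccc = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²)`, per Lin's original definition;
Pearson's r uses the usual sample convention (the ratio is
denominator-invariant). CCC CIs are Fisher-z with Lin's asymptotic standard
error (the 2000-corrected form); Pearson CIs are Fisher-z with
`SE = 1/√(n−3)`; mean differences get paired-t CIs; Bland–Altman limits are
`d̄ ± 1.96·SD(d)` with the n−1 SD. The comparison battery reports (i)
Chapman vs distance-method abundance on all-roads surveys and (ii) all-roads
vs subset for each method's abundance, the marked proportion and the count
of dogs — for a single selectable survey day (default day 1), since pooling
days would double-count zones. CCC is omitted with a warning below 3 pairs.

## Synthetic survey generator

Geometry is an "unrolled strip": each zone's road network becomes one
straight transect of length `L` with a rectangular buffer of half-width
100 m per side, `A = 2·100·L`. This discards real road topology but
preserves everything the estimators consume — lateral distance
distribution, line length, area — which is exactly the role the GIS step
plays for field data.

Generative process per zone: `N ~ Poisson(D_true·A)`; positions uniform
along the road and uniform in lateral distance (an optional
truncated-exponential lateral decay is available as a road-attraction bias
experiment, off by default); marks i.i.d. Bernoulli(`p_mark`); each survey
detects each exposed dog independently with probability `g(lateral)` under
the true detection function, times an optional day-2 multiplier; subset
routes expose the first `subset_fraction` of the road and report the scaled
line length but the full zone buffer area (both arms extrapolate to the
whole zone); recorded distances are rounded to the nearest 5 m with
probability `heaping_prob` (default 0.5, echoing the heaping seen in field
distance histograms), else to the nearest metre; an `emigration_prob` can
knock dogs out per survey to break closure deliberately.

Calibrated defaults reproduce a 26-zone study design: 100.91 km of road
(equal shares per zone), subset fraction 47.20/100.91, true density
242 dogs/km², `p_mark = 0.45`, half-normal truth with σ = 10 m. With a
100 m buffer the expected sighting fraction is `σ√(π/2)/100 ≈ 0.125`, giving
≈ 23 sighted dogs per all-roads zone survey and a marked proportion of
0.45 — matching the survey summary the design emulates. Two days × two
routes × 26 zones = 104 survey groups.

Reproducibility: each zone consumes one RNG stream spawned from the master
seed (`SeedSequence.spawn`), so zone `i` is bit-identical regardless of how
many zones a scenario has; a fixed seed reproduces the output CSV byte for
byte.

What the simulator does **not** model — and hence what passing recovery
tests do not establish about field data: real road-network geometry and
non-uniform dog placement along roads, correlated detection across days,
double counting within a survey, group (cluster) sizes, surveyor
differences, and owned-dog/household structure. The recovery tests show the
estimators are correct under their own assumptions, not that field surveys
satisfy those assumptions.

## Problem sizes in the test suite

Simulation-backed tests use sizes chosen to give comfortable Monte-Carlo
margins at desk scale: 300 replicates at ~500 pooled detections for
parameter recovery and CI coverage (mean σ̂ and D̂ within 5%, coverage
90–98%), 200 replicates at n = 5000 for AIC family selection, 100 replicates
of the full 26-zone study for the study-scale CI-overlap check, and
exhaustive enumeration (not simulation) for Chapman unbiasedness. The whole
suite runs in well under a minute on one CPU.

## Known limitations

* The hazard-rate family is covariate-free; covariate detection functions
  and cluster-size estimation are out of scope.
* Continuous (unbinned) likelihoods are not implemented — with 5 m heaping
  the grouped likelihood is the honest choice.
* The Wald/summed-variance CI for Chapman totals and the log-normal CI for
  density are asymptotic; no bootstrap alternatives are provided.
* `DetectionFit.esw_cv` is 0 for the parameter-free uniform key, so a
  uniform-key density CI reflects encounter-rate variance only.
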