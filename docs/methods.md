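# Methods

This note records the models, the synthetic study conditions, the numerical
choices, and the known limits of what the tests demonstrate.

## Quality control

Daily station series pass through four steps in fixed order: physical-range
screening (values below 0 or above 1000 µg/m³ become missing; the
boundaries themselves are retained — the rule is a strict inequality),
sliding-window outlier detection, outlier replacement, and gap filling.

A point is an outlier when it deviates from its 15-day centred window mean
by more than 3 window SDs **and** lies outside the station's global
0.1/99.9 percentile band. The AND combination makes the percentile review a
confirmation step, which suppresses false positives on noisy winter peaks;
an OR variant is available (`combine="or"`). The candidate is excluded from
its own window statistics so a large spike cannot inflate the SD that
judges it; windows shrink at the series edges rather than dropping them,
and a point with fewer than three valid neighbours is not evaluable.
Detected outliers and interior missing runs of at most 15 days are linearly
interpolated; longer runs and runs touching a series edge stay missing.
Flags record each day's final disposition (a range-excluded day later
bridged by interpolation is reported as gap-filled), so flag counts always
sum to the series length. Windows are centred and percentiles are
per-station; both choices are conventions where the protocol is silent.

One caveat on the outlier rule: because the percentile band is estimated
from the series itself, simultaneous spikes occupying more than ~0.1% of a
short series raise the band and mask one another. This is a property of
the published rule, not of the implementation.

## Estimation model

The target is daily station PM2.5 from six meteorological covariates plus
three time terms standing in for emissions: the normalized seasonal
coefficient (NSC — monthly mean over station mean, so its
observation-count-weighted mean is exactly 1), day of week, and unix time.

Three architectures share one forest configuration:

- **GWRF**: one ensemble per anchor location, trained with sample weights
  `exp(-½ (d/b)²)` of the great-circle distance d (haversine) to the
  anchor. Predictions use the nearest anchor's ensemble. Anchors default to
  the station locations; a coarse grid is used for national-scale fits.
  Samples with weight below 0.01 are dropped from an anchor's training set
  (they cannot influence it materially, and pruning bounds cost); anchors
  left with fewer than 50 samples are dropped with a warning.
- **Holistic**: one pooled forest.
- **Pointwise**: one forest per station (≥30 samples, else the station is
  skipped and served by the nearest fitted station).

Weights enter tree construction raw; rescaling all weights by a constant
provably changes nothing, which the tests assert. Bandwidth is chosen by
K-fold CV (default 5) minimising mean RMSE, ties broken toward the larger,
smoother bandwidth. The 70/10/20 train/validation/test split is random by
record; forests need no early stopping, so the validation share is only
used for sanity metrics — a deliberate simplification.

Forests use 500 trees by default (100 in desk-scale runs), nodesize
(`min_samples_leaf`) 5, and consider **all** features at every split.
The last choice matters more than usual: under feature subsampling the
collinear meteorological variables routinely stand in for the time terms,
and the resampling step of deweathering then strips genuine emission
structure along with the weather. With full feature consideration the
greedy splitter keeps emission structure on the time terms whenever they
explain it better. The three-way architecture comparison passes
`max_features=1/3` (the classic regression-forest mtry) to all three models
alike, purely to keep that 100k-row fit tractable.

## Deweathering

For each observation the three time terms are frozen and the six met
covariates are replaced by draws (uniform, with replacement) from the pool
of all complete met records of all stations and days; the model predicts
each variant, and PM_dw is the mean over `n_resample = 1000` draws (100 in
desk-scale configurations, with correspondingly wider Monte-Carlo error).
`mc_se = SD/√n` quantifies the resampling error and shrinks as n^-1/2,
which is asserted across n ∈ {10, 100, 1000}.

The draw stream is keyed by (seed, station, date), so deweathered values do
not depend on processing order, and all observations share one pool — that
shared meteorological context is what makes PM_dw comparable across
stations and years.

The per-day meteorological contribution is `(PM_raw − PM_dw)/PM_dw`;
negative values mean the actual weather dispersed pollution below
average-met conditions. The deweathered denominator keeps the metric
consistent with the inequality attribution below; `denominator="raw"` is
available.

Two structural biases of forest-based deweathering surfaced during
validation and are worth knowing about. First, a *slow monotone* drift in a
meteorological variable is partially absorbed by the unix-time term (both
explain the same low-frequency variance), so deweathering removes only part
of such a drift. Second, the forest's time response is mildly shrunk toward
the mean near the edges of the observed span (bootstrap leaf averaging),
which flattens fitted trends by a few percent. Both effects shrink with
more stations and full-feature splits; the trend-recovery test quantifies
the net effect.

## Synthetic study conditions

The generator is the package's definition of "data like the method
expects", not a tuning dial:

- **Stations** from a two-component Gaussian mixture (weights 0.7/0.3) over
  a national-scale bounding box — dense east, sparse west. County centroids
  are uniform; provinces are longitude-contiguous county groups.
- **Meteorology**: per variable, mean + smooth spatial offset + winter-
  phased seasonal cosine + stationary AR(1) noise (lag-1 coefficient 0.7 by
  default), variables mutually independent — a documented simplification.
  30% of innovation variance is shared across stations (synoptic-scale
  coherence). Humidity is clipped to [0, 100]%, boundary-layer height
  floored at 50 m. Optional per-variable linear drifts emulate interannual
  change.
- **Emissions**: `base_i · (1+trend)^years · season(t) · weekday(t)` with a
  winter peak, weekday factor elevated Monday–Friday with zero weekly mean,
  and smooth lognormal station baselines (log-SD 0.25).
- **Met response**: linear in the six anomalies (relative to station
  climatology), with dispersion-physics signs (deeper boundary layer,
  stronger wind → lower PM; humidity → higher). Modes: zero, smooth
  spatial variation (Gaussian-kernel random field, correlation length
  800 km), or a hard sign flip across the median longitude.
- **PM**: emission + response·anomaly + Gaussian noise, floored at
  0.1 µg/m³. Default noise 6 µg/m³ daily.
- **Populations**: county totals lognormal; each stratification axis
  (occupation, age, gender, education, residence, origin) partitions every
  county's total exactly via largest-remainder apportionment of
  Dirichlet-jittered shares. GDP per capita is lognormal and can be
  rank-coupled to county exposure so income-quartile analyses are
  non-degenerate.
- **Network build-out**: optionally, only a backbone fraction of stations
  reports from day one and the rest activate at uniform random dates —
  real monitoring networks grow, and record-length heterogeneity is what
  actually separates per-station from pooled models.

Frozen evaluation scenarios (in `pmdecode.pipeline`):

- *Model comparison*: 200 stations / 50 counties / 2 years daily, sign-flip
  response, noise 14 µg/m³ (the daily residual scale of national networks),
  10% backbone with activation throughout the span; 5×3 anchor grid,
  bandwidth 500 km, 100 trees. Under these conditions GWRF < holistic <
  pointwise in test RMSE.
- *Trend recovery*: 40 stations / 3 years, emission −30% over the period
  (−11.2%/yr), smooth response at scale 0.8, noise 5, seasonal amplitude
  0.25, plus an unfavourable met drift (blh −150 m/yr, t2m −1 K/yr) that
  masks part of the decline in the raw series. The deweathered trend lands
  within 20% of truth and closer than the raw trend, and SD(PM_dw) <
  SD(PM_raw).

## Kriging and exposure

Annual station means (raw and deweathered separately) — not daily fields —
are kriged to county centroids: the exposure and inequality results are
annual, and daily kriging would multiply cost ~365× with no analytic gain.
The variogram is exponential (`spherical` available), fitted to binned
empirical semivariances by pair-count-weighted least squares; a constant
field degenerates to pure nugget with a warning. Ordinary kriging solves
the standard bordered system; weights sum to 1 (asserted to 1e-10), the
predictor is exact at station locations, duplicate coordinates are averaged
first, and negative estimates are floored at zero. County concentration is
the centroid value, not an areal average — centroid tables are the only
geometry the package requires.

Group exposure weights county concentrations by the group's county
populations. Income groups L1–L4 are rank quartiles of province-level GDP
per capita (L1 = top 25%), ties broken by stable original order.

## Inequality

Analysis cells are county × group-label combinations weighted by cell
population. Note a structural consequence: because every group in a county
shares the county's concentration, the *total* cell-level Gini is
mathematically identical across stratification axes; axes differentiate
through the Theil group contributions (groups concentrate in different
counties) and through group-level exposure summaries. Gini uses the
weighted pairwise-difference formula, cross-checked against 1 − 2×(Lorenz
area) to 1e-9. Theil-T (not Theil-L) is used because it decomposes exactly
into between + within, which is what a per-group "contribution to
inequality" requires; a group's contribution is its between-group term plus
its weighted within-group term, reported as a share of the total.

The meteorological inequality effect is `100·(G_dw − G_raw)/G_dw`. The
formula was fixed by checking it against both published worked pairs —
(0.018, 0.032) → 43.75 ≈ 43.7% and (0.021, 0.022) → 4.55 ≈ 4.5% — and is
the only denominator convention consistent with both. Report rounding: 3
decimals for Gini, 1 for percentages.

## Pipeline and reproducibility

All randomness descends from one seed through named per-stage substreams
(`numpy.random.SeedSequence.spawn`). Every stage writes plain CSV/JSON with
SHA-256 digests into `manifest.json`; a completed stage with intact outputs
is skipped on rerun, and a full rerun with the same configuration is
byte-identical. The demonstration configuration (20 stations, 10 counties,
2 years, 100 trees, 100 resamples) runs in roughly a minute on one CPU;
test and script problem sizes throughout were chosen so the whole suite
runs at desk scale.

## What passing tests do and do not show

The generator exercises the statistical structure the method assumes —
spatial heterogeneity, met confounding, seasonal collinearity, stratified
populations — but not real-data pathologies: instrument drift and
calibration changes, cross-variable met covariance, terrain effects,
population mobility, or reporting artifacts. Quantities tied to real
inputs (absolute exposure levels, specific group rankings, reduction
percentages by province) are outside what synthetic validation can
establish; the tests establish correctness of the *mathematics* and
recovery of *known* structure under controlled conditions.

Known limitations: the met-free identity (`met_response=0`, zero noise)
holds up to the forest's interpolation floor (~2% of the mean here) rather
than exactly — any bootstrap-averaged tree model reproduces observations
only approximately, and the residual is unrelated to meteorology (the mean
met contribution is ~3·10⁻⁴). Monotone met drifts are only partially
removable in the presence of a unix-time feature (see Deweathering).
Cell-level Gini's axis-invariance (above) means occupation-specific
inequality statements rest on the Theil contributions, not on the total.
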