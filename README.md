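# pmdecode

Separating what emissions did from what the weather did to PM2.5 exposure —
and asking who carries the burden.

Long-term PM2.5 trends confound two signals: changes in emissions and the
year-to-year vagaries of meteorology (boundary-layer depth, wind, humidity,
temperature, pressure). `pmdecode` implements a full analysis chain that

1. quality-controls daily station PM2.5 series,
2. fits a **geographically weighted random forest (GWRF)**
   `PM2.5 = f(msl, rh, t2m, u10, v10, blh, NSC, day-of-week, unix-time)`,
   one distance-weighted ensemble per anchor location with Gaussian kernel
   weights `w = exp(-½ (d/b)²)` and CV-selected bandwidth `b`,
3. **deweathers** each observation: time terms are held fixed while the six
   meteorological covariates are resampled from a national pool; the mean
   of the resampled predictions is PM_dw, the concentration expected under
   average meteorological conditions,
4. interpolates annual station means (raw and deweathered) to county
   centroids by **ordinary kriging** under a fitted exponential variogram,
5. computes **population-weighted exposure** per socio-economic group,
   `PWE = Σᵢ Cᵢ Pᵢ / Σᵢ Pᵢ`, across counties i, and
6. quantifies **exposure inequality** — Lorenz curves, population-weighted
   Gini `G = Σᵢⱼ wᵢwⱼ|xᵢ−xⱼ| / (2W²x̄)`, Theil-T with exact
   between/within-group decomposition — and attributes meteorology's role
   in inequality as `100·(G_dw − G_raw)/G_dw` (positive: actual weather
   mitigated the inequality that emissions alone would have produced).

Because the real inputs (national monitoring networks, reanalysis
meteorology, census tables) are large and access-controlled, the package
ships a first-class **synthetic-data generator** that reproduces the
statistical structure the method needs — clustered station networks,
seasonal AR(1) meteorology with synoptic-scale coherence, multiplicative
emission signals (trend × season × weekday), spatially varying linear met
responses, and stratified county populations — with known ground truth, so
every stage is testable end to end.

Audience: air-quality and environmental-justice researchers who want a
reproducible, inspectable implementation of weather normalization plus
exposure-inequality accounting.

## Worked example

```python
from pmdecode import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, n_stations=20, n_counties=10, n_years=2,
                     n_trees=100, n_resample=100)
manifest = run_pipeline(cfg, "out/")
print(manifest["summary"])
```

prints (abridged):

```json
{
  "model_metrics": {
    "bandwidth_km": 800.0,
    "gwrf": {"r2": 0.905, "rmse": 7.58, "mape": 21.4, "mae": 5.91, "r": 0.951}
  },
  "national_pwe_dw_start": 56.08,
  "national_pwe_dw_end": 52.68,
  "national_reduction_pct": 6.06,
  "inequality": [
    {"axis": "occupation", "year": 2013,
     "gini_raw": 0.067, "gini_dw": 0.034, "met_effect_pct": -95.9}
  ]
}
```

Reading the numbers: the forest explains 90% of daily PM2.5 variance
(RMSE 7.6 µg/m³, Pearson r 0.95) on held-out data. Population-weighted
deweathered exposure fell from 56.1 to 52.7 µg/m³ over the two simulated
years — a 6.1% reduction, which matches the configured −8%/yr emission
trend over one year-to-year step better than the weather-confounded raw
series does. In 2013 the raw exposure Gini (0.067) exceeds the deweathered
Gini (0.034): in this synthetic world meteorological variability *adds*
spatial inequality on top of the emission field, so the met effect is
negative (−95.9% of the deweathered Gini). The same machinery applied to
the published 2013 occupational Gini pair (0.018 raw vs 0.032 deweathered)
gives +43.7% — weather there *masked* inequality instead.

The same stages are scriptable from the shell:

```bash
pmdecode run --config cfg.yaml --seed 7 --out out/
pmdecode synthdata --seed 3 --out data/       # generator only
pmdecode qc --pm data/pm.csv --out data/pm_qc.csv
pmdecode describe --out out/                  # fitted-model summary
```

Every run writes `manifest.json` with SHA-256 digests of all artifacts;
rerunning with the same config and seed reproduces them byte for byte.

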