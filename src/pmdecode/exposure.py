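"""County-level concentration fields and population-weighted exposure.

Annual station means (raw and deweathered) are interpolated to county
centroids by ordinary kriging under a fitted exponential variogram; county
fields are then combined with stratified population counts to give the
population-weighted exposure of each socio-economic group,

    PWE = sum_i(conc_i * P_i) / sum_i(P_i),

together with income-quartile regional groupings (L1 = top 25% of GDP per
capita ... L4 = bottom 25%) and start-to-end reduction fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import curve_fit

from ._spatial import pairwise_distances_km

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ variogram

@dataclass
class Variogram:
    """Semivariogram model gamma(h); h in km, gamma in (ug/m3)^2.

    gamma(0) = 0 by convention; the nugget applies at any positive lag.
    """

    nugget: float
    psill: float  # partial sill; total sill = nugget + psill
    range_km: float
    model: str = "exponential"

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        if self.model == "exponential":
            g = self.nugget + self.psill * (1.0 - np.exp(-h / self.range_km))
        elif self.model == "spherical":
            r = np.clip(h / self.range_km, 0.0, 1.0)
            g = self.nugget + self.psill * (1.5 * r - 0.5 * r**3)
        else:
            raise ValueError(f"unknown variogram model {self.model!r}")
        return np.where(h > 0, g, 0.0)


def empirical_semivariance(lat, lon, values, n_lags: int = 15, max_dist_km: float | None = None):
    """Binned empirical semivariance: lag centres, gamma-hat, pair counts."""
    d = pairwise_distances_km(lat, lon)
    v = np.asarray(values, dtype=float)
    iu = np.triu_indices(len(v), k=1)
    dist = d[iu]
    sq = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    if max_dist_km is None:
        max_dist_km = dist.max() / 2.0
    edges = np.linspace(0.0, max_dist_km, n_lags + 1)
    centres, gammas, counts = [], [], []
    for i in range(n_lags):
        mask = (dist > edges[i]) & (dist <= edges[i + 1])
        if mask.sum() == 0:
            continue
        centres.append(dist[mask].mean())
        gammas.append(sq[mask].mean())
        counts.append(int(mask.sum()))
    return np.array(centres), np.array(gammas), np.array(counts)


def fit_variogram(
    lat, lon, values, model: str = "exponential", n_lags: int = 15
) -> Variogram:
    """Fit a variogram to annual station means by weighted least squares.

    Bin weights are pair counts.  A spatially constant field degenerates to
    a pure-nugget model (psill = 0) with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("variogram fitting requires at least 10 stations")
    if np.allclose(values, values[0]):
        warnings.warn("constant field: returning pure-nugget variogram")
        return Variogram(nugget=0.0, psill=0.0, range_km=1.0, model=model)
    h, g, n = empirical_semivariance(lat, lon, values, n_lags=n_lags)
    var = values.var()
    p0 = [max(g.min(), 1e-6), max(var - g.min(), 1e-6), max(h.max() / 3.0, 1.0)]

    def _f(h_, nug, ps, rng_):
        return Variogram(nug, ps, rng_, model)(h_)

    try:
        popt, _ = curve_fit(
            _f, h, g, p0=p0, sigma=1.0 / np.sqrt(n), absolute_sigma=False,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("variogram fit failed to converge; using moment defaults")
        popt = p0
    return Variogram(nugget=float(popt[0]), psill=float(popt[1]), range_km=float(popt[2]), model=model)


# -------------------------------------------------------------------- kriging

def _dedupe(lat, lon, values):
    """Average values at duplicated coordinates (singular-system guard)."""
    df = pd.DataFrame({"lat": lat, "lon": lon, "v": values})
    agg = df.groupby(["lat", "lon"], sort=False, as_index=False).mean()
    return agg["lat"].to_numpy(), agg["lon"].to_numpy(), agg["v"].to_numpy()


def kriging_weights(
    st_lat, st_lon, variogram: Variogram, tg_lat, tg_lon
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging weights and Lagrange multipliers for each target.

    Solves [[Gamma, 1], [1^T, 0]] [lambda; mu] = [gamma_0; 1] per target.
    Weights sum to one by construction; at a target coinciding with a
    station the solution is exact interpolation.
    """
    n = len(st_lat)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram(pairwise_distances_km(st_lat, st_lon))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    factor = lu_factor(A)
    g0 = variogram(pairwise_distances_km(st_lat, st_lon, tg_lat, tg_lon))  # (n, m)
    B = np.vstack([g0, np.ones(g0.shape[1])])
    sol = lu_solve(factor, B)
    return sol[:n].T, sol[n]  # weights (m, n), mu (m,)


def krige(
    st_lat, st_lon, values, variogram: Variogram, tg_lat, tg_lon
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging estimates and variances at target points."""
    st_lat, st_lon, values = _dedupe(np.asarray(st_lat, float), np.asarray(st_lon, float),
                                     np.asarray(values, float))
    if len(values) < 3:
        raise ValueError("kriging requires at least 3 distinct stations")
    lam, mu = kriging_weights(st_lat, st_lon, variogram, tg_lat, tg_lon)
    est = lam @ values
    g0 = variogram(pairwise_distances_km(np.asarray(tg_lat, float), np.asarray(tg_lon, float),
                                         st_lat, st_lon))  # (m, n)
    var = np.maximum(np.sum(lam * g0, axis=1) + mu, 0.0)
    return est, var


def krige_to_counties(
    stations: pd.DataFrame, station_values: pd.Series, variogram: Variogram,
    counties: pd.DataFrame,
) -> pd.DataFrame:
    """Interpolate station values to county centroids.

    Returns (county_id, value, kriging_variance); negative estimates are
    floored at zero (concentrations are non-negative).
    """
    vals = station_values.reindex(stations["station_id"]).to_numpy(dtype=float)
    ok = np.isfinite(vals)
    est, var = krige(
        stations["lat"].to_numpy()[ok], stations["lon"].to_numpy()[ok], vals[ok],
        variogram, counties["lat"].to_numpy(), counties["lon"].to_numpy(),
    )
    return pd.DataFrame(
        {"county_id": counties["county_id"], "value": np.maximum(est, 0.0), "kriging_variance": var}
    )


def annual_county_fields(
    pm_qc: pd.DataFrame, dw: pd.DataFrame, stations: pd.DataFrame, counties: pd.DataFrame,
    variogram_model: str = "exponential", min_days: int = 60,
) -> pd.DataFrame:
    """Kriged county fields of annual-mean raw and deweathered PM2.5.

    Station-years with fewer than ``min_days`` valid days are excluded from
    the interpolation of that year.  Returns a table (county_id, year,
    conc_raw, conc_dw, kriging_variance) where the variance refers to the
    raw field.
    """
    pm = pm_qc.dropna(subset=["pm25"]).copy()
    pm["year"] = pd.to_datetime(pm["date"]).dt.year
    dwc = dw.dropna(subset=["pm_dw"]).copy()
    dwc["year"] = pd.to_datetime(dwc["date"]).dt.year
    out = []
    for year in sorted(pm["year"].unique()):
        grp = pm[pm["year"] == year].groupby("station_id")["pm25"]
        raw_mean = grp.mean()[grp.count() >= min_days]
        grp_dw = dwc[dwc["year"] == year].groupby("station_id")["pm_dw"]
        dw_mean = grp_dw.mean()[grp_dw.count() >= min_days]
        vg_raw = fit_variogram(
            stations.set_index("station_id").loc[raw_mean.index, "lat"],
            stations.set_index("station_id").loc[raw_mean.index, "lon"],
            raw_mean.to_numpy(), model=variogram_model,
        )
        raw_field = krige_to_counties(stations, raw_mean, vg_raw, counties)
        vg_dw = fit_variogram(
            stations.set_index("station_id").loc[dw_mean.index, "lat"],
            stations.set_index("station_id").loc[dw_mean.index, "lon"],
            dw_mean.to_numpy(), model=variogram_model,
        )
        dw_field = krige_to_counties(stations, dw_mean, vg_dw, counties)
        out.append(
            pd.DataFrame(
                {
                    "county_id": counties["county_id"],
                    "year": year,
                    "conc_raw": raw_field["value"].to_numpy(),
                    "conc_dw": dw_field["value"].to_numpy(),
                    "kriging_variance": raw_field["kriging_variance"].to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ------------------------------------------------------------------- exposure

def population_weighted_exposure(county_conc: pd.Series, county_pop: pd.Series) -> float:
    """Population-weighted mean concentration over counties.

    Both series are indexed by county id; counties absent from either side
    are ignored.  Raises on zero total population.
    """
    joined = pd.concat([county_conc.rename("c"), county_pop.rename("p")], axis=1).dropna()
    total = joined["p"].sum()
    if total <= 0:
        raise ValueError("zero total population for group")
    return float((joined["c"] * joined["p"]).sum() / total)


def exposure_table(
    county_field: pd.DataFrame, population: pd.DataFrame
) -> pd.DataFrame:
    """Per-group, per-year population-weighted exposure for raw and dw fields.

    Returns (axis, label, year, pwe_raw, pwe_dw, met_contribution,
    population), where met_contribution = (pwe_raw - pwe_dw) / pwe_dw.
    """
    rows = []
    for year, field in county_field.groupby("year"):
        conc_raw = field.set_index("county_id")["conc_raw"]
        conc_dw = field.set_index("county_id")["conc_dw"]
        for (axis, label), grp in population.groupby(["axis", "label"], sort=True):
            pop = grp.set_index("county_id")["count"].astype(float)
            if pop.sum() <= 0:
                warnings.warn(f"group {axis}/{label}: zero population, skipped")
                continue
            pwe_raw = population_weighted_exposure(conc_raw, pop)
            pwe_dw = population_weighted_exposure(conc_dw, pop)
            met = (pwe_raw - pwe_dw) / pwe_dw if pwe_dw > 0 else np.nan
            rows.append((axis, label, int(year), pwe_raw, pwe_dw, met, float(pop.sum())))
    return pd.DataFrame(
        rows,
        columns=["axis", "label", "year", "pwe_raw", "pwe_dw", "met_contribution", "population"],
    )


def group_regions_by_income(gdp_per_capita: pd.Series) -> pd.Series:
    """Quartile income labels L1 (top 25% of GDP per capita) ... L4 (bottom).

    Rank-based cut with ties broken by stable original order.  Requires at
    least four regions.
    """
    if len(gdp_per_capita) < 4:
        raise ValueError("income quartiles require at least 4 regions")
    vals = gdp_per_capita.to_numpy(dtype=float)
    n = len(vals)
    asc = np.argsort(vals, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[asc] = np.arange(n)
    quartile = np.minimum((rank * 4) // n, 3)  # 0 = bottom ... 3 = top
    labels = np.array(["L4", "L3", "L2", "L1"])[quartile]
    return pd.Series(labels, index=gdp_per_capita.index, name="income_group")


def reduction_fraction(conc_start: float, conc_end: float) -> float:
    """Percent reduction 100*(start - end)/start; negative for an increase."""
    if conc_start <= 0:
        raise ValueError("starting concentration must be positive")
    return 100.0 * (conc_start - conc_end) / conc_start
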