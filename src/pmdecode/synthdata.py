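"""Seeded synthetic data: station networks, meteorology, emissions, PM2.5, populations.

The generator produces data with the statistical structure the downstream
analysis assumes — a clustered monitoring network, autocorrelated seasonal
meteorology, a multiplicative emission signal (trend x season x weekday), a
spatially varying linear meteorological response, and county populations
stratified along several socio-economic axes — so that every stage of the
pipeline can be exercised and validated against known ground truth without
any external downloads.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._spatial import pairwise_distances_km

logger = logging.getLogger(__name__)

MET_VARS = ["msl", "rh", "t2m", "u10", "v10", "blh"]

#: Default national-scale bounding box (lat_min, lat_max, lon_min, lon_max).
DEFAULT_BOUNDS = (18.0, 54.0, 75.0, 135.0)

#: Default stratification axes with baseline population shares.
DEFAULT_AXES: dict[str, dict[str, float]] = {
    "occupation": {
        "agriculture": 0.25,
        "manufacturing": 0.19,
        "construction": 0.12,
        "mining": 0.03,
        "it": 0.05,
        "services": 0.36,
    },
    "age": {"0-14": 0.18, "15-59": 0.62, "60+": 0.20},
    "gender": {"male": 0.51, "female": 0.49},
    "education": {"primary": 0.35, "secondary": 0.45, "tertiary": 0.20},
    "residence": {"urban": 0.40, "town": 0.20, "rural": 0.40},
    "origin": {"native": 0.85, "outsider": 0.15},
}

# Per-variable meteorology configuration: (mean, seasonal amplitude with
# winter sign applied, day-to-day noise SD).  Units follow the reanalysis
# convention: msl Pa, rh %, t2m K, winds m/s, blh m.
_MET_CONFIG = {
    "msl": (101325.0, 800.0, 350.0),
    "rh": (62.0, -8.0, 9.0),
    "t2m": (287.0, -12.0, 3.0),
    "u10": (0.5, 0.8, 1.8),
    "v10": (-0.3, -0.5, 1.8),
    "blh": (620.0, -250.0, 130.0),
}

# Baseline linear response of PM2.5 to meteorological anomalies, per unit of
# each variable.  Signs follow dispersion physics: deeper boundary layer,
# stronger wind and warmer near-surface air dilute PM; humidity promotes
# hygroscopic growth / secondary formation.
_BASE_RESPONSE = {
    "msl": 0.002,
    "rh": 0.12,
    "t2m": -0.35,
    "u10": -0.9,
    "v10": 0.6,
    "blh": -0.010,
}


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests.

    Attributes
    ----------
    emission : DataFrame with columns (station_id, date, emission) — the true
        emission-driven concentration in ug/m3.
    met_response : DataFrame indexed by station_id with one column per
        meteorological variable — linear response coefficients.
    noise_sd : observation noise SD in ug/m3.
    met_reference : per-station climatological reference (DataFrame indexed
        by station_id, one column per variable) defining "anomaly = value
        minus reference", so the response acts on weather variability rather
        than on static spatial offsets; filled in by :func:`synthesize_pm`
        from the station means of the meteorological series if not set.
    """

    emission: pd.DataFrame
    met_response: pd.DataFrame
    noise_sd: float
    met_reference: pd.DataFrame | None = field(default=None)


def _seasonal_basis(dates: pd.DatetimeIndex) -> np.ndarray:
    """Annual cosine peaking on 1 January (winter peak by construction)."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    return np.cos(2.0 * np.pi * (doy - 1.0) / 365.25)


def _smooth_field(lat, lon, rng, length_scale_km=800.0, n_anchors=12):
    """Smooth random spatial field in roughly [-1, 1].

    Gaussian-kernel interpolation of iid anchor values gives a field with a
    controllable correlation length; used for spatially varying baselines and
    response coefficients.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    alat = rng.uniform(lat.min(), lat.max(), n_anchors)
    alon = rng.uniform(lon.min(), lon.max(), n_anchors)
    vals = rng.normal(0.0, 1.0, n_anchors)
    d = pairwise_distances_km(lat, lon, alat, alon)
    w = np.exp(-0.5 * (d / length_scale_km) ** 2)
    fld = (w @ vals) / np.maximum(w.sum(axis=1), 1e-12)
    fld = fld - fld.mean()
    sd = fld.std()
    return np.clip(fld / sd if sd > 0 else fld, -1.5, 1.5)


def generate_station_network(
    n_stations: int,
    n_counties: int,
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
    seed: int = 0,
    n_provinces: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a clustered station network and county centroid table.

    Stations are drawn from a two-component Gaussian mixture over the
    bounding box (weights 0.7/0.3), reproducing the dense-east / sparse-west
    character of real monitoring networks.  County centroids are uniform over
    the box; each station is assigned to its nearest county, and counties are
    grouped into ``n_provinces`` longitude-contiguous provinces.

    Returns
    -------
    (stations, counties) : stations has columns (station_id, lat, lon,
        county_id); counties has (county_id, lat, lon, province_id).
    """
    if n_stations < 3:
        raise ValueError("need at least 3 stations")
    if n_counties < 1 or n_provinces < 1:
        raise ValueError("counts must be positive")
    lat_min, lat_max, lon_min, lon_max = bounds
    rng = np.random.default_rng(seed)

    means = np.array([[0.68, 0.72], [0.38, 0.30]])  # (lat, lon) in unit box
    sds = np.array([[0.16, 0.14], [0.12, 0.12]])
    weights = np.array([0.7, 0.3])
    pts = np.empty((0, 2))
    while len(pts) < n_stations:
        comp = rng.choice(2, size=n_stations, p=weights)
        cand = rng.normal(means[comp], sds[comp])
        cand = cand[((cand >= 0) & (cand <= 1)).all(axis=1)]
        pts = np.vstack([pts, cand])
    pts = pts[:n_stations]
    st_lat = lat_min + pts[:, 0] * (lat_max - lat_min)
    st_lon = lon_min + pts[:, 1] * (lon_max - lon_min)

    co_lat = rng.uniform(lat_min, lat_max, n_counties)
    co_lon = rng.uniform(lon_min, lon_max, n_counties)
    county_ids = [f"C{i:04d}" for i in range(n_counties)]
    # longitude-contiguous provinces
    order = np.argsort(co_lon, kind="stable")
    prov_of = np.empty(n_counties, dtype=int)
    splits = np.array_split(order, min(n_provinces, n_counties))
    for p, idx in enumerate(splits):
        prov_of[idx] = p
    counties = pd.DataFrame(
        {
            "county_id": county_ids,
            "lat": co_lat,
            "lon": co_lon,
            "province_id": [f"P{p:02d}" for p in prov_of],
        }
    )

    d = pairwise_distances_km(st_lat, st_lon, co_lat, co_lon)
    nearest = d.argmin(axis=1)
    stations = pd.DataFrame(
        {
            "station_id": [f"S{i:04d}" for i in range(n_stations)],
            "lat": st_lat,
            "lon": st_lon,
            "county_id": [county_ids[j] for j in nearest],
        }
    )
    return stations, counties


def generate_meteorology(
    stations: pd.DataFrame,
    dates: pd.DatetimeIndex,
    seed: int = 0,
    ar_coef: float = 0.7,
    drift_per_year: dict[str, float] | None = None,
    shared_frac: float = 0.3,
) -> pd.DataFrame:
    """Daily six-variable meteorology per station.

    Each variable is mean + station offset + seasonal cosine (winter-phased)
    + stationary AR(1) noise with lag-1 coefficient ``ar_coef``.  Variables
    are generated independently of one another.  Relative humidity is clipped
    to [0, 100] and boundary-layer height floored at 50 m.

    ``drift_per_year`` optionally adds a slow linear drift (units of the
    variable per year) to selected variables — a controlled stand-in for
    interannual meteorological change, which confounds raw concentration
    trends.  ``shared_frac`` is the fraction of the AR(1) innovation
    variance common to all stations, emulating synoptic-scale weather that
    is regionally coherent rather than station-local.

    Returns a long DataFrame (station_id, date, msl, rh, t2m, u10, v10, blh).
    """
    if len(stations) == 0:
        raise ValueError("empty station table")
    if len(dates) == 0:
        raise ValueError("empty date range")
    if not (0 <= ar_coef < 1):
        raise ValueError("ar_coef must be in [0, 1)")
    if not (0 <= shared_frac <= 1):
        raise ValueError("shared_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_s, n_t = len(stations), len(dates)
    season = _seasonal_basis(dates)

    cols = {}
    lat = stations["lat"].to_numpy()
    for var, (mean, amp, sd) in _MET_CONFIG.items():
        # smooth spatial offsets; t2m additionally cools toward high latitude
        offset = 0.3 * abs(amp) * _smooth_field(lat, stations["lon"].to_numpy(), rng)
        if var == "t2m":
            offset = offset - 0.4 * (lat - lat.mean())
        innov_sd = sd * np.sqrt(1.0 - ar_coef**2)
        own = rng.normal(0.0, 1.0, size=(n_s, n_t))
        common = rng.normal(0.0, 1.0, size=n_t)
        innov = innov_sd * (
            np.sqrt(1.0 - shared_frac) * own + np.sqrt(shared_frac) * common[None, :]
        )
        noise = lfilter([1.0], [1.0, -ar_coef], innov, axis=1)
        series = mean + offset[:, None] + amp * season[None, :] + noise
        if drift_per_year and var in drift_per_year:
            years = (dates - dates[0]).days.to_numpy(dtype=float) / 365.25
            series = series + drift_per_year[var] * years[None, :]
        if var == "rh":
            series = np.clip(series, 0.0, 100.0)
        if var == "blh":
            series = np.maximum(series, 50.0)
        cols[var] = series.ravel()

    out = pd.DataFrame(
        {
            "station_id": np.repeat(stations["station_id"].to_numpy(), n_t),
            "date": np.tile(dates.to_numpy(), n_s),
        }
    )
    for var in MET_VARS:
        out[var] = cols[var]
    return out


def generate_emission_signal(
    stations: pd.DataFrame,
    dates: pd.DatetimeIndex,
    base: float = 55.0,
    trend: float = -0.08,
    seasonal_amp: float = 0.40,
    weekday_amp: float = 0.05,
    base_spread: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """True emission-driven concentration series (ug/m3).

    emission(t) = base_i * (1+trend)^years(t) * season(t) * weekday(t), with
    years measured as elapsed days / 365.25 from the first date, a winter-
    peaking seasonal factor 1 + seasonal_amp*cos, and a weekday factor that
    is elevated Monday-Friday and reduced at weekends with zero mean over the
    week.  Station baselines vary smoothly over space by a lognormal factor
    with log-SD ``base_spread``.
    """
    if not (-1.0 < trend < 1.0):
        raise ValueError("trend must be in (-1, 1)")
    if seasonal_amp < 0 or weekday_amp < 0:
        raise ValueError("amplitudes must be non-negative")
    if seasonal_amp >= 1.0 or weekday_amp >= 1.0:
        raise ValueError("amplitudes >= 1 would produce non-positive emissions")
    if len(dates) == 0:
        raise ValueError("empty date range")
    rng = np.random.default_rng(seed)
    n_s, n_t = len(stations), len(dates)

    years = (dates - dates[0]).days.to_numpy(dtype=float) / 365.25
    seasonal = 1.0 + seasonal_amp * _seasonal_basis(dates)
    dow_effect = np.where(dates.dayofweek.to_numpy() < 5, 0.4, -1.0)  # zero-mean over a week
    weekday = 1.0 + weekday_amp * dow_effect
    time_factor = (1.0 + trend) ** years * seasonal * weekday

    base_i = base * np.exp(
        base_spread * _smooth_field(stations["lat"].to_numpy(), stations["lon"].to_numpy(), rng)
    )
    series = base_i[:, None] * time_factor[None, :]
    return pd.DataFrame(
        {
            "station_id": np.repeat(stations["station_id"].to_numpy(), n_t),
            "date": np.tile(dates.to_numpy(), n_s),
            "emission": series.ravel(),
        }
    )


def make_met_response(
    stations: pd.DataFrame,
    mode: str = "smooth",
    scale: float = 1.0,
    seed: int = 0,
    length_scale_km: float = 800.0,
    boundary_lon: float | None = None,
) -> pd.DataFrame:
    """Per-station linear met-response coefficients.

    Modes
    -----
    - ``"zero"``: all coefficients zero (meteorology-free truth).
    - ``"smooth"``: baseline coefficients modulated by a smooth spatial field
      (correlation length ``length_scale_km``), so geographic weighting has a
      recoverable signal.
    - ``"two_regime"``: coefficient signs flip for stations east of
      ``boundary_lon`` (default: median station longitude) — a hard spatial
      discontinuity that a single pooled model cannot represent.
    """
    idx = stations["station_id"].to_numpy()
    base = np.array([_BASE_RESPONSE[v] for v in MET_VARS]) * scale
    if mode == "zero":
        coefs = np.zeros((len(idx), len(MET_VARS)))
    elif mode == "smooth":
        rng = np.random.default_rng(seed)
        coefs = np.empty((len(idx), len(MET_VARS)))
        for k in range(len(MET_VARS)):
            fld = _smooth_field(
                stations["lat"].to_numpy(), stations["lon"].to_numpy(), rng, length_scale_km
            )
            coefs[:, k] = base[k] * (1.0 + 0.6 * fld)
    elif mode == "two_regime":
        lon = stations["lon"].to_numpy()
        cut = np.median(lon) if boundary_lon is None else boundary_lon
        sign = np.where(lon < cut, 1.0, -1.0)
        coefs = sign[:, None] * base[None, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(coefs, index=pd.Index(idx, name="station_id"), columns=MET_VARS)


def synthesize_pm(truth: SyntheticTruth, met: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Forward model: PM = emission + response . met_anomaly + noise, floored at 0.1.

    The emission table and meteorology must align exactly on station x date.
    Meteorological anomalies are taken relative to ``truth.met_reference``
    (pooled national-period means, computed and stored on first use).
    """
    em = truth.emission.sort_values(["station_id", "date"]).reset_index(drop=True)
    mt = met.sort_values(["station_id", "date"]).reset_index(drop=True)
    if len(em) != len(mt) or not (
        em["station_id"].to_numpy() == mt["station_id"].to_numpy()
    ).all() or not (em["date"].to_numpy() == mt["date"].to_numpy()).all():
        raise ValueError("emission and meteorology are not aligned on station x date")

    if truth.met_reference is None:
        truth.met_reference = mt.groupby("station_id")[MET_VARS].mean()
    ref = truth.met_reference.loc[mt["station_id"].to_numpy()].to_numpy()
    anom = mt[MET_VARS].to_numpy() - ref
    resp = truth.met_response.loc[em["station_id"].to_numpy()].to_numpy()
    met_term = (anom * resp).sum(axis=1)

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, truth.noise_sd, len(em)) if truth.noise_sd > 0 else 0.0
    pm = np.maximum(em["emission"].to_numpy() + met_term + noise, 0.1)
    return pd.DataFrame({"station_id": em["station_id"], "date": em["date"], "pm25": pm})


def stagger_station_records(
    pm: pd.DataFrame,
    seed: int = 0,
    backbone_fraction: float = 0.25,
    latest_start: float = 0.75,
) -> pd.DataFrame:
    """Truncate station records to staggered activation dates.

    Monitoring networks grow over time, so station record lengths are
    heterogeneous: a ``backbone_fraction`` of stations report from the first
    day, while the rest activate at a uniform random point within the first
    ``latest_start`` fraction of the study span.  Observations before a
    station's activation are dropped.
    """
    if not 0 <= backbone_fraction <= 1 or not 0 < latest_start <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(pm["date"])
    t0, t1 = dates.min(), dates.max()
    span_days = (t1 - t0).days
    sids = np.sort(pm["station_id"].unique())
    backbone = rng.random(len(sids)) < backbone_fraction
    start_frac = np.where(backbone, 0.0, rng.uniform(0.0, latest_start, len(sids)))
    start_date = {
        s: t0 + pd.Timedelta(days=int(round(f * span_days))) for s, f in zip(sids, start_frac)
    }
    keep = dates >= pm["station_id"].map(start_date)
    return pm.loc[keep].reset_index(drop=True)


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment preserving the exact total."""
    raw = shares * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_population(
    counties: pd.DataFrame,
    axes: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    total_mean: float = 2.0e5,
    total_log_sd: float = 0.6,
    jitter: float | None = 60.0,
    county_exposure: pd.Series | None = None,
    gdp_exposure_rho: float = 0.5,
    totals: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified county populations plus a GDP-per-capita table.

    Each axis partitions every county's total exactly (largest-remainder
    apportionment), with county-level share variation drawn from a Dirichlet
    around the axis' baseline shares (concentration ``jitter``; ``None``
    means exact baseline shares everywhere).  GDP per capita is lognormal
    and, when ``county_exposure`` is supplied, rank-correlated with it with
    sign and strength ``gdp_exposure_rho`` so income-stratified analyses are
    non-degenerate.

    Returns (population, gdp): population has columns (county_id, axis,
    label, count); gdp has (county_id, gdp_per_capita).
    """
    if len(counties) == 0:
        raise ValueError("need at least one county")
    axes = DEFAULT_AXES if axes is None else axes
    if not axes:
        raise ValueError("empty axis list")
    rng = np.random.default_rng(seed)
    n = len(counties)
    if totals is None:
        totals = np.round(total_mean * np.exp(rng.normal(0.0, total_log_sd, n))).astype(int)
        totals = np.maximum(totals, 100)
    else:
        totals = np.asarray(totals, dtype=int)

    rows = []
    for axis, base_shares in axes.items():
        labels = list(base_shares)
        p = np.array([base_shares[l] for l in labels], dtype=float)
        p = p / p.sum()
        if jitter is None:
            shares = np.tile(p, (n, 1))
        else:
            shares = rng.dirichlet(p * jitter, size=n)
        for i, cid in enumerate(counties["county_id"]):
            counts = _largest_remainder(shares[i], int(totals[i]))
            for l, c in zip(labels, counts):
                rows.append((cid, axis, l, int(c)))
    population = pd.DataFrame(rows, columns=["county_id", "axis", "label", "count"])

    z_noise = rng.normal(0.0, 1.0, n)
    if county_exposure is not None:
        exp_vals = county_exposure.reindex(counties["county_id"]).to_numpy(dtype=float)
        z_exp = (exp_vals - np.nanmean(exp_vals)) / (np.nanstd(exp_vals) + 1e-12)
        z = gdp_exposure_rho * z_exp + np.sqrt(max(0.0, 1 - gdp_exposure_rho**2)) * z_noise
    else:
        z = z_noise
    gdp = pd.DataFrame(
        {
            "county_id": counties["county_id"],
            "gdp_per_capita": 5.0e4 * np.exp(0.45 * z),
        }
    )
    return population, gdp


def idw_county_truth(
    stations: pd.DataFrame, counties: pd.DataFrame, station_values: pd.Series, power: float = 2.0
) -> pd.Series:
    """Inverse-distance-weighted county-level 'truth' from station values.

    Gives kriging a recoverable target and supplies the generator's notion
    of county mean exposure (used to couple GDP per capita to pollution).
    """
    vals = station_values.reindex(stations["station_id"]).to_numpy(dtype=float)
    d = pairwise_distances_km(
        counties["lat"].to_numpy(), counties["lon"].to_numpy(),
        stations["lat"].to_numpy(), stations["lon"].to_numpy(),
    )
    w = 1.0 / np.maximum(d, 1.0) ** power
    return pd.Series((w @ vals) / w.sum(axis=1), index=counties["county_id"].to_numpy())


def stable_station_key(station_id: str) -> int:
    """Deterministic 32-bit key for a station id (used for seed streams)."""
    return zlib.crc32(str(station_id).encode("utf-8"))


def write_dataset(outdir, stations, counties, met, pm, population, gdp) -> dict[str, str]:
    """Write the synthetic tables as UTF-8 CSV with ISO-8601 dates."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in [
        ("stations", stations),
        ("counties", counties),
        ("met", met),
        ("pm", pm),
        ("population", population),
        ("gdp", gdp),
    ]:
        path = os.path.join(outdir, f"{name}.csv")
        out = df.copy()
        if "date" in out.columns:
            out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        paths[name] = path
    return paths
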