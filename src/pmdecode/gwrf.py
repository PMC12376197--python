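"""Geographically weighted random forest for PM2.5, with pooled and
per-station baselines.

The estimation model maps six meteorological covariates plus three time
terms to daily PM2.5:

    PM2.5 = f(msl, rh, t2m, u10, v10, blh, NSC, day-of-week, unix time)

Three architectures are supported:

- **GWRF** — one random-forest ensemble per anchor location, trained with
  Gaussian distance-decay sample weights w = exp(-0.5 (d/bandwidth)^2); a
  prediction uses the ensemble of the nearest anchor.  Kernel bandwidth is
  selected by K-fold cross-validation (minimum mean RMSE, ties toward the
  larger, smoother bandwidth).
- **holistic** — a single pooled forest over all stations.
- **pointwise** — an independent forest per station.

Sample weights are used raw (unnormalised); scaling all weights by a
positive constant leaves tree construction unchanged.  Samples whose weight
falls below a floor are dropped from an anchor's training set, which bounds
the cost of national-scale fits without affecting the kernel's local
behaviour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from ._spatial import haversine_km, pairwise_distances_km

logger = logging.getLogger(__name__)

MET_FEATURES = ["msl", "rh", "t2m", "u10", "v10", "blh"]
TIME_FEATURES = ["nsc", "day_of_week", "unix_time"]
FEATURES = MET_FEATURES + TIME_FEATURES

DEFAULT_N_TREES = 500
DEFAULT_SPLITS = (0.70, 0.10, 0.20)
DEFAULT_CV_FOLDS = 5


# ----------------------------------------------------------------- time terms

def compute_nsc(pm: pd.DataFrame) -> pd.DataFrame:
    """Normalized seasonal coefficient per station and calendar month.

    nsc(month) = mean PM in that calendar month (across years) divided by
    the station's overall mean, so that the observation-count-weighted mean
    of the twelve coefficients is exactly 1.  Months with no data get the
    neutral value 1.  Requires at least one full year of span.
    """
    pm = pm.dropna(subset=["pm25"])
    if len(pm) == 0:
        raise ValueError("no valid observations")
    dates = pd.to_datetime(pm["date"])
    if (dates.max() - dates.min()).days < 364:
        raise ValueError("NSC requires at least one full year of data")
    df = pm.assign(month=dates.dt.month)
    rows = []
    for sid, grp in df.groupby("station_id", sort=True):
        overall = grp["pm25"].mean()
        monthly = grp.groupby("month")["pm25"].mean()
        for m in range(1, 13):
            nsc = float(monthly.get(m, overall) / overall) if overall > 0 else 1.0
            rows.append((sid, m, nsc))
    return pd.DataFrame(rows, columns=["station_id", "month", "nsc"])


def build_features(
    pm: pd.DataFrame, met: pd.DataFrame, stations: pd.DataFrame, nsc: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the model table: features, target, and location columns.

    Joins PM observations with co-located meteorology and station
    coordinates, and attaches the three time terms.  Rows with a missing
    target or missing meteorology are dropped.
    """
    pm = pm.copy()
    pm["date"] = pd.to_datetime(pm["date"])
    met = met.copy()
    met["date"] = pd.to_datetime(met["date"])
    if nsc is None:
        nsc = compute_nsc(pm)
    df = pm.merge(met, on=["station_id", "date"], how="inner")
    df["month"] = df["date"].dt.month
    df = df.merge(nsc, on=["station_id", "month"], how="left")
    df["nsc"] = df["nsc"].fillna(1.0)
    df["day_of_week"] = df["date"].dt.dayofweek
    df["unix_time"] = df["date"].astype("int64") // 10**9
    df = df.merge(stations[["station_id", "lat", "lon"]], on="station_id", how="left")
    df = df.dropna(subset=["pm25"] + FEATURES).reset_index(drop=True)
    return df.drop(columns=["month"])


def split_data(
    n: int, fractions: tuple[float, float, float] = DEFAULT_SPLITS, seed: int = 0
) -> dict[str, np.ndarray]:
    """Random disjoint train/val/test index split by record."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train : n_train + n_val]),
        "test": np.sort(perm[n_train + n_val :]),
    }


# -------------------------------------------------------------------- kernels

def gaussian_weight(distance_km, bandwidth_km: float):
    """Gaussian distance-decay weight exp(-0.5 (d/b)^2), in (0, 1]."""
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    return np.exp(-0.5 * (d / bandwidth_km) ** 2)


# --------------------------------------------------------------------- models

def _new_forest(n_trees: int, seed: int, max_features: float = 1.0) -> RandomForestRegressor:
    """Regression forest with nodesize 5.

    ``max_features`` defaults to all features per split: met/time-term
    attribution — which deweathering depends on — degrades under feature
    subsampling, because collinear meteorological variables then stand in
    for the time terms.  The classic p/3 subsampling can be requested for
    large fits where runtime dominates.
    """
    return RandomForestRegressor(
        n_estimators=n_trees,
        random_state=int(seed) % 2**31,
        n_jobs=1,
        min_samples_leaf=5,
        max_features=max_features,
    )


class HolisticModel:
    """Single pooled forest over all stations."""

    def __init__(self, n_trees: int = DEFAULT_N_TREES, seed: int = 0, max_features: float = 1.0):
        self.forest = _new_forest(n_trees, seed, max_features)

    def fit(self, train: pd.DataFrame, sample_weight=None) -> "HolisticModel":
        self.forest.fit(train[FEATURES], train["pm25"], sample_weight=sample_weight)
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(data[FEATURES])


class PointwiseModel:
    """Independent forest per station; stations with too few samples are
    skipped and served by the nearest fitted station's forest."""

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        seed: int = 0,
        min_samples: int = 30,
        max_features: float = 1.0,
    ):
        self.n_trees = n_trees
        self.seed = seed
        self.min_samples = min_samples
        self.max_features = max_features
        self.forests: dict[str, RandomForestRegressor] = {}
        self.locations: pd.DataFrame | None = None

    def fit(self, train: pd.DataFrame) -> "PointwiseModel":
        locs = []
        for k, (sid, grp) in enumerate(train.groupby("station_id", sort=True)):
            if len(grp) < self.min_samples:
                warnings.warn(f"station {sid}: {len(grp)} samples < {self.min_samples}, skipped")
                continue
            f = _new_forest(self.n_trees, self.seed + k, self.max_features)
            f.fit(grp[FEATURES], grp["pm25"])
            self.forests[sid] = f
            locs.append((sid, grp["lat"].iloc[0], grp["lon"].iloc[0]))
        if not self.forests:
            raise ValueError("no station meets the pointwise sample minimum")
        self.locations = pd.DataFrame(locs, columns=["station_id", "lat", "lon"])
        return self

    def _route(self, data: pd.DataFrame) -> pd.Series:
        sid = data["station_id"].copy()
        unknown = ~sid.isin(self.forests)
        if unknown.any():
            d = pairwise_distances_km(
                data.loc[unknown, "lat"], data.loc[unknown, "lon"],
                self.locations["lat"], self.locations["lon"],
            )
            sid.loc[unknown] = self.locations["station_id"].to_numpy()[d.argmin(axis=1)]
        return sid

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        routed = self._route(data)
        pred = np.empty(len(data))
        for sid, idx in routed.groupby(routed).groups.items():
            pos = data.index.get_indexer(idx)
            pred[pos] = self.forests[sid].predict(data.loc[idx, FEATURES])
        return pred


@dataclass
class GWRFModel:
    """Anchor-local weighted ensembles with Gaussian distance decay."""

    bandwidth_km: float
    anchors: pd.DataFrame  # columns: lat, lon
    forests: list[RandomForestRegressor]

    def describe(self) -> dict:
        """Inspectable summary: bandwidth, anchors, ensemble sizes."""
        return {
            "bandwidth_km": self.bandwidth_km,
            "n_anchors": len(self.forests),
            "anchors": self.anchors.round(4).to_dict(orient="records"),
            "n_trees": self.forests[0].n_estimators if self.forests else 0,
        }

    def nearest_anchor(self, lat, lon) -> np.ndarray:
        d = pairwise_distances_km(lat, lon, self.anchors["lat"], self.anchors["lon"])
        return d.argmin(axis=1)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        which = self.nearest_anchor(data["lat"].to_numpy(), data["lon"].to_numpy())
        pred = np.empty(len(data))
        X = data[FEATURES]
        for a in np.unique(which):
            mask = which == a
            pred[mask] = self.forests[a].predict(X[mask])
        return pred


def fit_gwrf(
    train: pd.DataFrame,
    bandwidth_km: float,
    anchor_locations: pd.DataFrame | None = None,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    weight_floor: float = 0.01,
    min_anchor_samples: int = 50,
    max_features: float = 1.0,
) -> GWRFModel:
    """Fit one weighted forest per anchor location.

    Anchors default to the distinct station locations in ``train``.  For
    each anchor, samples are weighted by the Gaussian kernel of their
    distance to the anchor; samples with weight below ``weight_floor`` are
    dropped.  Anchors left with fewer than ``min_anchor_samples`` weighted
    samples are dropped with a warning.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    if anchor_locations is None:
        anchor_locations = (
            train.groupby("station_id", sort=True)[["lat", "lon"]].first().reset_index(drop=True)
        )
    anchors = anchor_locations[["lat", "lon"]].reset_index(drop=True)
    s_lat = train["lat"].to_numpy()
    s_lon = train["lon"].to_numpy()

    kept_anchors, forests = [], []
    for a in range(len(anchors)):
        d = haversine_km(s_lat, s_lon, anchors.at[a, "lat"], anchors.at[a, "lon"])
        w = gaussian_weight(d, bandwidth_km)
        mask = w > weight_floor
        if mask.sum() < min_anchor_samples:
            warnings.warn(f"anchor {a}: {int(mask.sum())} weighted samples, dropped")
            continue
        f = _new_forest(n_trees, seed + a, max_features)
        sub = train.loc[mask]
        f.fit(sub[FEATURES], sub["pm25"], sample_weight=w[mask])
        kept_anchors.append(a)
        forests.append(f)
    if not forests:
        raise ValueError("all anchors dropped: no anchor has enough weighted samples")
    return GWRFModel(
        bandwidth_km=bandwidth_km,
        anchors=anchors.iloc[kept_anchors].reset_index(drop=True),
        forests=forests,
    )


def fit_baselines(
    train: pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    min_station_samples: int = 30,
    max_features: float = 1.0,
) -> tuple[HolisticModel, PointwiseModel]:
    """Fit the pooled (holistic) and per-station (pointwise) baselines."""
    holistic = HolisticModel(n_trees, seed, max_features).fit(train)
    pointwise = PointwiseModel(n_trees, seed, min_station_samples, max_features).fit(train)
    return holistic, pointwise


def select_bandwidth(
    train: pd.DataFrame,
    candidates_km: list[float],
    folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    n_trees: int = 100,
    anchor_locations: pd.DataFrame | None = None,
    **fit_kwargs,
) -> float:
    """Choose the kernel bandwidth by K-fold CV, minimising mean RMSE.

    Ties (within 1e-12) are broken toward the larger bandwidth, preferring
    the smoother model.  A single candidate is returned directly.
    """
    if not candidates_km:
        raise ValueError("empty candidate list")
    if len(candidates_km) == 1:
        return float(candidates_km[0])
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % 2**31)
    idx = np.arange(len(train))
    mean_rmse = []
    for bw in candidates_km:
        errs = []
        for tr, va in kf.split(idx):
            model = fit_gwrf(
                train.iloc[tr], bw, anchor_locations, n_trees=n_trees, seed=seed, **fit_kwargs
            )
            pred = model.predict(train.iloc[va])
            errs.append(float(np.sqrt(np.mean((pred - train.iloc[va]["pm25"]) ** 2))))
        mean_rmse.append(float(np.mean(errs)))
        logger.info("bandwidth %.1f km: CV RMSE %.4f", bw, mean_rmse[-1])
    best = min(mean_rmse)
    chosen = max(bw for bw, e in zip(candidates_km, mean_rmse) if e <= best + 1e-12)
    return float(chosen)


# ------------------------------------------------------------------- metrics

@dataclass
class ModelMetrics:
    """Accuracy summary: R2, RMSE (ug/m3), MAPE (%), MAE (ug/m3), Pearson r."""

    r2: float
    rmse: float
    mape: float
    mae: float
    r: float

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "mape": self.mape, "mae": self.mae, "r": self.r}


def compute_metrics(obs: np.ndarray, pred: np.ndarray) -> ModelMetrics:
    """Pooled accuracy metrics; zero observations are excluded from MAPE."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(obs) == 0:
        raise ValueError("empty evaluation set")
    resid = pred - obs
    sse = float(np.sum(resid**2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    nz = obs != 0
    if not nz.all():
        warnings.warn(f"{int((~nz).sum())} zero observations excluded from MAPE")
    mape = float(np.mean(np.abs(resid[nz]) / obs[nz]) * 100.0) if nz.any() else float("nan")
    if np.std(obs) > 0 and np.std(pred) > 0:
        r = float(np.corrcoef(obs, pred)[0, 1])
    else:
        r = 1.0 if np.allclose(obs, pred) else 0.0
    return ModelMetrics(r2=r2, rmse=rmse, mape=mape, mae=mae, r=r)


def evaluate(model, test: pd.DataFrame) -> ModelMetrics:
    """Evaluate a fitted model on a held-out table."""
    if len(test) == 0:
        raise ValueError("empty test set")
    return compute_metrics(test["pm25"].to_numpy(), model.predict(test))
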