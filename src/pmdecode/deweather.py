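"""Meteorological normalization (deweathering) of PM2.5.

PM_dw — the concentration expected under average meteorological conditions —
is computed per observation by holding the three time terms (NSC, day of
week, unix time) fixed while replacing the meteorological covariates with
draws from a national pool of complete met records, predicting with the
fitted model for each draw, and averaging.  Sharing one pool across all
observations places every deweathered value in the same meteorological
context, which is what makes PM_dw values comparable across stations and
years.

The resample stream is keyed by (seed, station, date), so results do not
depend on the order in which observations are processed.

The meteorological contribution of a day is the fractional difference
(PM_raw - PM_dw) / PM_dw: negative values mean the actual weather dispersed
pollution below what average conditions would have produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwrf import FEATURES, MET_FEATURES, TIME_FEATURES
from .synthdata import stable_station_key

logger = logging.getLogger(__name__)

DEFAULT_N_RESAMPLE = 1000


@dataclass
class MetPool:
    """Pool of complete six-variable meteorological records.

    Draws are uniform with replacement under a seeded generator.
    """

    records: np.ndarray  # shape (n, 6), columns MET_FEATURES

    def __len__(self) -> int:
        return len(self.records)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.records[rng.integers(0, len(self.records), size=n)]


def build_met_pool(met: pd.DataFrame) -> MetPool:
    """Assemble the national pool from all stations and dates.

    Records with any of the six variables missing are excluded.
    """
    if len(met) == 0:
        raise ValueError("empty meteorological table")
    arr = met[MET_FEATURES].to_numpy(dtype=float)
    complete = np.isfinite(arr).all(axis=1)
    if not complete.any():
        raise ValueError("no complete meteorological records")
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("met pool: %d incomplete records excluded", n_dropped)
    return MetPool(records=arr[complete])


def _obs_rng(seed: int, station_id: str, date) -> np.random.Generator:
    """Generator keyed by observation identity, independent of order."""
    day = int(pd.Timestamp(date).value // 86_400_000_000_000)
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, stable_station_key(station_id), day & 0x7FFFFFFF])
    )


def deweather_point(
    model,
    time_terms: tuple[float, int, float],
    location: tuple[float, float],
    pool: MetPool,
    n_resample: int = DEFAULT_N_RESAMPLE,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Deweather a single observation.

    Returns (pm_dw, mc_se): the mean of ``n_resample`` predictions with met
    drawn from the pool and time terms fixed, and the Monte-Carlo standard
    error of that mean (0 when n_resample == 1).
    """
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    if len(pool) == 0:
        raise ValueError("empty meteorological pool")
    if rng is None:
        rng = np.random.default_rng(seed)
    met_draws = pool.sample(n_resample, rng)
    X = pd.DataFrame(met_draws, columns=MET_FEATURES)
    nsc, dow, unix_time = time_terms
    X["nsc"] = nsc
    X["day_of_week"] = dow
    X["unix_time"] = unix_time
    X["lat"] = location[0]
    X["lon"] = location[1]
    preds = model.predict(X)
    pm_dw = float(preds.mean())
    mc_se = float(preds.std(ddof=1) / np.sqrt(n_resample)) if n_resample > 1 else 0.0
    return pm_dw, mc_se


def deweather_series(
    model,
    observations: pd.DataFrame,
    pool: MetPool,
    n_resample: int = DEFAULT_N_RESAMPLE,
    seed: int = 0,
    chunk_rows: int = 500_000,
) -> pd.DataFrame:
    """Deweather every observation of a feature table.

    ``observations`` must carry station_id, date, pm25, lat, lon and the
    three time terms (as produced by :func:`pmdecode.gwrf.build_features`).
    Each observation gets its own resample stream keyed by (seed, station,
    date); predictions are batched for speed.

    Returns a table (station_id, date, pm25_raw, pm_dw, mc_se,
    met_contribution).
    """
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    obs = observations.reset_index(drop=True)
    n_obs = len(obs)
    draws_idx = np.empty((n_obs, n_resample), dtype=np.int64)
    for i in range(n_obs):
        rng = _obs_rng(seed, obs.at[i, "station_id"], obs.at[i, "date"])
        draws_idx[i] = rng.integers(0, len(pool), size=n_resample)

    pm_dw = np.empty(n_obs)
    mc_se = np.empty(n_obs)
    per_chunk = max(1, chunk_rows // n_resample)
    for start in range(0, n_obs, per_chunk):
        stop = min(start + per_chunk, n_obs)
        block = obs.iloc[start:stop]
        k = len(block)
        met = pool.records[draws_idx[start:stop].ravel()]
        X = pd.DataFrame(met, columns=MET_FEATURES)
        for col in TIME_FEATURES + ["lat", "lon"]:
            X[col] = np.repeat(block[col].to_numpy(), n_resample)
        preds = model.predict(X).reshape(k, n_resample)
        pm_dw[start:stop] = preds.mean(axis=1)
        if n_resample > 1:
            mc_se[start:stop] = preds.std(axis=1, ddof=1) / np.sqrt(n_resample)
        else:
            mc_se[start:stop] = 0.0

    raw = obs["pm25"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "station_id": obs["station_id"],
            "date": obs["date"],
            "pm25_raw": raw,
            "pm_dw": pm_dw,
            "mc_se": mc_se,
            "met_contribution": met_contribution(raw, pm_dw),
        }
    )


def met_contribution(pm_raw, pm_dw, denominator: str = "dw"):
    """Fractional meteorological contribution (PM_raw - PM_dw) / PM_dw.

    ``denominator="raw"`` switches the reference to the observed value.
    Non-positive denominators yield NaN.
    """
    pm_raw = np.asarray(pm_raw, dtype=float)
    pm_dw = np.asarray(pm_dw, dtype=float)
    den = pm_dw if denominator == "dw" else pm_raw
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, (pm_raw - pm_dw) / den, np.nan)
    if out.ndim == 0:
        return float(out)
    return out
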