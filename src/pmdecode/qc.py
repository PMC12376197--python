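"""Quality control for station PM2.5 series.

Protocol, applied per station in fixed order:

1. physical-range screen — concentrations below 0 or above 1000 ug/m3 are
   excluded (strict inequalities; the boundary values are retained);
2. outlier detection — a point is an outlier when it deviates from its
   15-day centred sliding-window mean by more than 3 window SDs *and* falls
   outside the station's global 0.1/99.9 percentile band (the percentile
   review confirms extremes; an OR combination is available via
   ``combine="or"``).  The candidate point is excluded from its own window
   statistics, and windows shrink at the series edges;
3. outlier replacement by linear interpolation between the nearest valid
   neighbours in time;
4. gap filling — interior missing runs of at most 15 days are linearly
   interpolated; longer runs and runs touching a series edge stay missing.

Flags record the final disposition of each day:
``valid``, ``range_excluded``, ``outlier_replaced``, ``gap_filled``,
``missing_unfilled`` — mutually exclusive, summing to the series length.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLAG_VALID = "valid"
FLAG_RANGE = "range_excluded"
FLAG_OUTLIER = "outlier_replaced"
FLAG_GAP = "gap_filled"
FLAG_MISSING = "missing_unfilled"
FLAGS = [FLAG_VALID, FLAG_RANGE, FLAG_OUTLIER, FLAG_GAP, FLAG_MISSING]

PM_MIN = 0.0
PM_MAX = 1000.0


def screen_physical_range(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Set physically invalid concentrations (<0 or >1000 ug/m3) to NaN.

    Returns (screened values, boolean mask of excluded points).  The rule is
    a strict inequality: exactly 0 and exactly 1000 are retained.
    """
    x = np.asarray(values, dtype=float).copy()
    bad = np.isfinite(x) & ((x < PM_MIN) | (x > PM_MAX))
    x[bad] = np.nan
    return x, bad


def _window_stats_excluding_self(x: np.ndarray, window: int):
    """Centred sliding-window mean/SD/count, excluding the centre point.

    Windows shrink at the edges.  SD is the sample SD (ddof=1) over the
    remaining points.  NaNs never contribute.
    """
    valid = np.isfinite(x)
    xf = np.where(valid, x, 0.0)
    kernel = np.ones(window)

    def conv(a):
        # centred moving sum; robust to series shorter than the window
        out = np.convolve(a, kernel, mode="full")
        half = (window - 1) // 2
        return out[half : half + len(a)]

    cnt = conv(valid.astype(float))
    s = conv(xf)
    ss = conv(xf * xf)
    n_ex = cnt - valid
    s_ex = s - np.where(valid, xf, 0.0)
    ss_ex = ss - np.where(valid, xf * xf, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s_ex / n_ex
        var = (ss_ex - n_ex * mean * mean) / (n_ex - 1.0)
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean, sd, n_ex.astype(int)


def flag_outliers(
    values: np.ndarray,
    window_days: int = 15,
    k_sd: float = 3.0,
    pct_low: float = 0.001,
    pct_high: float = 0.999,
    combine: str = "and",
) -> np.ndarray:
    """Boolean outlier mask for a single daily series.

    A point is flagged iff it lies more than ``k_sd`` sliding-window SDs
    from the window mean (window of ``window_days`` centred on the point,
    excluding it, shrunk at edges) and — under the default ``"and"``
    combination — also outside the series' global
    [``pct_low``, ``pct_high``] quantile band.  Points with fewer than three
    valid neighbours in the window are not evaluable and are left unflagged.
    """
    if window_days < 3 or window_days % 2 == 0:
        raise ValueError("window_days must be odd and >= 3")
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    x = np.asarray(values, dtype=float)
    valid = np.isfinite(x)
    if valid.sum() == 0:
        return np.zeros_like(valid)
    mean, sd, n_ex = _window_stats_excluding_self(x, window_days)
    with np.errstate(invalid="ignore"):
        sliding = np.abs(x - mean) > k_sd * sd
    sliding &= valid & (n_ex >= 3)
    qlo, qhi = np.nanquantile(x, [pct_low, pct_high])
    extreme = valid & ((x < qlo) | (x > qhi))
    return (sliding & extreme) if combine == "and" else (sliding | extreme)


def replace_outliers(values: np.ndarray, flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate flagged points between nearest valid neighbours.

    Returns (values with replacements, boolean mask of points actually
    replaced).  A flagged point without a valid neighbour on one side is
    left as NaN (and not marked replaced).
    """
    x = np.asarray(values, dtype=float).copy()
    flags = np.asarray(flags, dtype=bool)
    good = np.isfinite(x) & ~flags
    idx = np.arange(len(x))
    replaced = np.zeros(len(x), dtype=bool)
    x[flags] = np.nan
    if good.sum() >= 2:
        lo, hi = idx[good].min(), idx[good].max()
        interior = flags & (idx > lo) & (idx < hi)
        x[interior] = np.interp(idx[interior], idx[good], x[good])
        replaced = interior
    return x, replaced


def fill_gaps(values: np.ndarray, max_gap_days: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Fill interior missing runs of length <= max_gap_days by linear interpolation.

    Runs touching either edge of the series and runs longer than the window
    are left missing.  Returns (filled values, boolean mask of filled points).
    """
    x = np.asarray(values, dtype=float).copy()
    n = len(x)
    filled = np.zeros(n, dtype=bool)
    good = np.isfinite(x)
    if good.sum() < 2:
        return x, filled
    idx = np.arange(n)
    miss = ~good
    # enumerate missing runs
    starts = idx[miss & ~np.roll(miss, 1)] if n else []
    if n and miss[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    for s in np.atleast_1d(starts):
        e = s
        while e + 1 < n and miss[e + 1]:
            e += 1
        run_len = e - s + 1
        if s == 0 or e == n - 1 or run_len > max_gap_days:
            continue
        x[s : e + 1] = np.interp(idx[s : e + 1], [s - 1, e + 1], [x[s - 1], x[e + 1]])
        filled[s : e + 1] = True
    return x, filled


def qc_series(
    values: np.ndarray,
    window_days: int = 15,
    k_sd: float = 3.0,
    pct_low: float = 0.001,
    pct_high: float = 0.999,
    max_gap_days: int = 15,
    combine: str = "and",
) -> tuple[np.ndarray, np.ndarray]:
    """Full QC chain for one daily series: screen, flag, replace, fill.

    Returns (clean values, flag array of strings).  Flags report the final
    disposition: a range-excluded or outlier point that is subsequently
    interpolated is reported as replaced/filled.
    """
    x0 = np.asarray(values, dtype=float)
    flags = np.full(len(x0), FLAG_VALID, dtype=object)
    flags[~np.isfinite(x0)] = FLAG_MISSING

    x, range_bad = screen_physical_range(x0)
    flags[range_bad] = FLAG_RANGE

    out_mask = flag_outliers(x, window_days, k_sd, pct_low, pct_high, combine)
    x, replaced = replace_outliers(x, out_mask)
    flags[replaced] = FLAG_OUTLIER
    flags[out_mask & ~replaced] = FLAG_MISSING

    x, filled = fill_gaps(x, max_gap_days)
    flags[filled] = FLAG_GAP
    still_missing = ~np.isfinite(x)
    flags[still_missing & (flags == FLAG_VALID)] = FLAG_MISSING
    # range-excluded points that were never refilled keep their flag
    return x, flags.astype(str)


def apply_qc(pm: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply the QC chain per station on a long (station_id, date, pm25) table.

    Each station is reindexed to the full daily span of the table, so days
    absent from the input participate as missing and may be gap-filled.
    Returns a long table with columns (station_id, date, pm25, qc_flag).
    """
    if len(pm) == 0:
        return pm.assign(qc_flag=pd.Series(dtype=str))
    pm = pm.copy()
    pm["date"] = pd.to_datetime(pm["date"])
    full_range = pd.date_range(pm["date"].min(), pm["date"].max(), freq="D")
    out = []
    for sid, grp in pm.groupby("station_id", sort=True):
        ser = grp.set_index("date")["pm25"].reindex(full_range)
        clean, flags = qc_series(ser.to_numpy(), **kwargs)
        out.append(
            pd.DataFrame(
                {"station_id": sid, "date": full_range, "pm25": clean, "qc_flag": flags}
            )
        )
    return pd.concat(out, ignore_index=True)


def qc_summary(qcd: pd.DataFrame) -> dict[str, int]:
    """Counts per QC flag over a flagged table."""
    counts = qcd["qc_flag"].value_counts().to_dict()
    return {f: int(counts.get(f, 0)) for f in FLAGS}
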