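"""Exposure inequality: Lorenz curves, population-weighted Gini, Theil
decomposition, and the meteorological attribution of inequality.

Inequality is measured over analysis cells (here: county x group cells)
with population weights.  Two index families are used:

- the **Gini coefficient**, computed from the weighted pairwise-difference
  formula G = sum_ij w_i w_j |x_i - x_j| / (2 W^2 xbar), which equals
  1 - 2 * (area under the Lorenz curve) by the trapezoidal rule;
- the **Theil-T index** T = sum_i (w_i/W)(x_i/xbar) ln(x_i/xbar), which
  decomposes exactly into between-group + within-group parts, so each
  group's contribution to total inequality can be reported.

Meteorology's effect on inequality is the relative difference of the Gini
coefficients of deweathered and raw exposure,
100 * (G_dw - G_raw) / G_dw: positive values mean actual meteorology
mitigated the inequality that emissions alone would have produced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _check_inputs(exposures, weights):
    x = np.asarray(exposures, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(x) != len(w):
        raise ValueError("exposures and weights must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(x < 0):
        raise ValueError("exposures must be non-negative")
    return x, w


def lorenz_curve(exposures, weights) -> np.ndarray:
    """Lorenz curve points, including the (0, 0) origin.

    Cells are sorted by ascending exposure; each point is (cumulative
    population share, cumulative population-weighted exposure share).  The
    curve ends at (1, 1).  An all-zero exposure vector degenerates to the
    diagonal (flagged with a warning).
    """
    x, w = _check_inputs(exposures, weights)
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cum_pop = np.cumsum(w) / w.sum()
    total = (x * w).sum()
    if total == 0:
        warnings.warn("all exposures zero: Lorenz curve degenerates to the diagonal")
        cum_exp = cum_pop.copy()
    else:
        cum_exp = np.cumsum(x * w) / total
    return np.column_stack([np.concatenate([[0.0], cum_pop]), np.concatenate([[0.0], cum_exp])])


def gini(exposures, weights) -> float:
    """Population-weighted Gini coefficient (pairwise-difference formula)."""
    x, w = _check_inputs(exposures, weights)
    xbar = (x * w).sum() / w.sum()
    if xbar == 0:
        raise ValueError("mean exposure is zero: Gini undefined")
    diff = np.abs(x[:, None] - x[None, :])
    return float((w[:, None] * w[None, :] * diff).sum() / (2.0 * w.sum() ** 2 * xbar))


def gini_from_lorenz(points: np.ndarray) -> float:
    """Gini as 1 - 2 * trapezoidal area under the Lorenz curve."""
    p, L = points[:, 0], points[:, 1]
    area = float(np.trapezoid(L, p))
    return 1.0 - 2.0 * area


@dataclass
class TheilResult:
    """Theil-T total with exact between/within split and per-group shares."""

    total: float
    between: float
    within: float
    group_contributions: dict[str, float]  # share of total (sums to 1)
    group_absolute: dict[str, float]  # between_g + weighted within_g


def theil_decomposition(exposures, weights, labels) -> TheilResult:
    """Theil-T index with between/within decomposition over a partition.

    Cells with non-positive exposure are excluded (warning): the logarithm
    requires strictly positive values.  The absolute contribution of group
    g is its between-group term plus its population- and exposure-weighted
    within-group term; shares are relative to the total (all zero when the
    distribution is perfectly equal).
    """
    x = np.asarray(exposures, dtype=float)
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    ok = x > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} non-positive exposures excluded from Theil index")
        x, w, labels = x[ok], w[ok], labels[ok]
    if len(x) == 0:
        raise ValueError("no positive exposures")
    W = w.sum()
    xbar = (x * w).sum() / W
    ratio = x / xbar
    total = float(np.sum((w / W) * ratio * np.log(ratio)))

    between = 0.0
    absolute: dict[str, float] = {}
    within = 0.0
    for g in pd.unique(labels):
        m = labels == g
        Wg = w[m].sum()
        xg = (x[m] * w[m]).sum() / Wg
        b_g = (Wg / W) * (xg / xbar) * np.log(xg / xbar)
        r_g = x[m] / xg
        t_g = float(np.sum((w[m] / Wg) * r_g * np.log(r_g)))
        wi_g = (Wg / W) * (xg / xbar) * t_g
        between += b_g
        within += wi_g
        absolute[str(g)] = float(b_g + wi_g)
    if abs(total) > 1e-12:
        shares = {g: v / total for g, v in absolute.items()}
    else:
        shares = {g: 0.0 for g in absolute}
    return TheilResult(
        total=total, between=float(between), within=float(within),
        group_contributions=shares, group_absolute=absolute,
    )


def met_inequality_effect(gini_raw: float, gini_dw: float) -> float:
    """Meteorology's percent effect on exposure inequality.

    100 * (G_dw - G_raw) / G_dw; positive when actual meteorology mitigated
    the inequality present in the emission-driven (deweathered) field.
    """
    if gini_dw == 0:
        if gini_raw == 0:
            return 0.0
        raise ValueError("deweathered Gini is zero: effect undefined")
    return 100.0 * (gini_dw - gini_raw) / gini_dw


@dataclass
class InequalityReport:
    """Paired raw/deweathered inequality summary for one axis and year."""

    axis: str
    year: int
    gini_raw: float
    gini_dw: float
    met_effect_pct: float
    theil_total_raw: float
    theil_total_dw: float
    theil_contributions_dw: dict[str, float]
    lorenz_raw: np.ndarray = field(repr=False)
    lorenz_dw: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "axis": self.axis,
            "year": self.year,
            "gini_raw": round(self.gini_raw, 3),
            "gini_dw": round(self.gini_dw, 3),
            "met_effect_pct": round(self.met_effect_pct, 1),
            "theil_total_raw": self.theil_total_raw,
            "theil_total_dw": self.theil_total_dw,
            "theil_contributions_dw": self.theil_contributions_dw,
            "lorenz_raw": self.lorenz_raw.tolist(),
            "lorenz_dw": self.lorenz_dw.tolist(),
        }


def inequality_report(
    county_field: pd.DataFrame, population: pd.DataFrame, axis: str, year: int
) -> InequalityReport:
    """Build the inequality summary for one stratification axis and year.

    Analysis cells are county x group-label combinations weighted by cell
    population; exposures are the county's kriged raw and deweathered
    concentrations; Theil contributions are decomposed by group label.
    """
    field_y = county_field[county_field["year"] == year]
    pop = population[population["axis"] == axis]
    cells = pop.merge(field_y, on="county_id", how="inner")
    cells = cells[cells["count"] > 0]
    if len(cells) < 2:
        raise ValueError(f"not enough populated cells for axis {axis!r}, year {year}")
    w = cells["count"].to_numpy(dtype=float)
    x_raw = cells["conc_raw"].to_numpy(dtype=float)
    x_dw = cells["conc_dw"].to_numpy(dtype=float)
    g_raw = gini(x_raw, w)
    g_dw = gini(x_dw, w)
    labels = cells["label"].to_numpy()
    return InequalityReport(
        axis=axis,
        year=int(year),
        gini_raw=g_raw,
        gini_dw=g_dw,
        met_effect_pct=met_inequality_effect(g_raw, g_dw),
        theil_total_raw=theil_decomposition(x_raw, w, labels).total,
        theil_total_dw=theil_decomposition(x_dw, w, labels).total,
        theil_contributions_dw=theil_decomposition(x_dw, w, labels).group_contributions,
        lorenz_raw=lorenz_curve(x_raw, w),
        lorenz_dw=lorenz_curve(x_dw, w),
    )
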