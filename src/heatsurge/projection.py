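"""Future exposure matrices by 1 °C-bin row rearrangement, and projection.

Rather than rebuilding a spline basis from the future temperature series,
each future day borrows the *present-day* crossbasis row of the observed
day whose temperature falls in the same 1 °C bin (nearest temperature
within the bin; ties to the earliest date). This keeps the regression
coefficients and the empirical present-day exposure structure applicable
to the shifted series. Future days hotter (or colder) than anything in
the present record are out-of-support: their rows are evaluated directly
from the future lagged temperatures, which is safe because the basis
boundary knots were extended to cover the projected extremes.

Expected daily ED visits follow from the fitted coefficients by
``E[Y] = exp(xᵀβ)`` with delta-method standard errors
``se = E[Y] · sqrt(xᵀ V x)``; non-temperature covariates (day of week,
time trend) stay at their present-day calendar values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .basis import CrossBasis, build_crossbasis
from .models import Design, FitResult

__all__ = [
    "ScenarioTemps",
    "ProjectionSeries",
    "bin_edges",
    "assign_bins",
    "rearrange_future_matrix",
    "predict_series",
    "apply_monthly_deltas",
    "project_county",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioTemps:
    """Future daily maximum temperatures for one GCM × SSP."""

    gcm: str
    ssp: str
    future_tmax: np.ndarray


@dataclass
class ProjectionSeries:
    """Expected daily ED visits with standard errors."""

    dates: pd.DatetimeIndex
    expected: np.ndarray
    se: np.ndarray
    source: str  # "present" or "gcm/ssp"

    def annual_total(self) -> float:
        """Mean total expected visits per calendar year."""
        years = self.dates.year
        return float(pd.Series(self.expected).groupby(np.asarray(years)).sum().mean())


def bin_edges(present_temps: np.ndarray) -> np.ndarray:
    """1 °C bin edges anchored at whole degrees covering the present range.

    Bins are half-open ``[a, a+1)``; the final bin starts at
    ``floor(max)`` so the observed maximum is always in-support.
    """
    present_temps = np.asarray(present_temps, dtype=float)
    lo = np.floor(present_temps.min())
    hi = np.floor(present_temps.max()) + 1.0
    return np.arange(lo, hi + 0.5)


def assign_bins(temps, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map each day to a 1 °C bin index; flag days outside the grid.

    Returns ``(bin_index, out_of_support)``; out-of-support days get
    bin index −1.
    """
    temps = np.asarray(temps, dtype=float)
    idx = np.floor(temps - edges[0]).astype(int)
    out = (temps < edges[0]) | (temps >= edges[-1])
    idx[out] = -1
    return idx, out


def rearrange_future_matrix(
    present_cb: CrossBasis,
    present_temps,
    future_temps,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Future crossbasis rows by 1 °C-bin rearrangement of present rows.

    For each future day in-support: donor = the present non-burn-in day in
    the same bin with the nearest temperature (ties → earliest date); the
    future row is a copy of the donor's row. An in-support bin with no
    donors falls back to the nearest populated bin (warned). Out-of-support
    days get rows evaluated directly from the future lagged series.

    Returns ``(rows, out_of_support, donor_index)`` over all days; burn-in
    handling is inherited from ``present_cb`` (donors exclude burn-in days,
    and callers should drop the same burn-in rows they drop when fitting).
    ``donor_index`` is −1 for out-of-support days.
    """
    present_temps = np.asarray(present_temps, dtype=float)
    future_temps = np.asarray(future_temps, dtype=float)
    if future_temps.size != present_temps.size:
        raise ValueError("future series must share the present series' calendar")
    edges = bin_edges(present_temps)
    donors_ok = ~present_cb.burn_in
    p_bins, _ = assign_bins(present_temps, edges)
    f_bins, out = assign_bins(future_temps, edges)

    # donor lookup per bin, sorted by (temperature, date) so searchsorted
    # lands on the earliest among equal temperatures
    by_bin: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    donor_days = np.flatnonzero(donors_ok)
    for b in np.unique(p_bins[donor_days]):
        days = donor_days[p_bins[donor_days] == b]
        order = np.lexsort((days, present_temps[days]))
        days = days[order]
        by_bin[int(b)] = (present_temps[days], days)
    populated = np.array(sorted(by_bin.keys()))

    n = future_temps.size
    donor_index = np.full(n, -1, dtype=int)
    fallback_count = 0
    for day in np.flatnonzero(~out):
        b = int(f_bins[day])
        if b not in by_bin:
            b = int(populated[np.argmin(np.abs(populated - b))])
            fallback_count += 1
        temps_b, days_b = by_bin[b]
        t = future_temps[day]
        pos = np.searchsorted(temps_b, t)
        best, bestd = None, np.inf
        for cand in (pos - 1, pos):
            if 0 <= cand < temps_b.size:
                d = abs(temps_b[cand] - t)
                # strict < keeps the earlier-date donor on exact distance ties
                if d < bestd or (d == bestd and best is not None and days_b[cand] < best):
                    best, bestd = int(days_b[cand]), d
        donor_index[day] = best
    if fallback_count:
        logger.warning(
            "%d in-support future day(s) fell in empty bins; used nearest populated bin",
            fallback_count,
        )

    rows = np.empty_like(present_cb.matrix)
    in_sup = ~out
    rows[in_sup] = present_cb.matrix[donor_index[in_sup]]
    if out.any():
        future_cb = build_crossbasis(future_temps, present_cb.spec)
        rows[out] = future_cb.matrix[out]
    return rows, out, donor_index


def predict_series(
    fit: FitResult, X: np.ndarray, dates: pd.DatetimeIndex, source: str = "present"
) -> ProjectionSeries:
    """Expected visits and delta-method standard errors for design rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != fit.beta.size:
        raise ValueError(f"design has {X.shape[1]} columns, fit has {fit.beta.size}")
    eta = X @ fit.beta
    expected = np.exp(eta)
    var_eta = np.maximum(np.einsum("ti,ij,tj->t", X, fit.vcov, X), 0.0)
    return ProjectionSeries(
        dates=dates, expected=expected, se=expected * np.sqrt(var_eta), source=source
    )


def apply_monthly_deltas(
    dates: pd.DatetimeIndex, tmax: np.ndarray, deltas: pd.DataFrame
) -> np.ndarray:
    """Add monthly warming deltas (broadcast to the days of each month)."""
    by_month = deltas.set_index("month")["delta_c"]
    missing = set(range(1, 13)) - set(by_month.index)
    if missing:
        raise ValueError(f"scenario missing months {sorted(missing)}")
    return np.asarray(tmax, dtype=float) + by_month.reindex(dates.month).to_numpy()


def _swap_crossbasis(design: Design, fit: FitResult, new_rows: np.ndarray) -> np.ndarray:
    X = design.X.copy()
    X[:, design.column_map["crossbasis"]] = new_rows[design.row_index]
    return X


def project_county(
    fit: FitResult,
    design: Design,
    present_cb: CrossBasis,
    dates: pd.DatetimeIndex,
    scenario: ScenarioTemps | None = None,
) -> ProjectionSeries:
    """Present-day or scenario projection for one fitted county.

    The non-burn-in calendar (``design.row_index``) defines the projected
    days; scenario projections reuse the present-day covariate rows and
    swap only the crossbasis block.
    """
    kept_dates = dates[design.row_index]
    if scenario is None:
        return predict_series(fit, design.X, kept_dates, source="present")
    rows, _, _ = rearrange_future_matrix(present_cb, present_cb.temps, scenario.future_tmax)
    X = _swap_crossbasis(design, fit, rows)
    return predict_series(fit, X, kept_dates, source=f"{scenario.gcm}/{scenario.ssp}")
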