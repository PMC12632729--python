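"""High-healthcare-utilization days: thresholds, exceedances, summaries.

A "high utilization" day is one whose daily ED visit count strictly
exceeds the county- and year-specific 95th percentile of daily counts.
The percentile uses the ceiling-rank empirical-CDF convention (order
statistic at rank ⌈n·p⌉): for a 365-day year of distinct counts this
leaves exactly 18 days above threshold, which anchors the increase
milestones of 27 days (+50%), 36 days (doubled) and 45 days (+150%).
Future series are always compared against the matching *present-day*
year's threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BASELINE_EXCEED_DAYS",
    "INCREASE_MILESTONES",
    "utilization_threshold",
    "count_exceedances",
    "annual_thresholds",
    "UtilizationReport",
    "exceedance_change_summary",
]

BASELINE_EXCEED_DAYS = 18  # distinct-count 365-day year at p = 0.95

# milestone day-counts derived from the 18-day baseline
INCREASE_MILESTONES = {
    "50pct_increase": 27,   # 18 × 1.5
    "100pct_increase": 36,  # 18 × 2
    "150pct_increase": 45,  # 18 × 2.5
}

MIN_DAYS_PER_YEAR = 300


def utilization_threshold(daily_counts, p: float = 0.95) -> float:
    """County-year threshold: order statistic at rank ⌈n·p⌉ (1-based).

    The ceiling-rank (empirical-CDF) quantile is used rather than an
    interpolating convention: with 365 distinct values exactly
    ``365 − ⌈365·0.95⌉ = 18`` days strictly exceed it.
    """
    x = np.asarray(daily_counts, dtype=float)
    if x.size < MIN_DAYS_PER_YEAR:
        raise ValueError(f"need >= {MIN_DAYS_PER_YEAR} days per county-year, got {x.size}")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    rank = math.ceil(x.size * p)
    return float(np.sort(x)[rank - 1])


def annual_thresholds(dates: pd.DatetimeIndex, counts, p: float = 0.95) -> dict[int, float]:
    """Per-calendar-year thresholds from a present-day daily series."""
    counts = np.asarray(counts, dtype=float)
    years = np.asarray(dates.year)
    return {
        int(y): utilization_threshold(counts[years == y], p) for y in np.unique(years)
    }


def count_exceedances(
    dates: pd.DatetimeIndex, values, thresholds: dict[int, float]
) -> dict[int, int]:
    """Days per year strictly above that year's (present-day) threshold."""
    values = np.asarray(values, dtype=float)
    years = np.asarray(dates.year)
    out = {}
    for y in np.unique(years):
        y = int(y)
        if y not in thresholds:
            raise ValueError(f"no present-day threshold for year {y}")
        out[y] = int((values[years == y] > thresholds[y]).sum())
    return out


@dataclass
class UtilizationReport:
    """Per-county exceedance-day accounting, present vs future scenarios."""

    county: str
    thresholds: dict[int, float]
    n_exceed_present: dict[int, int]
    n_exceed_future: dict[str, dict[int, int]] = field(default_factory=dict)  # key "gcm/ssp"

    def mean_present(self) -> float:
        return float(np.mean(list(self.n_exceed_present.values())))

    def mean_future(self, ssp: str | None = None) -> float:
        """Mean future exceedance days per year, averaged over GCMs."""
        per_gcm = [
            np.mean(list(v.values()))
            for k, v in self.n_exceed_future.items()
            if ssp is None or k.endswith(f"/{ssp}")
        ]
        if not per_gcm:
            raise ValueError(f"no future scenarios recorded for ssp={ssp!r}")
        return float(np.mean(per_gcm))


def exceedance_change_summary(
    reports: list[UtilizationReport], ssp: str | None = None, max_days: int = 120
) -> dict:
    """County proportions passing the 27/36/45-day milestones, plus the
    cumulative distribution of mean future exceedance days.

    Milestones follow their definitions literally: strictly more than 27
    (>50% increase) and more than 36 days (doubling), and 45 or more days
    (a 150% increase).
    """
    if not reports:
        raise ValueError("no utilization reports")
    means = np.array([r.mean_future(ssp) for r in reports])
    n = means.size
    proportions = {
        "50pct_increase": float((means > INCREASE_MILESTONES["50pct_increase"]).mean()),
        "100pct_increase": float((means > INCREASE_MILESTONES["100pct_increase"]).mean()),
        "150pct_increase": float((means >= INCREASE_MILESTONES["150pct_increase"]).mean()),
    }
    grid = np.arange(0, max_days + 1)
    cumulative = pd.DataFrame(
        {
            "min_days": grid,
            "prop_counties": [(means >= d).mean() for d in grid],
        }
    )
    return {
        "n_counties": n,
        "mean_future_days": means,
        "proportions": proportions,
        "cumulative": cumulative,
    }
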