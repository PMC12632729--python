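"""Two-stage bootstrap of present-vs-future differences in ED visits.

Stage one treats each day's present and future expected counts (with
their delta-method standard errors) as two normal distributions and draws
250 samples of the future-minus-present difference per GCM. Stage two
combines the GCMs within an SSP by resampling the pooled per-day draws,
yielding a mean difference and a 2.5/97.5 empirical confidence interval
(eCI) that reflects the spread around the combined estimate rather than
the range across GCMs. Regional/monthly summaries resample one draw per
county-day per iteration and sum, so the eCI of any aggregate is the
percentile interval of iteration-level sums.

All randomness derives from a single master seed through hierarchical
substreams keyed by (county, GCM, stage), so adding a GCM or county
never perturbs the other streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import ProjectionSeries

__all__ = [
    "substream",
    "DifferenceSamples",
    "DifferenceSummary",
    "RegionalSummary",
    "bootstrap_difference",
    "pool_draws",
    "combine_gcms",
    "summarize_region_month",
    "annual_change_pct",
]

N_DRAWS = 250


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Independent generator derived from the master seed and string keys."""
    tokens = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, *tokens]))


@dataclass
class DifferenceSamples:
    """Per-day bootstrap draws of future − present expected visits."""

    draws: np.ndarray  # (n_draws, n_days)
    dates: pd.DatetimeIndex
    gcm: str
    ssp: str


@dataclass
class DifferenceSummary:
    """Per-day combined difference with empirical 95% CI."""

    dates: pd.DatetimeIndex
    mean: np.ndarray
    eci_lo: np.ndarray
    eci_hi: np.ndarray
    ssp: str


def bootstrap_difference(
    present: ProjectionSeries,
    future: ProjectionSeries,
    n_draws: int = N_DRAWS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    gcm: str = "",
    ssp: str = "",
) -> DifferenceSamples:
    """Draw ``future_k − present_k`` with each term Normal(expected, se)."""
    if len(present.dates) != len(future.dates) or not (present.dates == future.dates).all():
        raise ValueError("present and future series must share a calendar")
    for s in (present, future):
        if np.any(s.se < 0):
            raise ValueError("negative standard error")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_days = present.expected.size
    fut = rng.normal(future.expected, future.se, size=(n_draws, n_days))
    pres = rng.normal(present.expected, present.se, size=(n_draws, n_days))
    if not gcm and "/" in future.source:
        gcm, ssp = future.source.split("/", 1)
    return DifferenceSamples(draws=fut - pres, dates=present.dates, gcm=gcm, ssp=ssp)


def pool_draws(samples: list[DifferenceSamples]) -> DifferenceSamples:
    """Stack per-GCM draws for one SSP into a single pooled sample set."""
    if not samples:
        raise ValueError("no GCM samples to pool")
    ssp = samples[0].ssp
    for s in samples[1:]:
        if s.ssp != ssp or len(s.dates) != len(samples[0].dates):
            raise ValueError("samples must share SSP and calendar")
    return DifferenceSamples(
        draws=np.vstack([s.draws for s in samples]),
        dates=samples[0].dates,
        gcm="*",
        ssp=ssp,
    )


def combine_gcms(
    samples: list[DifferenceSamples],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    n_iter: int = N_DRAWS,
    chunk: int = 64,
) -> DifferenceSummary:
    """Combine GCM draw sets within an SSP by a second bootstrap.

    Per day, the pooled draws across GCMs are resampled with replacement
    ``n_iter`` times; the summary is the mean and the 2.5/97.5 percentiles
    of the resampled means.
    """
    pooled = pool_draws(samples)
    if rng is None:
        rng = np.random.default_rng(seed)
    m, n_days = pooled.draws.shape
    means = np.empty((n_iter, n_days))
    for start in range(0, n_days, chunk):
        sl = slice(start, min(start + chunk, n_days))
        days = np.arange(sl.start, sl.stop)
        idx = rng.integers(0, m, size=(n_iter, m, days.size))
        vals = pooled.draws[idx, days[None, None, :]]
        means[:, sl] = vals.mean(axis=1)
    return DifferenceSummary(
        dates=pooled.dates,
        mean=means.mean(axis=0),
        eci_lo=np.percentile(means, 2.5, axis=0),
        eci_hi=np.percentile(means, 97.5, axis=0),
        ssp=pooled.ssp,
    )


@dataclass
class RegionalSummary:
    """Monthly/annual regional sums of the combined difference.

    ``monthly_samples[region]`` holds iteration-level average-annual sums
    per calendar month, shape ``(n_iter, 12)``; the national aggregate is
    the sum over regions per iteration (partition conservation is exact).
    """

    monthly_samples: dict[str, np.ndarray]
    ssp: str

    def annual_samples(self, region: str | None = None) -> np.ndarray:
        if region is not None:
            return self.monthly_samples[region].sum(axis=1)
        return sum(v for v in self.monthly_samples.values()).sum(axis=1)

    def table(self) -> pd.DataFrame:
        rows = []
        for region, arr in sorted(self.monthly_samples.items()):
            for m in range(12):
                col = arr[:, m]
                rows.append(
                    {
                        "region": region,
                        "ssp": self.ssp,
                        "month": m + 1,
                        "mean_diff": col.mean(),
                        "eci_lo": np.percentile(col, 2.5),
                        "eci_hi": np.percentile(col, 97.5),
                    }
                )
        return pd.DataFrame(rows)

    def annual_table(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self.monthly_samples):
            a = self.annual_samples(region)
            rows.append(
                {
                    "region": region,
                    "ssp": self.ssp,
                    "annual_mean_diff": a.mean(),
                    "eci_lo": np.percentile(a, 2.5),
                    "eci_hi": np.percentile(a, 97.5),
                }
            )
        nat = self.annual_samples()
        rows.append(
            {
                "region": "All",
                "ssp": self.ssp,
                "annual_mean_diff": nat.mean(),
                "eci_lo": np.percentile(nat, 2.5),
                "eci_hi": np.percentile(nat, 97.5),
            }
        )
        return pd.DataFrame(rows)


def summarize_region_month(
    county_samples: dict[str, DifferenceSamples],
    region_map: dict[str, str],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    n_iter: int = N_DRAWS,
) -> RegionalSummary:
    """Bootstrap monthly sums of county differences to the region level.

    Each iteration samples one draw per county-day, sums within calendar
    month (averaged over the years of the series) and accumulates county
    sums into their region. Reported values are therefore average *annual*
    additional visits per month; the annual rollup is the sum of months.
    """
    if not county_samples:
        raise ValueError("no county samples")
    unmapped = [c for c in county_samples if c not in region_map]
    if unmapped:
        raise ValueError(f"county not in region map: {unmapped[0]}")
    if rng is None:
        rng = np.random.default_rng(seed)
    ssp = next(iter(county_samples.values())).ssp
    monthly: dict[str, np.ndarray] = {}
    for county in sorted(county_samples):
        s = county_samples[county]
        n_draws, n_days = s.draws.shape
        months = s.dates.month.to_numpy() - 1
        n_years = s.dates.year.nunique()
        idx = rng.integers(0, n_draws, size=(n_iter, n_days))
        vals = s.draws[idx, np.arange(n_days)]  # (n_iter, n_days)
        sums = np.zeros((n_iter, 12))
        for m in range(12):
            sums[:, m] = vals[:, months == m].sum(axis=1)
        sums /= n_years
        region = region_map[county]
        monthly[region] = monthly.get(region, 0) + sums
    return RegionalSummary(monthly_samples=monthly, ssp=ssp)


def annual_change_pct(present: ProjectionSeries, combined: DifferenceSummary) -> float:
    """Percent change in annual ED visits: 100 × mean annual summed
    difference / mean annual summed present expectation."""
    if len(present.dates) != len(combined.dates):
        raise ValueError("present series and combined summary must share a calendar")
    present_total = float(present.expected.sum())
    if present_total <= 0:
        raise ValueError("present expected total must be positive")
    return 100.0 * float(combined.mean.sum()) / present_total
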