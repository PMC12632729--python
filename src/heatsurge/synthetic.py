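"""Synthetic county panels and warming-scenario deltas with known truth.

Real inputs for this kind of analysis — insurance-claims ED counts,
population-weighted reanalysis temperatures, climate-model projections —
are restricted or bulky. This module generates stand-ins with a *known*
exposure-response relationship so every downstream stage (crossbasis,
quasi-Poisson fit, lag reduction, projection, bootstrap, utilization
metrics) can be validated against ground truth.

Per county it simulates:

* daily maximum temperature = seasonal sinusoid (summer peak) + AR(1) noise,
* overdispersed daily ED counts whose log-rate combines a baseline, a
  long-term trend, day-of-week effects, and a known cumulative lagged
  temperature effect distributed over lags 0..L by fixed weights,
* annual enrollment levels,

plus per-GCM monthly warming deltas interpolated between a winter and a
summer draw (order 1-3 °C, larger in summer), mimicking mid-century
scenario output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CountyPanel

__all__ = [
    "TrueExposureResponse",
    "SimConfig",
    "NCA4_REGIONS",
    "gen_temperature",
    "gen_counts",
    "gen_panel",
    "gen_panels",
    "gen_scenario_deltas",
    "default_truth",
    "write_panels",
    "read_panels",
    "write_scenarios",
    "read_scenarios",
    "read_region_map",
]

logger = logging.getLogger(__name__)

NCA4_REGIONS = (
    "Southeast",
    "Southwest",
    "Northern Great Plains",
    "Southern Great Plains",
    "Midwest",
    "Northeast",
    "Northwest",
)

PANEL_COLUMNS = ["county", "date", "tmax_c", "ed_visits", "enrollees"]
SCENARIO_COLUMNS = ["gcm", "ssp", "month", "delta_c"]

_PEAK_DOY = 196  # mid-July
_AR1_PHI = 0.7


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TrueExposureResponse:
    """Ground-truth cumulative exposure-response and lag profile.

    ``log_rr`` is the cumulative (summed over lags) log relative risk at
    each grid temperature; ``lag_weights`` distribute it over lags 0..L
    and sum to one.
    """

    temp_grid: np.ndarray
    log_rr: np.ndarray
    lag_weights: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.temp_grid, dtype=float)
        lrr = np.asarray(self.log_rr, dtype=float)
        w = np.asarray(self.lag_weights, dtype=float)
        object.__setattr__(self, "temp_grid", grid)
        object.__setattr__(self, "log_rr", lrr)
        object.__setattr__(self, "lag_weights", w)
        if grid.shape != lrr.shape:
            raise ConfigError("temp_grid and log_rr must have matching shapes")
        if not np.all(np.isfinite(lrr)):
            raise ConfigError("log_rr must be finite on the grid")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ConfigError("lag_weights must be non-negative and sum to 1")

    @property
    def max_lag(self) -> int:
        return self.lag_weights.size - 1

    def log_rr_at(self, temps: np.ndarray) -> np.ndarray:
        """Cumulative log-RR at arbitrary temperatures; linear beyond the
        grid (matching natural-spline tail behaviour)."""
        temps = np.asarray(temps, dtype=float)
        g, v = self.temp_grid, self.log_rr
        out = np.interp(temps, g, v)
        below, above = temps < g[0], temps > g[-1]
        if below.any() or above.any():
            logger.warning(
                "extrapolating true log-RR for %d day(s) outside [%.1f, %.1f] degC",
                int(below.sum() + above.sum()), g[0], g[-1],
            )
            slope_lo = (v[1] - v[0]) / (g[1] - g[0])
            slope_hi = (v[-1] - v[-2]) / (g[-1] - g[-2])
            out[below] = v[0] + slope_lo * (temps[below] - g[0])
            out[above] = v[-1] + slope_hi * (temps[above] - g[-1])
        return out


def default_truth(
    max_log_rr: float = np.log(1.10),
    temp_range: tuple[float, float] = (-15.0, 40.0),
    max_lag: int = 5,
    decay: float = 0.6,
) -> TrueExposureResponse:
    """Monotone-increasing truth: risk flat at cold, rising smoothly to
    ``max_log_rr`` at the hottest grid point, with geometric lag decay."""
    grid = np.arange(temp_range[0], temp_range[1] + 0.5, 1.0)
    z = (grid - 18.0) / 8.0  # risk ramps up above ~18 degC
    curve = max_log_rr / (1.0 + np.exp(-z))
    curve = curve - curve[0]
    curve *= max_log_rr / curve[-1]
    w = decay ** np.arange(max_lag + 1)
    return TrueExposureResponse(grid, curve, w / w.sum())


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults give a plausible mid-size county."""

    n_counties: int = 5
    n_years: int = 3
    seed: int = 0
    start_year: int = 2010
    base_rate: float = 50.0  # expected daily ED visits
    dispersion: float = 1.5  # var / mean of daily counts
    dow_effects: tuple[float, ...] = (1.08, 1.0, 0.97, 0.97, 1.0, 0.95, 1.03)  # Mon..Sun
    trend_amplitude: float = 0.05  # peak log-rate drift over the series
    temp_mean: float = 15.0
    temp_amplitude: float = 10.0
    temp_noise_sd: float = 2.0
    enrollees_per_year: int = 10_000

    def __post_init__(self):
        if self.n_counties < 1 or self.n_years < 1 or self.enrollees_per_year < 1:
            raise ConfigError("counts must be positive")
        if self.dispersion < 1:
            raise ConfigError("dispersion must be >= 1")
        if len(self.dow_effects) != 7 or any(e <= 0 for e in self.dow_effects):
            raise ConfigError("dow_effects must be 7 positive factors")
        if self.base_rate <= 0:
            raise ConfigError("base_rate must be positive")


def _rng(config: SimConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, *keys]))


def sim_dates(config: SimConfig) -> pd.DatetimeIndex:
    """Real Gregorian calendar (leap days included)."""
    return pd.date_range(
        start=f"{config.start_year}-01-01",
        end=f"{config.start_year + config.n_years - 1}-12-31",
        freq="D",
    )


def gen_temperature(config: SimConfig, county_index: int = 0) -> np.ndarray:
    """Daily maximum temperature: seasonal sinusoid + AR(1) noise."""
    if config.n_years < 1:
        raise ConfigError("n_years must be >= 1")
    dates = sim_dates(config)
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = config.temp_mean + config.temp_amplitude * np.cos(
        2 * np.pi * (doy - _PEAK_DOY) / 365.25
    )
    n = seasonal.size
    rng = _rng(config, 1, county_index)
    if config.temp_noise_sd > 0:
        innov_sd = config.temp_noise_sd * np.sqrt(1 - _AR1_PHI**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.temp_noise_sd)
        for t in range(1, n):
            noise[t] = _AR1_PHI * noise[t - 1] + eps[t]
    else:
        noise = np.zeros(n)
    return seasonal + noise


def expected_rate(
    temps: np.ndarray, truth: TrueExposureResponse, config: SimConfig, dates: pd.DatetimeIndex
) -> np.ndarray:
    """Deterministic daily mean: base rate × trend × day-of-week × lagged
    temperature effect (truncated lag sums in the first L days)."""
    n = temps.size
    L = truth.max_lag
    if n < L + 1:
        raise ConfigError(f"series length {n} must be at least max_lag+1 = {L + 1}")
    lag_effect = np.zeros(n)
    daily_lrr = truth.log_rr_at(temps)
    for lag, w in enumerate(truth.lag_weights):
        lag_effect[lag:] += w * daily_lrr[: n - lag]
    t = np.arange(n, dtype=float)
    trend = config.trend_amplitude * (2 * t / max(n - 1, 1) - 1.0) / 2.0
    dow = np.asarray(config.dow_effects)[dates.dayofweek.to_numpy()]
    return config.base_rate * np.exp(trend + np.log(dow) + lag_effect)


def gen_counts(
    temps: np.ndarray,
    truth: TrueExposureResponse,
    config: SimConfig,
    county_index: int = 0,
    dates: pd.DatetimeIndex | None = None,
) -> np.ndarray:
    """Overdispersed daily counts around :func:`expected_rate`.

    Quasi-Poisson prescribes only var = dispersion × mean, so draws come
    from a negative binomial parameterized to that variance (Poisson when
    dispersion = 1).
    """
    if dates is None:
        dates = sim_dates(config)
    mu = expected_rate(np.asarray(temps, dtype=float), truth, config, dates)
    rng = _rng(config, 2, county_index)
    phi = config.dispersion
    if phi == 1.0:
        return rng.poisson(mu).astype(np.int64)
    # NB with var = mu + mu^2/size = phi*mu  =>  size = mu/(phi-1)
    size = mu / (phi - 1.0)
    return rng.negative_binomial(size, 1.0 / phi).astype(np.int64)


def _gen_enrollees(config: SimConfig, county_index: int, years: np.ndarray) -> dict[int, int]:
    rng = _rng(config, 3, county_index)
    jitter = 1.0 + 0.05 * rng.uniform(-1.0, 1.0, size=years.size)
    return {int(y): int(round(config.enrollees_per_year * j)) for y, j in zip(years, jitter)}


def gen_panel(
    config: SimConfig,
    county_index: int = 0,
    truth: TrueExposureResponse | None = None,
    region: str | None = None,
) -> CountyPanel:
    """One synthetic county panel (validated)."""
    if truth is None:
        truth = default_truth()
    dates = sim_dates(config)
    temps = gen_temperature(config, county_index)
    counts = gen_counts(temps, truth, config, county_index, dates)
    years = dates.year.to_numpy()
    enroll_by_year = _gen_enrollees(config, county_index, np.unique(years))
    df = pd.DataFrame(
        {
            "date": dates,
            "tmax_c": temps,
            "ed_visits": counts,
            "enrollees": [enroll_by_year[int(y)] for y in years],
        }
    )
    if region is None:
        region = NCA4_REGIONS[county_index % len(NCA4_REGIONS)]
    return CountyPanel(county=f"C{county_index:03d}", region=region, data=df)


def gen_panels(
    config: SimConfig, truth: TrueExposureResponse | None = None
) -> list[CountyPanel]:
    return [gen_panel(config, i, truth) for i in range(config.n_counties)]


def gen_scenario_deltas(
    n_gcms: int,
    summer_delta_range: tuple[float, float] = (1.6, 3.3),
    winter_delta_range: tuple[float, float] = (1.2, 2.0),
    seed: int = 0,
    ssp: str = "SSP5-8.5",
) -> pd.DataFrame:
    """Per-GCM monthly additive warming deltas (°C).

    For each GCM a winter and a summer delta are drawn uniformly from the
    given ranges, then the 12 monthly deltas follow a cosine interpolation
    peaking in July. Defaults match mid-century high-emission magnitudes
    (summer 1.6-3.3 °C, winter 1.2-2.0 °C).
    """
    if n_gcms < 1:
        raise ConfigError("n_gcms must be >= 1")
    for name, (lo, hi) in (("summer", summer_delta_range), ("winter", winter_delta_range)):
        if lo > hi:
            raise ConfigError(f"{name}_delta_range bounds reversed: ({lo}, {hi})")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 4]))
    months = np.arange(1, 13)
    weight = (1.0 - np.cos(2 * np.pi * (months - 1) / 12)) / 2.0  # 0 in Jan, 1 in Jul
    rows = []
    for g in range(n_gcms):
        w = rng.uniform(*winter_delta_range)
        s = rng.uniform(*summer_delta_range)
        deltas = w + (s - w) * weight
        for m, d in zip(months, deltas):
            rows.append({"gcm": f"GCM{g + 1:02d}", "ssp": ssp, "month": int(m), "delta_c": d})
    return pd.DataFrame(rows, columns=SCENARIO_COLUMNS)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_panels(panels: list[CountyPanel], path) -> None:
    frames = []
    for p in panels:
        df = p.data[["date", "tmax_c", "ed_visits", "enrollees"]].copy()
        df.insert(0, "county", p.county)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.6f")


def read_panels(path, region_map: dict[str, str] | None = None) -> list[CountyPanel]:
    df = pd.read_csv(path, parse_dates=["date"])
    panels = []
    for county, grp in df.groupby("county", sort=True):
        region = (region_map or {}).get(str(county), "")
        panels.append(
            CountyPanel(county=str(county), region=region, data=grp.drop(columns="county").reset_index(drop=True))
        )
    return panels


def write_scenarios(deltas: pd.DataFrame, path) -> None:
    deltas.to_csv(path, index=False, float_format="%.6f", columns=SCENARIO_COLUMNS)


def read_scenarios(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SCENARIO_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"scenario file missing columns {sorted(missing)}")
    return df[SCENARIO_COLUMNS]


def write_region_map(panels: list[CountyPanel], path) -> None:
    pd.DataFrame(
        {"county": [p.county for p in panels], "region": [p.region for p in panels]}
    ).to_csv(path, index=False)


def read_region_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["county"].astype(str), df["region"].astype(str)))
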