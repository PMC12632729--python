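"""County daily panels and the county-level quasi-Poisson regression.

Each county contributes a contiguous daily time series of maximum
temperature, all-cause emergency department (ED) visit counts, and annual
health-plan enrollment. Counties with 500 or fewer enrollees in any year
are excluded; within retained counties, daily counts are adjusted for
year-to-year enrollment drift before model fitting.

The regression is a quasi-Poisson generalized linear model (log link,
variance proportional to the mean) of daily ED visits on the lagged
temperature crossbasis, day-of-week dummies and a long-term time spline
with 8 degrees of freedom per year.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import CrossBasis, DataValidationError, NaturalSpline

__all__ = [
    "CountyPanel",
    "FitResult",
    "Design",
    "filter_counties",
    "adjust_counts",
    "build_design",
    "fit_quasipoisson",
    "fit_county",
]

# pandas dayofweek: Monday=0 .. Sunday=6; Sunday is the reference level
DOW_LEVELS = ("mon", "tue", "wed", "thu", "fri", "sat")
MIN_ENROLLEES = 500


@dataclass
class CountyPanel:
    """One county's daily panel.

    ``data`` columns: ``date`` (daily, contiguous), ``tmax_c``,
    ``ed_visits`` (non-negative), ``enrollees`` (constant within each
    calendar year). ``ed_adjusted`` is added by :func:`adjust_counts`.
    """

    county: str
    region: str
    data: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        required = {"date", "tmax_c", "ed_visits", "enrollees"}
        missing = required - set(df.columns)
        if missing:
            raise DataValidationError(f"county {self.county}: missing columns {sorted(missing)}")
        dates = pd.to_datetime(df["date"])
        gaps = np.flatnonzero(dates.diff().dt.days.iloc[1:].to_numpy() != 1)
        if gaps.size:
            after = dates.iloc[int(gaps[0])].date()
            raise DataValidationError(f"county {self.county}: date gap after {after}")
        if (df["ed_visits"] < 0).any():
            raise DataValidationError(f"county {self.county}: negative ED visit count")
        per_year = df.groupby(dates.dt.year)["enrollees"].nunique()
        if (per_year != 1).any():
            yr = int(per_year[per_year != 1].index[0])
            raise DataValidationError(
                f"county {self.county}: enrollees not constant within year {yr}"
            )

    @property
    def dates(self) -> pd.Series:
        return pd.to_datetime(self.data["date"])

    @property
    def tmax(self) -> np.ndarray:
        return self.data["tmax_c"].to_numpy(dtype=float)

    @property
    def n_years(self) -> int:
        return int(self.dates.dt.year.nunique())

    def annual_enrollees(self) -> pd.Series:
        return self.data.groupby(self.dates.dt.year)["enrollees"].first()

    @property
    def counts(self) -> np.ndarray:
        col = "ed_adjusted" if "ed_adjusted" in self.data.columns else "ed_visits"
        return self.data[col].to_numpy(dtype=float)


def filter_counties(panels: list[CountyPanel]) -> list[CountyPanel]:
    """Retain counties with more than 500 enrollees in every year."""
    kept = []
    for p in panels:
        enroll = p.annual_enrollees()
        if enroll.isna().any():
            raise DataValidationError(f"county {p.county}: missing enrollee year")
        if (enroll > MIN_ENROLLEES).all():
            kept.append(p)
    return kept


def adjust_counts(panel: CountyPanel, mode: str = "rescale") -> CountyPanel:
    """Adjust daily counts for annual enrollment drift.

    ``rescale`` (default) multiplies each day's count by
    ``mean annual enrollment / that year's enrollment``, yielding
    real-valued adjusted counts on a common enrollment denominator.
    ``offset`` leaves counts untouched and records ``log(enrollees /
    reference)`` in an ``offset`` column for use as a GLM offset.
    """
    if mode not in ("rescale", "offset"):
        raise ValueError(f"unknown adjustment mode {mode!r}")
    enroll = panel.annual_enrollees()
    if (enroll <= 0).any():
        raise DataValidationError(f"county {panel.county}: non-positive enrollment")
    reference = float(enroll.mean())
    df = panel.data.copy()
    year_enroll = df["enrollees"].to_numpy(dtype=float)
    if mode == "rescale":
        df["ed_adjusted"] = df["ed_visits"].to_numpy(dtype=float) * (reference / year_enroll)
    else:
        df["offset"] = np.log(year_enroll / reference)
    return CountyPanel(county=panel.county, region=panel.region, data=df)


@dataclass
class Design:
    """Model matrix for one county (burn-in rows already dropped)."""

    X: np.ndarray
    y: np.ndarray
    column_map: dict[str, list[int]]
    names: list[str]
    row_index: np.ndarray  # positions into the panel's day axis
    offset: np.ndarray | None = None


def _time_spline(n_days: int, n_years: int, df_per_year: int = 8) -> tuple[np.ndarray, int]:
    df = df_per_year * n_years
    idx = np.arange(n_days, dtype=float)
    internal = np.quantile(idx, np.linspace(0, 1, df + 1)[1:-1])
    basis = NaturalSpline(internal, (idx[0] - 0.5, idx[-1] + 0.5))(idx)
    return basis, df


def build_design(
    panel: CountyPanel, crossbasis: CrossBasis, df_per_year: int = 8
) -> Design:
    """Assemble intercept + day-of-week + time-spline + crossbasis columns.

    Sunday is the day-of-week reference level; the time spline has
    ``df_per_year × n_years`` degrees of freedom with knots at quantiles of
    the day index. Burn-in rows of the crossbasis are excluded.
    """
    n = len(panel.data)
    if crossbasis.matrix.shape[0] != n:
        raise DataValidationError("crossbasis was not built from this panel's temperatures")
    dow = panel.dates.dt.dayofweek.to_numpy()
    dow_block = np.column_stack([(dow == k).astype(float) for k in range(6)])
    time_block, tdf = _time_spline(n, panel.n_years, df_per_year)
    blocks = [np.ones((n, 1)), dow_block, time_block, crossbasis.matrix]
    names = (
        ["intercept"]
        + [f"dow_{d}" for d in DOW_LEVELS]
        + [f"time_{k}" for k in range(1, tdf + 1)]
        + [f"cb_{k}" for k in range(1, crossbasis.matrix.shape[1] + 1)]
    )
    X = np.hstack(blocks)
    keep = ~crossbasis.burn_in
    X, row_index = X[keep], np.flatnonzero(keep)
    y = panel.counts[keep]
    offset = None
    if "offset" in panel.data.columns:
        offset = panel.data["offset"].to_numpy(dtype=float)[keep]

    starts = np.cumsum([0] + [b.shape[1] for b in blocks])
    column_map = {
        "intercept": list(range(starts[0], starts[1])),
        "dow": list(range(starts[1], starts[2])),
        "time": list(range(starts[2], starts[3])),
        "crossbasis": list(range(starts[3], starts[4])),
    }

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR exposes which columns fail to add rank
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(piv[rank:])
        warnings.warn(
            f"design matrix rank {rank} < {X.shape[1]}; "
            f"near-dependent columns: {[names[i] for i in bad]} "
            f"(min |R| diag {diag.min():.2e})",
            stacklevel=2,
        )
    return Design(X=X, y=y, column_map=column_map, names=names, row_index=row_index, offset=offset)


@dataclass
class FitResult:
    """Quasi-Poisson fit: coefficients, covariance and dispersion."""

    beta: np.ndarray
    vcov: np.ndarray
    dispersion: float
    column_map: dict[str, list[int]]
    names: list[str]
    n_obs: int

    def __post_init__(self):
        if self.beta.size != self.vcov.shape[0] or self.vcov.shape[0] != self.vcov.shape[1]:
            raise ValueError("beta / vcov dimension mismatch")

    def block(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients and covariance of one named column block."""
        idx = self.column_map[name]
        return self.beta[idx], self.vcov[np.ix_(idx, idx)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta.tolist(),
                "vcov": self.vcov.tolist(),
                "dispersion": self.dispersion,
                "column_map": self.column_map,
                "names": self.names,
                "n_obs": self.n_obs,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        return cls(
            beta=np.asarray(d["beta"]),
            vcov=np.asarray(d["vcov"]),
            dispersion=float(d["dispersion"]),
            column_map={k: list(v) for k, v in d["column_map"].items()},
            names=list(d["names"]),
            n_obs=int(d["n_obs"]),
        )


def fit_quasipoisson(
    design: Design,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> FitResult:
    """Fit the quasi-Poisson GLM by iteratively reweighted least squares.

    The point estimate is the Poisson maximum-likelihood fit (log link);
    dispersion is the Pearson chi-square divided by residual degrees of
    freedom, and the covariance is dispersion × the inverse Fisher
    information. Real-valued (enrollment-adjusted) responses are accepted:
    the variance-proportional-to-mean assumption needs no integrality.
    """
    if np.any(design.y < 0):
        raise DataValidationError("negative response value")
    model = sm.GLM(
        design.y, design.X, family=sm.families.Poisson(), offset=design.offset
    )
    with warnings.catch_warnings():
        # adjusted counts are intentionally non-integer
        warnings.simplefilter("ignore")
        res = model.fit(scale="X2", maxiter=maxiter, tol=tol)
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"IRLS did not converge in {maxiter} iterations; "
            f"deviance trace: {res.fit_history.get('deviance', [])[-5:]}"
        )
    return FitResult(
        beta=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        dispersion=float(res.scale),
        column_map=design.column_map,
        names=design.names,
        n_obs=int(design.y.size),
    )


def fit_county(panel: CountyPanel, crossbasis: CrossBasis, df_per_year: int = 8) -> FitResult:
    """Convenience: build the design for a panel and fit it."""
    return fit_quasipoisson(build_design(panel, crossbasis, df_per_year=df_per_year))
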