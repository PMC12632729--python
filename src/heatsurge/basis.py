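"""Natural cubic spline bases and the lagged-temperature crossbasis.

The exposure-response model is a distributed lag non-linear model (DLNM):
a natural cubic spline over daily maximum temperature is tensor-combined
with a natural cubic spline over lag days 0..L, producing a crossbasis
design matrix whose coefficients describe how risk varies jointly with
temperature and lag.

Two details matter for projection under warming scenarios and are baked
into :class:`NaturalSpline`:

* boundary knots can be placed beyond the observed data (e.g. extended to
  cover projected future temperature extremes), and
* the basis is *exactly linear* beyond the boundary knots (zero second
  derivative), so risk estimates extrapolate linearly into unobserved heat.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import BSpline

__all__ = [
    "NaturalSpline",
    "natural_spline_basis",
    "log_spaced_lag_knots",
    "CrossBasisSpec",
    "CrossBasis",
    "build_crossbasis",
    "lag_cumulation_map",
    "cumulate_over_lags",
]


class SpecificationError(ValueError):
    """Invalid spline or crossbasis specification."""


class DataValidationError(ValueError):
    """Input data violates a precondition (non-finite values, gaps, ...)."""


class NaturalSpline:
    """Natural cubic spline basis with fixed interior and boundary knots.

    Construction follows the classical recipe: a cubic B-spline basis on
    ``[boundary[0], boundary[1]]`` with the given interior knots, the
    intercept column dropped, then projected onto the null space of the
    two boundary second-derivative constraints. The resulting basis has
    ``len(internal_knots) + 1`` columns and is linear outside the boundary
    knots (implemented by first-order Taylor extension at each boundary).

    Parameters
    ----------
    internal_knots
        Strictly increasing knots, all inside the open boundary interval.
    boundary_knots
        Pair ``(lo, hi)``; the basis has zero curvature at and beyond these.
    """

    def __init__(self, internal_knots: Sequence[float], boundary_knots: Sequence[float]):
        internal = np.asarray(internal_knots, dtype=float)
        lo, hi = (float(boundary_knots[0]), float(boundary_knots[1]))
        if not np.all(np.isfinite(internal)) or not np.isfinite([lo, hi]).all():
            raise SpecificationError("knots must be finite")
        if lo >= hi:
            raise SpecificationError(f"boundary knots must satisfy lo < hi, got ({lo}, {hi})")
        if internal.size and (np.any(np.diff(internal) <= 0)):
            raise SpecificationError("internal knots must be strictly increasing")
        if internal.size and (internal[0] <= lo or internal[-1] >= hi):
            raise SpecificationError(
                f"internal knots {internal.tolist()} must lie strictly inside "
                f"boundary ({lo}, {hi})"
            )
        self.internal = internal
        self.boundary = (lo, hi)

        t = np.r_[[lo] * 4, internal, [hi] * 4]
        nb = internal.size + 4
        self._bs = BSpline(t, np.eye(nb), 3, extrapolate=True)
        # boundary-curvature constraints on the intercept-free basis
        const = self._bs.derivative(2)(np.array([lo, hi]))[:, 1:]
        q, _ = np.linalg.qr(const.T, mode="complete")
        self._proj = q[:, 2:]  # (nb-1, nb-3) null-space map
        # cached values/slopes at the boundaries for linear tails
        self._bval = {b: self._eval_inside(np.array([b]))[0] for b in (lo, hi)}
        d1 = self._bs.derivative(1)
        self._bslope = {b: d1(np.array([b]))[:, 1:] @ self._proj for b in (lo, hi)}
        self._bslope = {b: v[0] for b, v in self._bslope.items()}

    @property
    def df(self) -> int:
        return self.internal.size + 1

    def _eval_inside(self, x: np.ndarray) -> np.ndarray:
        return self._bs(x)[:, 1:] @ self._proj

    def __call__(self, x) -> np.ndarray:
        """Evaluate the basis at ``x``; returns ``(len(x), df)``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise DataValidationError(f"non-finite value at position {bad}")
        lo, hi = self.boundary
        out = self._eval_inside(np.clip(x, lo, hi))
        for b, mask in ((lo, x < lo), (hi, x > hi)):
            if mask.any():
                out[mask] = self._bval[b] + (x[mask, None] - b) * self._bslope[b]
        return out


def natural_spline_basis(x, internal_knots, boundary_knots) -> np.ndarray:
    """Natural cubic spline design matrix, ``len(x) × (n_internal + 1)``."""
    return NaturalSpline(internal_knots, boundary_knots)(x)


def log_spaced_lag_knots(max_lag: int, n_knots: int = 3) -> np.ndarray:
    """Interior lag knots equally spaced on the log scale.

    The knots are the interior points of an ``n_knots + 2``-point grid
    equally spaced between ``log(1)`` and ``log(max_lag)`` (lag 0 anchors
    the lower *boundary* but is excluded from the log spacing).
    """
    if max_lag < 2:
        raise SpecificationError(f"max_lag must be >= 2 to place lag knots, got {max_lag}")
    grid = np.exp(np.linspace(0.0, np.log(max_lag), n_knots + 2))
    return grid[1:-1]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Configuration of the temperature × lag crossbasis.

    ``var_knots`` default to the 10th/75th/90th percentiles of present-day
    temperature; ``var_boundary`` should span present *and* projected
    future temperatures so that future exposures stay inside the spline's
    cubic region (beyond it the basis extrapolates linearly).
    """

    var_knots: tuple[float, ...]
    var_boundary: tuple[float, float]
    max_lag: int = 5
    lag_knots: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.lag_knots is None:
            object.__setattr__(self, "lag_knots", tuple(log_spaced_lag_knots(self.max_lag)))
        object.__setattr__(self, "var_knots", tuple(float(k) for k in self.var_knots))
        object.__setattr__(self, "var_boundary", tuple(float(b) for b in self.var_boundary))
        object.__setattr__(self, "lag_knots", tuple(float(k) for k in self.lag_knots))
        if not (self.var_boundary[0] < self.var_knots[0] and self.var_knots[-1] < self.var_boundary[1]):
            raise SpecificationError("var_boundary must span var_knots")
        lk = np.asarray(self.lag_knots)
        if np.any(np.diff(lk) <= 0) or lk[0] <= 0 or lk[-1] >= self.max_lag:
            raise SpecificationError("lag_knots must be increasing and inside (0, max_lag)")

    @property
    def lag_boundary(self) -> tuple[float, float]:
        return (0.0, float(self.max_lag))

    @property
    def var_basis(self) -> NaturalSpline:
        return NaturalSpline(self.var_knots, self.var_boundary)

    @property
    def lag_basis(self) -> NaturalSpline:
        return NaturalSpline(self.lag_knots, self.lag_boundary)

    @property
    def v_x(self) -> int:
        return len(self.var_knots) + 1

    @property
    def v_l(self) -> int:
        return len(self.lag_knots) + 1

    @classmethod
    def from_temperatures(
        cls,
        present: np.ndarray,
        future: np.ndarray | None = None,
        max_lag: int = 5,
        knot_percentiles: Sequence[float] = (10.0, 75.0, 90.0),
    ) -> "CrossBasisSpec":
        """Percentile knots from present-day temperatures with boundary knots
        extended to cover projected future extremes."""
        present = np.asarray(present, dtype=float)
        knots = np.percentile(present, knot_percentiles)
        lo, hi = float(present.min()), float(present.max())
        if future is not None:
            future = np.asarray(future, dtype=float)
            lo, hi = min(lo, float(future.min())), max(hi, float(future.max()))
        # tiny pad so percentile knots of short series stay strictly interior
        eps = 1e-9 * max(1.0, hi - lo)
        return cls(var_knots=tuple(knots), var_boundary=(lo - eps, hi + eps), max_lag=max_lag)

    def to_text(self) -> str:
        return yaml.safe_dump(
            {
                "var_knots": list(self.var_knots),
                "var_boundary": list(self.var_boundary),
                "max_lag": self.max_lag,
                "lag_knots": list(self.lag_knots),
            },
            sort_keys=False,
        )

    @classmethod
    def from_text(cls, text: str) -> "CrossBasisSpec":
        d = yaml.safe_load(io.StringIO(text))
        return cls(
            var_knots=tuple(d["var_knots"]),
            var_boundary=tuple(d["var_boundary"]),
            max_lag=int(d["max_lag"]),
            lag_knots=tuple(d["lag_knots"]),
        )


@dataclass
class CrossBasis:
    """Lagged-exposure design matrix ``(n_days, v_x * v_l)``.

    Column ``i * v_l + j`` holds Σ_l B_var(T_{t-l})_i · B_lag(l)_j. Rows with
    index < max_lag are burn-in: their lag window reaches before the series
    start (back-filled with the first observed temperature) and they are
    excluded from fitting by default.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    temps: np.ndarray
    burn_in: np.ndarray  # boolean, True for the first max_lag rows

    @property
    def v_x(self) -> int:
        return self.spec.v_x

    @property
    def v_l(self) -> int:
        return self.spec.v_l


def build_crossbasis(temps, spec: CrossBasisSpec) -> CrossBasis:
    """Build the crossbasis matrix for a daily temperature series.

    Lagged temperatures before the first observation are back-filled with
    the first observed value; the affected rows are flagged as burn-in.
    """
    temps = np.asarray(temps, dtype=float)
    if not np.all(np.isfinite(temps)):
        bad = int(np.flatnonzero(~np.isfinite(temps))[0])
        raise DataValidationError(f"non-finite temperature at day index {bad}")
    n, L = temps.size, spec.max_lag
    if n <= L:
        raise SpecificationError(f"series length {n} must exceed max_lag {L}")
    bvar, blag = spec.var_basis, spec.lag_basis
    B_lag = blag(np.arange(L + 1))  # (L+1, v_l)
    out = np.zeros((n, spec.v_x * spec.v_l))
    for lag in range(L + 1):
        shifted = np.concatenate([np.full(lag, temps[0]), temps[: n - lag]])
        Bv = bvar(shifted)  # (n, v_x)
        out += (Bv[:, :, None] * B_lag[lag][None, None, :]).reshape(n, -1)
    burn = np.zeros(n, dtype=bool)
    burn[:L] = True
    return CrossBasis(matrix=out, spec=spec, temps=temps, burn_in=burn)


def lag_cumulation_map(spec: CrossBasisSpec) -> np.ndarray:
    """Map ``C`` (v_x × v_x·v_l) collapsing crossbasis coefficients over lags.

    ``C @ beta_cb`` gives the reduced temperature-basis coefficients whose
    curve ``B_var(T) @ (C @ beta_cb)`` is the cumulative (over lags 0..L)
    log relative risk at constant exposure ``T``.
    """
    lag_totals = spec.lag_basis(np.arange(spec.max_lag + 1)).sum(axis=0)  # (v_l,)
    C = np.zeros((spec.v_x, spec.v_x * spec.v_l))
    for i in range(spec.v_x):
        C[i, i * spec.v_l : (i + 1) * spec.v_l] = lag_totals
    return C


def cumulate_over_lags(spec: CrossBasisSpec, coefficients, temp_grid):
    """Cumulative log-RR curve over a temperature grid and its linear map.

    Returns ``(curve, M)`` where ``M`` is ``(len(grid), v_x·v_l)`` with
    ``M @ beta = curve``; the covariance of the curve is ``M V Mᵀ``.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size != spec.v_x * spec.v_l:
        raise SpecificationError(
            f"coefficient length {coefficients.size} != v_x*v_l = {spec.v_x * spec.v_l}"
        )
    M = spec.var_basis(temp_grid) @ lag_cumulation_map(spec)
    return M @ coefficients, M
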