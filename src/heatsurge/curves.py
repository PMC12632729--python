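"""Cumulative exposure-response curves, reference centring, regional pooling.

A fitted DLNM is reduced along the lag dimension to a single cumulative
log relative-risk curve over temperature. The curve is anchored at the
temperature of lowest risk within the observed present-day range (the
minimum-risk reference, RR = 1 there), and county curves are pooled
within regions by fixed-effect multivariate inverse-variance weighting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import CrossBasisSpec, lag_cumulation_map
from .models import FitResult

__all__ = [
    "ExposureResponse",
    "reduce_to_curve",
    "find_reference",
    "pool_region",
    "pooled_curve",
    "export_curve",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass
class ExposureResponse:
    """Cumulative log-RR curve on a temperature grid.

    ``reduced_coef``/``reduced_vcov`` are the lag-cumulated temperature-basis
    coefficients; before centring ``ref_temp`` is None and ``log_rr`` is the
    raw basis curve, after :func:`find_reference` the curve satisfies
    ``log_rr(ref_temp) = 0`` exactly with se propagated for the contrast.
    """

    temp_grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reduced_coef: np.ndarray
    reduced_vcov: np.ndarray
    ref_temp: float | None = None

    def rr_frame(self) -> pd.DataFrame:
        rr = np.exp(self.log_rr)
        return pd.DataFrame(
            {
                "temp_c": self.temp_grid,
                "log_rr": self.log_rr,
                "se": self.se,
                "rr": rr,
                "rr_lo": np.exp(self.log_rr - Z95 * self.se),
                "rr_hi": np.exp(self.log_rr + Z95 * self.se),
            }
        )


def reduce_to_curve(
    fit: FitResult, spec: CrossBasisSpec, temp_grid
) -> ExposureResponse:
    """Collapse the crossbasis block of a fit over lags 0..L.

    Returns the un-centred cumulative curve: ``B_var(grid) @ C beta_cb``
    with covariance ``B (C V C') B'`` where C is the lag-cumulation map.
    """
    if "crossbasis" not in fit.column_map:
        raise ValueError("fit has no crossbasis block")
    temp_grid = np.asarray(temp_grid, dtype=float)
    beta_cb, vcov_cb = fit.block("crossbasis")
    C = lag_cumulation_map(spec)
    if C.shape[1] != beta_cb.size:
        raise ValueError(
            f"crossbasis block has {beta_cb.size} coefficients; spec implies {C.shape[1]}"
        )
    reduced_coef = C @ beta_cb
    reduced_vcov = C @ vcov_cb @ C.T
    B = spec.var_basis(temp_grid)
    curve = B @ reduced_coef
    se = np.sqrt(np.maximum(np.einsum("gi,ij,gj->g", B, reduced_vcov, B), 0.0))
    return ExposureResponse(
        temp_grid=temp_grid, log_rr=curve, se=se,
        reduced_coef=reduced_coef, reduced_vcov=reduced_vcov,
    )


def find_reference(
    curve: ExposureResponse,
    spec: CrossBasisSpec,
    observed_temps,
    pct_range: tuple[float, float] = (1.0, 99.0),
) -> ExposureResponse:
    """Re-centre the curve at the minimum-risk temperature.

    The reference is the grid point minimizing log-RR within the central
    1st-99th percentile band of *observed* temperatures (extrapolated
    tails are never eligible). Ties go to the coldest candidate. The
    recentred standard error is that of the contrast against the
    reference point, so se(ref) = 0.
    """
    observed_temps = np.asarray(observed_temps, dtype=float)
    lo, hi = np.percentile(observed_temps, pct_range)
    mask = (curve.temp_grid >= lo) & (curve.temp_grid <= hi)
    if not mask.any():
        raise ValueError("temperature grid does not intersect the observed range")
    cand = np.flatnonzero(mask)
    vals = curve.log_rr[cand]
    minval = vals.min()
    ties = cand[np.isclose(vals, minval, rtol=0.0, atol=1e-12)]
    if ties.size > 1:
        logger.info(
            "multiple minimum-risk temperatures %s; choosing the coldest",
            curve.temp_grid[ties].tolist(),
        )
    ref_idx = int(ties[0])
    ref_temp = float(curve.temp_grid[ref_idx])
    B = spec.var_basis(curve.temp_grid)
    D = B - B[ref_idx]  # contrast basis against the reference point
    log_rr = D @ curve.reduced_coef
    se = np.sqrt(np.maximum(np.einsum("gi,ij,gj->g", D, curve.reduced_vcov, D), 0.0))
    return ExposureResponse(
        temp_grid=curve.temp_grid, log_rr=log_rr, se=se,
        reduced_coef=curve.reduced_coef, reduced_vcov=curve.reduced_vcov,
        ref_temp=ref_temp,
    )


def pool_region(
    items: list[tuple[np.ndarray, np.ndarray]], ridge: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect multivariate inverse-variance pooling.

    ``pooled = (Σ V_i^-1)^-1 Σ V_i^-1 θ_i`` with covariance
    ``(Σ V_i^-1)^-1``. A numerically singular V_i is ridge-stabilized on
    the diagonal with a warning.
    """
    if not items:
        raise ValueError("need at least one county curve to pool")
    k = np.asarray(items[0][0]).size
    precision = np.zeros((k, k))
    weighted = np.zeros(k)
    for theta, V in items:
        theta = np.asarray(theta, dtype=float)
        V = np.asarray(V, dtype=float)
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            warnings.warn("singular curve covariance; ridge-stabilizing", stacklevel=2)
            Vinv = np.linalg.inv(V + ridge * np.eye(k))
        precision += Vinv
        weighted += Vinv @ theta
    pooled_vcov = np.linalg.inv(precision)
    pooled_coef = pooled_vcov @ weighted
    return pooled_coef, pooled_vcov


def pooled_curve(
    items: list[tuple[np.ndarray, np.ndarray]],
    spec: CrossBasisSpec,
    temp_grid,
    observed_temps=None,
) -> ExposureResponse:
    """Pool county reduced coefficients and evaluate (optionally centred)."""
    temp_grid = np.asarray(temp_grid, dtype=float)
    coef, vcov = pool_region(items)
    B = spec.var_basis(temp_grid)
    curve = ExposureResponse(
        temp_grid=temp_grid,
        log_rr=B @ coef,
        se=np.sqrt(np.maximum(np.einsum("gi,ij,gj->g", B, vcov, B), 0.0)),
        reduced_coef=coef,
        reduced_vcov=vcov,
    )
    if observed_temps is not None:
        curve = find_reference(curve, spec, observed_temps)
    return curve


def export_curve(curve: ExposureResponse, path) -> None:
    """Write ``temp_c,log_rr,se,rr,rr_lo,rr_hi`` with 95% Wald intervals."""
    curve.rr_frame().to_csv(path, index=False, float_format="%.8g")
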