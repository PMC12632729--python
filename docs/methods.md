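# Methods

This note records the model, the choices made where the design was
genuinely open, and what the synthetic validation does and does not
demonstrate.

## The county model

Each county contributes a contiguous daily panel of maximum temperature
`x_t`, all-cause ED visit counts `Y_t`, and annual enrollment. Counties
with 500 or fewer enrollees in any year are excluded (strict `> 500`
rule). Counts are adjusted for enrollment drift by rescaling each year's
counts to the panel-mean enrollment (`adjusted = raw × mean_enroll /
year_enroll`); the adjusted response is real-valued, which is legitimate
under quasi-likelihood because only the variance-to-mean relationship is
assumed. A log-offset alternative (`mode="offset"`) is available for
users who prefer modelling raw counts.

The regression is a quasi-Poisson GLM with log link:

    log E[Y_t] = α + cb_t'β + dow_t'γ + s(t)'δ

* `cb_t` — the DLNM crossbasis row (below);
* `dow_t` — six day-of-week dummies, Sunday as the reference level
  (arbitrary but fixed for reproducibility);
* `s(t)` — natural cubic spline in the day index with 8 degrees of
  freedom per year, knots at quantiles of the day index rather than
  calendar-equal spacing so leap years need no special casing.

Estimation is iteratively reweighted least squares (Poisson score,
convergence `max|Δβ| < 1e-8`, ≤ 100 iterations, via statsmodels GLM);
dispersion is the Pearson statistic over residual degrees of freedom,
and the covariance is dispersion × the inverse Fisher information, so
standard errors are exactly `sqrt(φ)` times the unit-scale Poisson ones.

## Spline and crossbasis conventions

The natural cubic spline basis is constructed from a cubic B-spline
basis with the intercept column dropped, projected onto the null space
of the two boundary second-derivative constraints; outside the boundary
knots every basis function continues linearly (first-order Taylor
extension). With `k` interior knots the basis has `k + 1` columns.

Temperature basis: interior knots at the 10th/75th/90th percentiles of
the county's present-day temperatures; boundary knots extended to cover
the projected future extremes (plus a ~1e-9-degree pad so percentile
knots of short series stay strictly interior). Extending the boundary
is what makes future exposures evaluable in the cubic region and keeps
beyond-data risk extrapolation linear in temperature.

Lag basis: integer lags 0..L with L = 5 by default (3 and 10 supported
for sensitivity runs); three interior knots placed at the interior
points of a five-point grid equally spaced between log 1 and log L. Lag
0 anchors the lower boundary knot but is excluded from the log spacing
(log 0 being undefined); this anchoring is a documented convention, not
an identity of the method.

Crossbasis entry `(t, i·v_l + j) = Σ_l B_var(x_{t−l})_i · B_lag(l)_j`.
The first L rows need temperatures before the series start; these are
back-filled with the first observed value and the rows flagged as
burn-in, excluded from fitting and projection (data are neither dropped
silently nor fabricated beyond the flagged rows).

Reduction over lags uses the linear map `C` with `C[i, i·v_l + j] =
Σ_l B_lag(l)_j`, so the cumulative curve is `B_var(T) (Cβ_cb)` with
covariance propagated through the same map.

## Reference temperature and pooling

The reference is the grid temperature minimizing the cumulative curve
within the central 1st–99th percentile band of observed temperatures —
extrapolated tails are never eligible, matching standard
minimum-risk-temperature practice; ties resolve to the coldest
candidate. Centring is a contrast against the reference basis row, so
the re-centred curve is exactly zero (se = 0) at the reference.

Regional pooling is fixed-effect multivariate inverse-variance
weighting of the lag-reduced coefficients:
`pooled = (Σ V_i⁻¹)⁻¹ Σ V_i⁻¹ θ_i`. Fixed-effect (not random-effects)
pooling was chosen because it is closed-form and fully testable;
random-effects meta-analysis and best linear unbiased prediction of
county curves are out of scope. Pooling acts on lag-reduced (not full
crossbasis) coefficients. Numerically singular county covariances are
ridge-stabilized (1e-8 on the diagonal) with a warning.

## Projection by 1 °C-bin row rearrangement

Scenario temperatures are the present series plus monthly additive
deltas broadcast to days. Bins are half-open `[a, a+1)` intervals
anchored at the whole degree below the county's present minimum; the
final bin starts at the whole degree below the maximum so the observed
maximum is always in-support.

For each future day within the present-day bin grid, the donor is the
present-day non-burn-in day in the same bin whose temperature is
nearest the future value, ties to the earliest date. Nearest-temperature
donor selection makes the null scenario (zero delta) an *exact* identity
— the rearranged matrix equals the present matrix row-for-row — which
anchors testing. An in-support bin with no donors falls back to the
nearest populated bin with a warning. Future days beyond the present
grid are out-of-support: their rows are evaluated directly from the
future lagged temperature series on the shared (extended-boundary)
basis.

Expected visits are `E[Y]_t = exp(x_t'β)` with delta-method standard
errors `se_t = E[Y]_t · sqrt(x_t' V x_t)`; day-of-week and time-spline
covariates stay at their present-day calendar values, so projections
describe the present population under future temperatures.

## Uncertainty

Stage one: for each GCM, 250 draws per day of
`Normal(E_future, se_future) − Normal(E_present, se_present)`,
independent across days and terms. Per-day independence is the simplest
reading of using the two series as normal parameters; a shared
coefficient realization across days would induce day-to-day correlation
and is left to sensitivity analysis. Stage two: the pooled per-day
draws across GCMs are resampled with replacement (250 iterations); the
summary is the mean and the 2.5/97.5 percentiles of resampled means,
so intervals reflect spread around the combined estimate rather than
the cross-GCM range (cross-GCM dispersion is deliberately not
characterized). Regional/monthly aggregates resample one draw per
county-day per iteration and sum within month × region (reported as
average annual sums); annual and national rollups are sums of the same
iteration-level values, so partition conservation across regions is
exact and percent-change intervals come from iteration-level annual
sums divided by the present-day annual total — never from summing
per-day interval endpoints.

Randomness is governed by one master seed; every stochastic stage draws
from a substream keyed by (county, GCM, stage) so adding a county or
GCM never perturbs other streams.

## High-utilization days

The county-year threshold is the order statistic at rank `⌈n·0.95⌉`
(empirical-CDF / ceiling-rank convention), the unique standard
convention under which a 365-day year of distinct counts has exactly 18
strictly-exceeding days; interpolating quantile definitions give 19.
Exceedance is strict (`>`), and future series are always compared
against the matching present-day year's threshold. The increase
milestones derived from the 18-day baseline are 27 (+50%), 36
(doubling) and 45 (+150%) days; county proportions use `> 27`, `> 36`
and `≥ 45`, following the milestones' definitions literally. Exceedance
days are counted on modeled expected series for both periods (keeping
present and future comparable); counting on observed counts is
available, and counting on bootstrap draws would systematically inflate
exceedances through noise.

## Synthetic data: what it emulates and what it does not

The generator produces, per county: a seasonal sinusoid of daily
maximum temperature peaking in mid-July (mean 15 °C, amplitude 10 °C)
plus AR(1) noise (sd 2 °C, autocorrelation 0.7); overdispersed daily
counts whose log-rate combines a base rate (50 visits/day), a small
linear secular trend, multiplicative day-of-week factors, and a known
cumulative lagged temperature effect with geometrically decaying lag
weights over lags 0–5 (ratio 0.6, normalized to sum to one); annual
enrollment near 10,000 with ±5% year jitter; and per-GCM monthly
warming deltas cosine-interpolated between winter draws (1.2–2.0 °C)
and summer draws (1.6–3.3 °C), typical mid-century high-emission
magnitudes. The default truth curve is monotone, flat below ~18 °C and
rising smoothly to a cumulative relative risk of 1.10 at the hottest
grid point. Overdispersion is generated by a negative binomial with
variance = dispersion × mean (default 1.5), since quasi-Poisson
specifies only a variance function, not a generative law. Calendars are
real Gregorian dates with leap days.

Not emulated: spatial correlation between counties, population
weighting of gridded temperatures, population dynamics or adaptation,
pandemic-era reporting shocks, and cross-GCM structural differences.
Passing tests therefore demonstrate statistical correctness of the
machinery under a well-specified data-generating process, not
robustness to the confounding structures of real claims data.

## Problem sizes and numerical choices

Validation runs use 5 counties × 3 years (≈ 1,100 days each), base rate
50, 3 GCMs × 1 SSP and 250 bootstrap draws — small enough for the whole
suite to run in well under a minute while leaving every stage
non-trivial. A fixed seed (7) is shared by the stochastic checks.
Truth-recovery comparisons contrast both the fitted and the true curve
against a common cold reference grid point; centring the truth at the
*fitted* minimum-risk temperature would bias the comparison through the
argmin selection. Per-county interval-coverage of the truth is an
inherently ~90% event at these signal sizes (curve-level errors are
strongly correlated across grid points), which is why coverage checks
are seeded. Degenerate inputs are rejected early with named errors
(non-finite temperatures name the day, unmapped counties are named,
reversed scenario ranges refuse to generate); design-matrix rank
deficiency warns with the offending column names rather than failing.

## Known limitations

* Fixed-effect pooling understates between-county heterogeneity.
* Per-day-independent bootstrap draws ignore temporal correlation of
  coefficient uncertainty; aggregate intervals are approximate.
* The row-rearrangement method preserves the present-day joint
  distribution of lagged exposures only up to the binning resolution;
  out-of-support days rely on linear extrapolation of the risk curve.
* Quasi-AIC comparisons use the full-model dispersion estimate.
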