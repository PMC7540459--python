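# Methods

## The forecasting problem

`firecast` predicts monthly fire carbon emissions 1–6 months ahead for a set
of data-defined land regions.  The system is purely statistical: it exploits
(i) the memory of recent fire activity within a season, (ii) slowly varying
large-scale climate state summarized by ocean climate indices (OCIs, monthly
SST-anomaly series), and (iii) local fire weather summarized by vapor
pressure deficit (VPD).  Forecast quality is always judged against two
baselines a forecaster gets for free: the monthly climatology (zero-anomaly
prediction) and persistence (the anomaly at the forecast origin carried
forward unchanged).

## Fire cohesive regions (FCRs)

A single global model is hopeless (fire regimes are too heterogeneous) and
1-degree cells are too noisy in most of the world, so the prediction units
are chosen adaptively.  On the development window, a candidate block of
cells becomes a region when its calendar-year emission series satisfies
three admission criteria:

1. **magnitude** — mean annual emissions at or above a threshold `e_min`
   (either supplied, or derived as the top-2% nearest-rank cutoff of
   per-cell mean annual totals among burning cells);
2. **continuity** — nonzero emissions in at least 90% of years;
3. **stability** — coefficient of variation (sample sd / mean) below 2.

Candidates are tested at 1°, then 2°, 4° and 8° resolution, each coarser
candidate summing only cells not already claimed at a finer level.  The
three tilings are aligned so that each coarser cell contains exactly four
finer cells; when the grid height (or width) is not a multiple of 8 the last
8° row (column) is truncated to 4°.  A passing block that crosses a country
border is split into one region per country, keeping its level label; the
fragments are not re-tested.  After the 8° pass, leftover 8° blocks whose
mean annual total exceeds a relaxed threshold (0.12 Tg C/yr) become level
"8r" regions.  Everything else is low-fire and excluded.  Ids are assigned
level by level in row-major order from the south-west corner, so the
partition is a pure function of the inputs.

The criteria series basis is configurable (`annual` | `monthly`); the
default is annual because monthly CVs exceed 2 for almost any strongly
seasonal regime and the continuity criterion is phrased per year.

Regional emissions are plain sums over member cells (missing values count
as zero, matching how fire inventories report no burning); regional VPD is
a cosine-latitude area-weighted mean with missing cells excluded.

## Anomaly transform

Monthly emission totals are strongly seasonal and right-skewed.  Each
regional series is reduced to a bounded anomaly

    y_hat(t) = 2 * tanh( (y(t) − mean_m(t)) / (2 * sd_m(t)) ),

where `mean_m`/`sd_m` are the across-year mean and sample (n−1) standard
deviation of calendar month m **within the development window only** — the
climatology is frozen and never updated, so no statistic of the
verification period leaks into the transform.  The transform is monotone,
maps the climatological mean to 0, ±2 interannual standard deviations to
±2·tanh(1) ≈ ±1.52, and saturates at ±2, damping extreme fire months.
Months with zero interannual sd (constant, usually zero-fire months) map to
anomaly 0 in both directions.  The inverse clips `y_hat/2` to ±(1 − 1e−6)
before `atanh` and floors the result at 0 Tg C/month (emissions are
non-negative).  Because of the floor, inverse∘transform is the identity
wherever the floor is inactive.

VPD is approximately Gaussian, so regional VPD is only standardized
(no tanh), with the same frozen-window convention.

VPD itself is computed from 2 m temperature T (°C), specific humidity Qv
(g/g) and surface pressure Ps (hPa):
`e_s = 6.112·exp(17.67·T/(T+243.5))` (Bolton's Clausius–Clapeyron fit),
`e_a = Qv·Ps/0.622`, `VPD = max(e_s − e_a, 0)`; finer-resolution source
grids are block-averaged (cosine-latitude weights) onto the 1° target grid.

## Predictor selection

For each region, the transformed anomaly is correlated with every usable
OCI and with the region's standardized VPD at lags of 0–11 months over the
development window (Pearson; zero-variance pairings are flagged and treated
as no signal).  For a forecast at lead L only lags in [L, 11] are usable —
the predictor value for the target month must already be observed at the
origin — so the frozen lookup stores, per (region, lead): the (OCI, lag)
pair maximizing |r| jointly over indices and usable lags, and the VPD lag
maximizing |r|.  The signed correlation is stored.  Ties break to the
smaller lag, then to the canonical index order, making selection
deterministic and independent of column order.  If every candidate is
flagged the entry holds a null predictor and the model degrades gracefully
to its autoregressive part.

## The ARIMAX engine

The model for each region and lead is a regression with ARIMA(p, d, q)
errors on the transformed scale:

    Δ^d y_hat(t) = c + γ₁·OCI(t − lag₁) + γ₂·VPDz(t − lag₂) + u(t),
    u(t) = Σᵢ αᵢ u(t−i) + ε(t) + Σⱼ βⱼ ε(t−j),  ε ~ N(0, σ²),

with p ≤ 2, d ≤ 1, q ≤ 2.  The intercept is always estimated (a drift when
d = 1), and the exogenous columns are differenced together with the target,
so the d = 1 model is exactly a regression with ARIMA errors after simple
differencing.  The Gaussian likelihood is evaluated exactly by a Kalman
filter in Harvey's companion state-space form with the stationary initial
covariance and the innovation variance concentrated out; L-BFGS-B maximizes
it over an unconstrained parameterization (partial-autocorrelation map for
AR stationarity, the mirrored map for MA invertibility).  Starting values
come from a Hannan–Rissanen regression (OLS residuals, long-AR innovation
estimates, lagged-innovation regression) with a plain lag-1-autocorrelation
start as fallback; warm starts from the previous forecast origin are reused
during walk-forward sweeps.  The filter loop is numba-compiled; a fit on
~200 months costs single-digit milliseconds, which is what makes monthly
re-fitting at scale tractable.  The engine agrees with the independent
state-space implementation in statsmodels (`SARIMAX` with simple
differencing and concentrated scale) to numerical precision wherever both
optimizers converge to the same optimum; on a sample of random series it
attains equal or higher likelihood.

AIC is `2k − 2 log L` with `k = 1 (intercept) + p + q + n_exog + 1
(innovation variance)`.  Order selection loops over all 18 (p, d, q)
combinations and keeps the admissible, converged fit with minimal AIC;
ties break to smaller p+d+q, then smaller p, then smaller q; if everything
fails the fallback is (0, 0, 0).  **Admissibility**: candidates whose AR or
MA inverse roots come within 2% of the unit circle, or whose AR and MA
roots nearly cancel (distance < 0.05), are rejected.  Such fits are
practically unidentified — their extra parameters chase sampling noise at
the stationarity/invertibility boundary and can inflate the likelihood by
more than the AIC penalty, which would make a white-noise series select
ARMA(2,2).  This guard mirrors the root checks used by production
order-search tools.  Orders are selected once per (region, lead, variant)
on the development window and frozen.

## Walk-forward protocol

Every month of the prediction window is a forecast origin.  At each origin
the regression and ARMA coefficients are re-optimized on **all** data up to
the origin (hyperparameters stay frozen), the state-space model is iterated
L steps ahead, and the predicted anomaly — clipped to [−2, 2] — is mapped
back to emissions with the frozen climatology.  Exogenous values needed for
target months are observed values at (target − lag), available by
construction since lag ≥ L.  Nothing after the origin is ever read: this is
tested by mutating all post-origin inputs and asserting bit-identical
forecasts.  If the frozen order fails to converge at some origin the engine
falls back to (0, 0, 0) for that origin and logs it.  Origins whose target
months run past the observed record still produce records, flagged
unverifiable and excluded from scores.

Seven variants isolate the contribution of each component: `OCIVPDAR`
(reference; both exogenous predictors + ARIMA), `OCIAR`, `VPDAR` (one
predictor each), `ARonly` (no exogenous), `Xonly` (static regression,
p=d=q=0), `Clim` and `Persistence` (no model at all).  An in-sample
hindcast (one-step-ahead Kalman predictions over the development period
from a single fit) is available for development-period diagnostics.

## Verification

Scores are computed per (variant, lead) at region scope and on the
global-sum series, each row carrying its sample count.  Observed anomalies
subtract the development-period climatology even during the prediction
period.  Metrics: Pearson anomaly correlation (undefined and flagged for
the zero-variance Clim predictions), RMSE (Tg C/month), and percent RMSE
change vs the Clim variant at the same lead and scope (negative = beats
climatology).  The per-region best-model table picks the minimal-RMSE
variant, ties resolved in the canonical variant order.  Because the global
anomaly correlation can be computed on the summed series or on pooled
per-region pairs, the report keeps the two scopes separate ("global" vs
per-region rows) rather than mixing them.

When scores are **compared across leads**, records are first restricted to
target months verified at every lead (common-sample verification): each
lead's raw verification window is shifted by one month, so per-lead RMSE
otherwise mixes genuine skill degradation with month composition — visible
as a lead-dependent RMSE even for the lead-independent climatology
forecast.  On the common sample the climatology RMSE is exactly flat in
lead, which doubles as a self-check of the restriction.

Diagnostics used to motivate the model ranges: OLS trend on annual totals,
KPSS stationarity tests (level and trend nulls, Newey–West lag truncation
⌊4(T/100)^0.25⌋, 5% critical values) and ACF/PACF (Durbin–Levinson) of the
deseasonalized series.

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
assumes: per-cell seasonal cycles (cosine bump raised to a concentration
power, renormalized to mean 1, peak month per cell), optional linear
trends, lagged log-scale coupling of emissions to one AR(1) OCI per cell
block, i.i.d. log-scale noise, optional zero inflation, and VPD fields
built from the cell's own standardized anomaly shifted to lead emissions by
a configurable short lag.  One root seed feeds per-cell substreams keyed by
grid coordinates, so enlarging the grid never reshuffles existing cells and
fixed seeds give bit-identical fields.

It makes no attempt at spatial realism: no spatial correlation of noise,
no realistic emission magnitudes or burned-area physics, no missing-data
patterns, and the planted couplings are exactly linear on the log scale.
Passing tests therefore demonstrate that the pipeline recovers structure it
is designed for and ranks models correctly when its assumptions hold — not
that real-world skill will match.

The bundled `standard_scenario` fixes the study conditions: an 8×8 grid of
steady emitters (each passes the level-1 criteria, giving 64 single-cell
regions), six OCIs with AR(1) coefficient 0.8 and a one-year spin-up, row
couplings at lags spread over 1..6 months with coupling 0.8 and noise sd
0.35 (signal-to-noise ≈ 2.3), two countries, an 18-year development window
and a 2-year prediction window.  The spread of planted lags makes aggregate
skill decay smoothly with lead, which is the qualitative pattern the
evaluation is designed to detect.

## Problem sizes and numerical choices

- End-to-end evaluation runs use 64 regions × 5 seeds, 18-year development
  windows, 24 forecast origins and leads 1–6 — large enough for stable
  aggregate orderings while a full five-seed sweep stays in the minutes
  range on one CPU.
- Engine tolerances: L-BFGS-B `ftol` 1e−9, `gtol` 1e−5, max 200 iterations;
  Kalman prediction variance floored at 1e−12; `atanh` clamp 1 − 1e−6.
- The monthly climatology uses the sample (n−1) denominator; months with
  fewer than two samples in the window are an error, zero-sd months are
  defined to have zero anomaly.
- All randomness flows from explicit integer seeds; model fitting itself is
  deterministic (no random restarts).

## Known limitations

- Regions are derived once from the development window; regime shifts
  (policy changes, land-use transitions) that move the fire geography are
  not tracked.
- One OCI per region; no multi-index or SST-field predictors.
- No seasonal ARMA terms: seasonality is handled entirely by the anomaly
  transform, so a change in seasonal timing degrades the forecast.
- The admissibility guard can, in principle, exclude a genuinely
  near-unit-root process; for monthly anomaly series this is the right
  trade against spurious ARMA(2,2) selections.
- Verification assumes the observed record is error-free; observation noise
  in real inventories would blur all scores.
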