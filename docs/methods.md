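# Methods

This note records the models, numerical choices, and open design decisions
behind `fluxlegacy`, and what the synthetic experiments do and do not show.

## Data model and screening

A site record is a gap-free daily calendar of GPP (night-time-partitioned,
gap-filled, gC m⁻² d⁻¹), latent and sensible heat (W m⁻²), air temperature
(°C), vapor-pressure deficit (hPa), incoming shortwave and net radiation
(W m⁻²), precipitation (mm d⁻¹), and per-variable QC fractions (the share of
measured or good-quality gap-filled half-hours). Turbulent fluxes are masked
on days with QC < 0.7; the unmasked gap-filled GPP is kept in a separate
channel because QC holes inside a drought would bias cumulative sums.
Calendar years containing a missing-LE run of ≥ 60 consecutive days are
dropped in full (such seasons would corrupt the water balance); the 60-day
cutoff is this package's choice — "long-period" gaps are not quantified in
the underlying method — and is configurable. Records need ≥ 7 usable years;
shorter records do not support a stable response model. Removed years stay
on the calendar as missing rows so downstream indexing never sees a gapped
calendar.

## Anomalies

Each variable is detrended, then deseasonalized. The Mann–Kendall test runs
on calendar-year means rather than daily values — daily series are strongly
autocorrelated through the seasonal cycle, which would make the test reject
almost always — and a significant trend (α = 0.05) is removed as the OLS
slope against time (Theil–Sen available behind a flag). The order
(detrend, then deseasonalize) and the use of the *unsmoothed* per-DOY mean
cycle for anomalies are package decisions where the method description is
silent. The 7-day-smoothed cycle is used only to delimit the growing season
(days above 25% of the cycle maximum; 10% for bimodal or cross-year
seasons). Growing seasons are represented as maximal runs of consecutive
in-season calendar days, so a season spanning a calendar-year boundary is a
single unit and a bimodal site contributes two units per year.

## Water balance

WAI follows the bucket recursion WAI_t = min(WAI_max, max(0, WAI_{t−1} +
P_t − ET_t)) with ET = LE·86400/λ(T), λ(T) = (2.501 − 0.002361·T)·10⁶
J kg⁻¹ (a constant λ is available for strict cross-site comparability).
Capacity is the maximum cumulative water deficit max_t D_t,
D_t = max(0, D_{t−1} + ET − P), computed on screened years. The printed
recursion clamps only at capacity; the floor at 0 is implied (a water store
cannot be negative) and binds exactly at the historically driest point.
Spin-up cycles the first calendar year five times starting from a full
bucket; the start value is irrelevant whenever the first year touches either
bound, which the tests check. Days with missing P or ET carry the store
(zero flux) — year screening has already removed long gaps.

## Drought definition

EF = LE/(LE+H), cleaned of values outside [0, 1], is deseasonalized like
every other variable; σ is the standard deviation of growing-season EF
anomalies — the analysis is confined to the growing season, so the σ pool
is too. Days strictly below −1σ are
flagged; flagged runs separated by ≤ 3 unflagged days merge; an episode
qualifies with ≥ 15 *flagged* days (counting the calendar span instead is a
config option). Events never cross growing-season boundaries.

Traceability uses daily SPEI₉₀: the 90-day trailing sum of P − PET
(Priestley–Taylor, coefficient 1.26, G = 0 at daily scale, negative
available energy clipped to zero) is fitted per calendar day with a
3-parameter log-logistic distribution — the generalized-logistic (Hosking)
parameterization estimated by unbiased probability-weighted moments — and
mapped through the standard-normal quantile. Calendar-day pools gather
values within ±5 days across years. The half-width trades fit stability
against seasonal-gradient leakage: with a strong PET seasonal cycle, wide
pools mix climatologically different days into one sample, inflating its
variance and damping genuine anomalies (we measured SPEI minima shrinking
several-fold at ±15 days on strongly seasonal input), so the default stays
narrow; pools of ~10 years × 11 days are ample for a 3-parameter fit. An
event is traceable if SPEI₉₀ < −1 at least once between 15 days before its
start and its end. Per site, the traceable event with the lowest cumulative
EF anomaly (summed over flagged days — each below −σ, so the sum is
strictly negative) is selected; records of ≥ 14 years also contribute the
second strongest.

## Concurrent and legacy quantification

The concurrent effect is the cumulative gap-filled GPP anomaly over the
event span (gap days included), normalized as % of the long-term mean total
growing-season GPP (a mean-annual-GPP base is a config option).

The response model is a bagged ensemble of 500 regression trees (⌈p/3⌉
features per split, out-of-bag variance explained as the skill metric; the
algorithm is named in the source method but no hyperparameters are, so
these defaults are ours). Predictors: SW_IN, TA, VPD and WAI anomalies plus
DOY; target: quality-screened GPP anomalies. Low-quality days drop out of
training automatically but contribute residuals through the gap-filled
channel.

**Sign convention.** The printed residual definition (expected minus
observed) maps reduced GPP to positive values, contradicting the narrative
in which negative legacies are persistent reductions. We define legacy =
observed − expected throughout, so negative means less carbon uptake than
the weather explains; the uncertainty gate below is expressed in the same
orientation and is algebraically equivalent to the printed max/min form.

**Duration.** The candidate window starts with the post-drought remainder
of the drought-year growing season and appends whole seasons while the
weekly-averaged residuals of the newest season differ from zero (two-sided
one-sample Wilcoxon signed-rank; exact null below 25 weekly values, normal
approximation with continuity correction above; zeros dropped). Duration
counts the consecutive significant tested windows, the drought-year
remainder included: under this convention a no-legacy site extends past its
drought year with probability ≈ α, and an imposed one-season legacy yields
duration 1 — counting only whole subsequent seasons (available via config)
would square the null rate and shift the modal recovered duration to 0. A
drought-year remainder too short to test (< 4 weekly values) stays in the
window untested; a whole season too short to test stops the search. If the
record ends while residuals are still significant the duration is censored
(`converged = False`); the magnitude is kept but such events are excluded
from duration statistics, and an earlier event still unconverged when a
site's second event starts is discarded entirely.

**Uncertainty gating.** Each non-legacy year is left out in turn; the model
trained on the rest predicts (a) the held-out year, pooling residuals by
DOY into 366 uncertainty distributions (empty DOYs borrow from ±3 days),
and (b) the legacy window, whose per-day median across iterations is the
expected anomaly. With d_t = observed − median expected and [q05, q95] the
per-DOY 5–95% residual band: values inside the band are model uncertainty
(gated to 0); outside, only the exceedance beyond the band survives. The
gate is piecewise-linear, continuous and monotone; because residual bands
straddle zero, gated magnitudes never exceed ungated ones per day. Gated
values are summed over the window and normalized like concurrent effects.
Gating is deliberately strict: with an imposed −15% legacy and realistic
model error, typically only the tail of daily residuals clears the band, so
gated cumulative magnitudes run well below the imposed offset while sign
and duration are recovered reliably — the shrinkage mirrors the
conservative intent of the published gate.

## Sensitivity shifts

For sites with detected legacies, two response models are trained on the
legacy window and on an equal-size random subsample of non-legacy days.
Per-observation additive attributions are computed by the
tree-path-dependent rule: descending each tree, the change in node mean at
every split is credited to the split feature, so attributions respect the
feature dependence encoded in the tree structure and satisfy exact local
accuracy (base + Σ attributions = prediction). This is this package's
conditional-attribution variant; an interventional variant is not provided.
Attribution-vs-predictor curves are smoothed by a locally weighted linear
smoother (tricube weights, span 1) with pointwise variance σ̂²‖l(x)‖² and
normal 95% bands, evaluated on a 100-point grid over the predictors' common
range; the overlap percentage is the share of grid points where the two
bands intersect. DOY is excluded from the comparison by default (it is a
clock, not climate). Fewer than 30 legacy days or 20 points in the common
range skips the comparison.

## Driver screening

Kernel tests use Gaussian kernels with median-heuristic bandwidths; binary
drivers (forest vs non-forest) use a delta kernel. HSIC is the biased
V-statistic tr(KHLH)/n²; its permutation p-value uses the add-one
convention, and the gamma variant moment-matches the permutation null.
KCIT residualizes centered kernels with R_z = ε(K̈z + εI)⁻¹ (the
x-kernel built on (x, z) so dependence through z is removed) and
approximates the null spectrally — sampling Σ λᵢμⱼ zᵢⱼ²/n over kernel
eigenvalue products — with the two-moment gamma fit as a fallback; with an
empty conditioning set it reduces to an unconditional kernel test. A driver
with at least two of three p-values below 0.05 is a candidate; multiple
candidates are re-tested conditionally on each other. No multiple-testing
correction is applied across drivers, matching the source analysis; the
output notes this.

## Synthetic data

The generator emulates a temperate, largely energy-limited flux site:
sinusoidal seasonal cycles in radiation (40–360 W m⁻²), temperature
(−2–20 °C) and VPD with AR(1) day-to-day noise (φ = 0.5, synoptic ~2-day
memory); Bernoulli–exponential rainfall (wet-day probability 0.5, mean
8 mm) against a peak demand of 3.2 mm d⁻¹, so the 50-mm soil bucket sits
near capacity except in dry spells; ET becomes supply-limited only below a
quarter of capacity, so EF collapses in severe droughts but otherwise
reflects energy partitioning plus 10% relative flux-measurement noise.
Available energy follows the smooth seasonal radiation (day-to-day
radiation noise is shed as sensible heat): this keeps EF from
anti-correlating with cloudiness, which would otherwise make flagged days
preferentially sunny and bias cumulative GPP sums. GPP is a product of
saturating light response, temperature optimum, linear VPD down-regulation,
a gentle water ramp, and a squared-sinusoid seasonal envelope, plus
heteroscedastic noise (0.9 gC m⁻² d⁻¹ at peak); out-of-the-box response
models reach OOB ≈ 0.45, matching the skill reported for real sites.

An imposed drought suppresses rain by 95% from 25 days before the EF window
until 10 days before its end (the store is recharging when the event
closes), pins drought-day EF at the configured depth below its climatology
(2σ default) — as an upper bound on the mechanistic flux, so a bucket
reconstruction from LE stays honest and the reconstructed WAI recovers
within days of the event rather than months — and multiplies GPP by
(1 − reduction). GPP couples to the *undisturbed* soil store: the imposed
drought reaches GPP only through its explicit reduction factor, making the
imposed concurrent truth exact, while the drought's full hydrological
footprint (EF collapse, WAI drawdown, SPEI deficit) remains in the
detectable signals. Legacies multiply GPP by (1 + m) from the day after the
drought through the configured number of growing seasons (constant or
linearly decaying). Truth (windows, imposed concurrent % on the noise-free
series, legacy sign/magnitude/duration) is returned with the record.

What the generator does not emulate: energy-balance closure gaps, partitioning
artifacts, instrument drift, co-limitation regimes where EF and GPP share
slow soil memory, or realistic turbulence spectra. Passing recovery tests
therefore shows the estimator chain is consistent under the stated
conditions, not that real-site estimates carry these error bars.

The driver-table generator draws 26 events (a binary forest indicator,
drought duration ~ N(35, 24) clipped at 15 days, standardized aridity and
pre-drought water limitation) with the legacy column dependent on exactly
one driver (slope −4, unit noise, r ≈ 0.97). The driver set is deliberately
small: each calibrated test rejects ~5% of independent drivers, so k null
drivers yield a clean screen only ~0.95^k of the time; at 26 events a
dozen-driver table would make a sole-candidate outcome unreachable
regardless of implementation.

The stationary calibration climate for the standardized drought index uses
a slowly varying intensity regime (log-AR(1), ~200-day memory) multiplying
both rainfall and demand with the mean balance held at zero. Aggregated
balances are then a scale mixture of near-Gaussian sums — symmetric with
mildly heavy tails, inside the reach of the fitted log-logistic family. On
climates with near-Gaussian balances the log-logistic quantile mapping is
known to put ~0.17 of days below −1 (a logistic fitted to normal data by
L-moments places its 15.9% quantile at −0.94σ); this is a property of the
standard method, not of this implementation, which reproduces the Φ(−1)
tail when the family fits.

## Problem sizes and numerical choices

Simulation experiments use 100-tree ensembles (estimates are stable beyond
~100 trees; the analysis default stays 500), cohorts of 50 synthetic sites
for recovery and null calibration, 500 replicates for kernel-test
calibration at n = 100, and three independent 40-year climates for index
standardization. Random-forest seeds, permutation seeds and generator seeds
all derive from a single run seed. Probability clipping at 10⁻⁶ bounds
standardized-index values at ≈ ±4.75; kernel ridge ε = 10⁻³·n with ×10
escalation on singularity; LOESS falls back to a weighted mean where the
local design is degenerate (zero weighted variance).

## Known limitations

- The EF σ-threshold couples detection to record length: long records dilute
  drought variance, slightly shifting thresholds across sites.
- Duration is quantized to growing seasons; sub-seasonal recovery appears
  as duration 1.
- The gate's shrinkage makes gated magnitudes conservative by design; they
  are lower bounds on the legacy, not unbiased estimates.
- KCIT's spectral null is approximate for small n and strong conditioning;
  its conditional type-I error runs near the upper edge of the nominal
  level in the chain benchmark.
- The bucket has no drainage or runoff term beyond the overflow clamp and
  no vertical structure; WAI is an index, not a soil-moisture estimate.
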