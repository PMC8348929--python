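# Methods

## Model

The record is modelled additively, `F(t) = Trend(t) + Fluctuations(t)`. The
fluctuation process u(t) is assumed superstatistical: within windows of a
long timescale T it is Gaussian with a fixed inverse variance β, and β
itself fluctuates across windows. Aggregating over windows then mixes
Gaussians of different variance, producing a leptokurtic marginal; when β is
χ²-distributed (a gamma law with shape n/2 and mean β0) the marginal is
exactly a q-Gaussian with

    q = 1 + 2 / (n + 1),    b = β0 (n + 1) / (2 n),

which the package exposes as `qgaussian_from_chi2` and verifies numerically
(pointwise relative error of the quadrature marginal against the fitted
q-Gaussian below 1e-3 across n ∈ {2, 4, 8}). For other β-laws (inverse-χ²,
log-normal, the two-χ² mixture) the marginal is not exactly q-Gaussian but
remains heavy-tailed.

The validity conditions are (i) local Gaussianity on scale T and (ii)
timescale separation τ ≪ T, where τ is the relaxation time of the
autocorrelation c(t) ~ exp(−t/τ). Both are checked, not assumed: local
snapshots are tested for Gaussian kurtosis, and the ratio τ/T is always
reported (default pass threshold 0.1, configurable — no universally agreed
cutoff exists for "≪").

## Detrending

Two interchangeable methods satisfy the additive identity
trend + fluctuations = input to 1e-9 relative:

* **Seasonal**: trend = centered moving average with window f (hours;
  default 6 h). Even sample-windows use the standard 2×MA (weights
  ½,1,…,1,½ over window+1 points) so the filter stays centered and phase
  free; this matches statsmodels' seasonal decomposition filter, against
  which the implementation is cross-checked in the tests. Endpoints where
  the window does not fit are trimmed (NaN trend).
* **EMD**: cubic-spline envelope sifting with mirror-symmetric extension of
  the extrema about the signal endpoints, a Cauchy-type stopping criterion
  (relative squared change below 0.2) with at most 12 sifting iterations per
  mode, and the final residual kept as the slowest mode, so mode
  completeness (sum of modes = signal) holds to machine precision. Modes are
  returned slowest first; the fluctuation channel is the sum of the m
  fastest modes (default m = 2). Spline type, extension, threshold and
  iteration cap are free choices of this implementation — the literature
  fixes none of them — and all are configurable.

## Timescale estimation

κ̄(Δt) averages the population-moment kurtosis over windows whose starts are
spaced by stride = window/10 (minimum 1), a dense discretization of the
average over all window positions; zero-variance or gap-crossing windows are
skipped and counted. Population (1/n) moments are used throughout — the
statistic is a ratio of raw moments, so bias correction would change its
Gaussian reference value. T is the first upward crossing of
κ̄(Δt) = 3, linearly interpolated between grid points (default grid:
2–200 h, 30 log-spaced points). Small windows are biased slightly below 3
(the population kurtosis of n Gaussian samples has expectation
≈ 3(n−1)/(n+1)), which is what makes the crossing well defined; as a
consequence the crossing sits at or somewhat below the true β-redraw period
rather than exactly at it (the synthetic-recovery tests find ≈ 11 h for a
16 h ground truth — within the factor-of-2 band that is meaningful for this
estimator). If κ̄ never reaches 3 the fluctuations are platykurtic — the
typical outcome of over-aggressive detrending that pushes deterministic
cycles into the fluctuation channel — and T is reported undefined; β
extraction and fitting are then skipped with the reason recorded.

τ is the 1/e crossing of the empirical ACF (linear interpolation between
integer lags; flagged resolution-limited when the ACF is already below 1/e
at lag one). Subtracting a moving-average trend is itself a linear filter
and systematically shortens the apparent decay of the residual ACF; when
the trend filter is known (seasonal method) the pipeline therefore fits τ
by matching the closed-form ACF of an exponentially correlated process
passed through the residual filter δ − w to the empirical ACF over short
lags (≤ 8 h). This removes a ≈ 45% downward bias at f = 6 h, τ = 1 h; the
plain crossing estimate is kept in the report as a cross-check. For EMD
detrending no linear-filter correction exists and the plain estimator is
used.

β values are computed on consecutive non-overlapping windows of length T
(floor rule; β = 1 / population variance about the window's own mean).
Non-overlapping windows keep the β draws near-independent for likelihood
fitting; overlap would inflate the effective sample size.

## Distribution fitting

All fits are maximum likelihood. Log-normal is closed form on log β. χ² and
inverse-χ² are gamma MLEs (the inverse-χ² via the gamma fit of 1/β, valid
because the Jacobian of the transform does not involve the parameters).
Degrees of freedom are continuous throughout — n is a gamma shape, not an
integer count. The q-Gaussian is fitted by L-BFGS-B over (q, log b, μ) with
multi-start q₀ ∈ {1.05, 1.3, 1.6, 2.0}, μ₀ at the median and b₀ moment
matched; q is restricted to [1, 2.8] (normalizability requires q < 3, and
the variance diverges for q ≥ 5/3, which is why scale is always reported as
b, never as a sample variance). The β convention is β = 1/σ²; the
alternative 1/(2σ²) convention only rescales β0.

The two-χ² mixture shares β0 between components. It is fitted by EM:
responsibilities in the E-step reduce the M-step to three sufficient
statistics per component (Σr, Σr·β, Σr·ln β), so the nested optimization —
each component's shape maximized one-dimensionally inside a bounded search
over the shared log β0 — costs O(1) per likelihood evaluation. Six starts
are used: W ∈ {0.2, 0.5, 0.8} with quantile-split moment matching, one
wide split (n = 0.5 vs 20), and one at the single-χ² solution with n₁ = n₂,
which guarantees the mixture log-likelihood is never below the single-χ²
one (likelihood nesting). Labels are resolved by enforcing n₁ ≤ n₂.
Model comparison is by AIC (2k − 2 logL, k = 2/2/2/3/4), which penalizes
the mixture's two extra parameters; ranking, not hypothesis testing, is the
contract.

## Synthetic data

The generator produces what the analysis assumes, with exact ground truth:
trend = base level + daily sinusoid + seasonal sinusoid + linear drift;
fluctuations are an AR(1) (discretized Ornstein–Uhlenbeck, φ =
exp(−Δt/τ_true)) whose stationary variance 1/β is redrawn i.i.d. from the
configured β-law at the start of every epoch of fixed length T_true. The
normalized AR(1) state is carried across epoch boundaries, so the variance
re-target is instantaneous while the autocorrelation stays continuous.
Defaults are dissolved-oxygen-like: 15-min step, 365 d, base 9, daily
amplitude 3, seasonal amplitude 4 (instrument units), T_true = 16 h,
τ_true = 1 h, log-normal β with μ_ln = 0, σ_ln = 1 (median local σ of 1).
The seed fully determines the output.

What the generator does **not** emulate: irregular regime switching (real β
dynamics are not clocked), asymmetric or skewed local distributions,
sensor artifacts (drift, quantization, spikes), rainfall/flow/photosynthesis
mechanisms, and cross-parameter dependence. Passing recovery tests therefore
demonstrates estimator correctness under the model's own assumptions, not
that any particular river satisfies them.

## Numerical choices and degenerate inputs

* Gaps: linear interpolation up to 60 min (configurable), longer gaps kept
  as explicit NaN markers; windows overlapping markers are skipped, never
  imputed, so local variances are not diluted. Duplicate timestamps collapse
  by mean. All-gap output is an error, as is a constant window for any
  variance-based statistic.
* κ̄ undefined at a grid point (window too long, all windows degenerate) is
  recorded as NaN in the curve, not an error; a curve needs two defined
  points before T can be sought.
* If κ̄ touches the target more than once, the first upward crossing wins —
  the smallest scale at which local Gaussianity breaks.
* EM convergence: relative log-likelihood change below 1e-8, cap 200
  iterations; non-convergence returns the best parameters found with
  `converged=False` rather than raising.
* Problem sizes in the test-suite and acceptance runs (10 seeds × 365 d at
  15 min for pipeline recovery; 1e4–1e5 draws for the fitter recoveries;
  50 random signals for EMD completeness) were chosen as the smallest sizes
  at which Monte-Carlo error is comfortably inside the asserted bands.

## Known limitations

* The κ̄ = 3 crossing estimates the order of magnitude of T, not its exact
  value; its location depends on the detrending parameter roughly linearly
  over the usable range (the `sweep` command reproduces this dependence).
* The filter-aware τ estimator assumes an exponential true ACF; strongly
  non-exponential short-range correlation would bias it.
* EM can merge components when the mixture is nearly unimodal; AIC then
  correctly prefers the single χ², but the mixture parameters themselves are
  weakly identified in that regime.
* No goodness-of-fit testing beyond AIC ranking, and no bivariate
  (cross-parameter) superstatistics.
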