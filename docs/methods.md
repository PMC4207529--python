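# Methods

## The EIL as a stochastic process

The economic injury level EIL = C/(V·I·D·K) is deterministic for fixed
inputs, but its economic inputs move from year to year. Holding C, I, D, K
constant and letting the commodity price V vary yearly turns the EIL into a
yearly time series y_t proportional to 1/V_t. `eilcast` models that series
as a stationary Gaussian autoregression

    y_t = u + a_1 y_{t-1} + ... + a_p y_{t-p} + eps_t,  eps_t ~ N(0, sigma^2),

with process mean mu = u/(1 - sum a_j). Stationarity means every root of
1 - a_1 z - ... - a_p z^p lies strictly outside the unit circle; it
guarantees the MA(infinity) representation y_t = mu + sum_j theta_j
eps_{t-j} (theta_0 = 1, theta_j = sum_{k<=min(j,p)} a_k theta_{j-k}) whose
squared-weight partial sums give the forecast-error variances.

Assumptions worth stating: the AR model treats the EIL series on its
natural scale (not log), innovations are Gaussian and homoscedastic, and
the years are equally spaced — the series container rejects calendar gaps
rather than imputing them, because the recursion has no meaning across a
hole.

## Likelihoods

*Conditional*: the prediction-error decomposition conditioning on the first
p observations,

    l_c = -((n-p)/2) log(2 pi sigma^2)
          - (1/(2 sigma^2)) sum_{t=p+1}^{n} (y_t - u - sum_j a_j y_{t-j})^2.

Its maximizer is ordinary least squares of y_t on (1, y_{t-1..t-p}), with
sigma^2 = SSR/(n-p); the implementation uses that closed form whenever the
OLS solution is stationary.

*Exact*: l_c plus the log density of the initial block (y_1..y_p) under the
stationary marginal — mean mu in every coordinate and covariance
Gamma_{ij} = gamma_{|i-j|}, where gamma_0..gamma_p solve the linear
Yule-Walker system. For p = 1 this reduces to y_1 ~ N(mu,
sigma^2/(1-a_1^2)). With a free intercept the marginal is centred at mu,
not at zero; centring at zero would only be correct for a mean-deleted
series.

Exact maximization is numerical: the objective is parameterized as
(intercept, atanh k_1..k_p, log sigma^2), where k_i are partial
autocorrelations mapped to coefficients by the Durbin-Levinson recursion.
Every point of that space is strictly stationary, so the initial-block
marginal always exists during optimization. The optimizer is L-BFGS-B
(objective tolerance 1e-12, gradient tolerance 1e-8), initialized from the
conditional fit (partials clipped to |k| <= 0.98), with a Nelder-Mead
fallback; non-convergence raises an error carrying the last iterate. The
exact likelihood implementation agrees with an independent full-series
multivariate-Gaussian evaluation to ~1e-13 (and with a state-space Kalman
evaluation), which the tests and the acceptance script verify.

Orders are compared with AIC = -2 log L + 2 rho. The parameter count is
rho = p + 2 with an estimated intercept (coefficients, intercept, sigma^2)
and p + 1 under `--zero-mean`; the convention is applied uniformly so
comparisons are internally consistent. All candidate orders use the same
likelihood kind, and the default is exact because conditional likelihoods
at different p are computed on different numbers of observations, which
makes their AICs incomparable. Ties resolve toward the smaller order.

## Diagnostics

The individuals & moving-range chart estimates process sigma as
mean|y_t - y_{t-1}| / d2 with d2 = 1.128, the unbiasing constant for a
range of span 2, and flags points beyond center +/- 3 sigma (the
moving-range chart's own limit uses D4 = 3.267). The multiplier is
configurable (`--limit-multiplier`); 3 is the default. A caveat inherent to
the method: under positive lag-1 autocorrelation rho_1 the expected sigma
estimate is sigma*sqrt(1 - rho_1), so the limits tighten and the false-alarm
rate exceeds the nominal 0.27% — at rho_1 = 0.3 the true in-control rate is
already ~98.7%. The chart is a screening tool here, not an inference.

The ACF uses the standard biased estimator (full-series sum of squares in
the denominator), which keeps the autocorrelation sequence positive
semidefinite — a requirement of the Durbin-Levinson recursion that produces
the PACF. Confidence bands are the flat white-noise +/- z_{1-alpha/2}/sqrt(n)
bands (default alpha = 0.05), not Bartlett's cumulative formula.

## Forecasting

Point forecasts iterate the fitted recursion, substituting earlier
forecasts for unobserved values; for AR(1) this is mu + a^h (y_n - mu).
The h-step standard error is sigma * sqrt(sum_{j<h} theta_j^2) and the
(default 95%) interval is the symmetric Gaussian plug-in interval. The
default horizon is 5 years. Parameter-estimation uncertainty is *not*
propagated into the intervals; on short series (n ~ 15) true coverage is
therefore somewhat below nominal. The Monte-Carlo coverage check in the
tests uses the true simulation model, i.e. it calibrates the interval
formula itself, not the plug-in approximation.

Residual diagnostics report the one-step in-sample errors
y_t - u - sum_j a_j y_{t-j} (t = p+1..n), a Shapiro-Wilk omnibus normality
test — chosen for its power at the short lengths typical here; with fewer
than 3 residuals the statistic is NaN — and Blom-position Q-Q pairs against
the fitted N(0, sigma^2). Back-testing fits on the first n-k years and
predicts each held-out year one step ahead using observed lagged values,
reporting the mean absolute error (NaN, flagged, for an empty holdout).

## Synthetic data

The generator serves two roles. `simulate_ar` is the plain Gaussian AR(p)
recursion with a 200-step burn-in (started at the process mean), explicit
seed, and bit-reproducible output. `simulate_case_study` emulates the
statistical shape of a short yearly commodity-price record and its induced
EIL series: log price follows a stationary AR(1) with lag-1 coefficient
0.6 (short memory — autocorrelation is negligible by lag 3), mean log-price
log(600), and innovation SD 0.08, giving strictly positive prices with a
~10% coefficient of variation, a realistic yearly swing for a fruit
commodity. The fixed constants C = 113 (currency/area), I = 2.5
(injuries/pest), D = 0.04 (yield loss/injury), K = 0.8 put the EIL level
near 113/(600·0.1·0.8) ≈ 2.35 pest specimens per sampling unit at the mean
price — the low-single-digit magnitude a larvae-per-fruit threshold
implies. Defaults are n = 15 years starting 1996.

What the fixture does *not* emulate: real price records have policy breaks,
trends, and occasional jumps that an AR(1) in logs cannot produce, and the
non-price EIL variables are genuinely constant here whereas in practice
management costs drift. Passing tests therefore demonstrate that the
estimation and forecasting machinery is correct and calibrated on its
stated model class, not that any particular crop's EIL follows an AR(1).

## Numerical choices and degenerate inputs

* Stationarity is checked through the roots of the monic reversed
  characteristic polynomial (reciprocals of the AR roots), which stays
  well-conditioned for arbitrarily small coefficients.
* Constant series are rejected by the fitters (zero variance has no
  Gaussian MLE) and produce a flagged zero-width chart in diagnostics.
* All file output uses 12 significant digits and atomic writes; identical
  seed and configuration reproduce every output file byte for byte.
* Replication sizes in the test suite and acceptance script (50 oracle
  models, 200 recovery replicates at n = 200, 100 selection replicates at
  n = 500, 500-600 coverage paths) are chosen so each study's sampling
  error is comfortably inside the asserted band while the whole suite stays
  quick on a single CPU.

## Known limitations

No moving-average terms, seasonal structure, unit-root testing, or
multivariate extensions; prediction intervals ignore parameter uncertainty;
EIL values are kept fractional (a threshold of 2.35 specimens per sampling
unit is meaningful as a decision boundary even though counts are integers);
no plotting — the CSV outputs are designed to drop into any plotting tool.
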