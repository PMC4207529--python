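# eilcast — stochastic modelling of economic injury levels

The **economic injury level** (EIL) is the cornerstone decision threshold of
integrated pest management: the pest density at which the cost of the damage
a pest inflicts equals the cost of controlling it. It is built from five
primary variables,

```
EIL = C / (V · I · D · K)
```

where *C* is the cost of the management tactic per production unit, *V* the
commodity price, *I* the injury units per pest, *D* the damage per unit
injury (so *I·D* is the slope *b* of the linear damage function
*Y = a + b·x*, *a* = 0), and *K* the proportionate reduction of injury
averted by the tactic. Because the commodity price *V* changes from year to
year, the yearly EIL is itself a stochastic process rather than a constant.

`eilcast` treats it as one. For crop-protection analysts and IPM
researchers it provides, as a Python library and a command-line tool:

* the deterministic EIL skeleton — pointwise EIL, damage-function slope,
  and the yearly EIL series induced by a yearly price series;
* pre-modelling diagnostics — an individuals & moving-range control chart
  (process sigma estimated as the mean moving range over d₂ = 1.128,
  3-sigma limits) and ACF/PACF correlograms with white-noise bands;
* stationary AR(p) fitting, `y_t = u + a₁y_{t−1} + … + a_p y_{t−p} + ε_t`
  with `ε_t ~ N(0, σ²)`, by **conditional** (prediction-error
  decomposition, closed-form OLS) or **exact** maximum likelihood (the
  conditional likelihood plus the stationary Gaussian marginal of the first
  *p* observations), with AIC = −2·log L + 2ρ order selection over
  p = 1..3;
* h-step forecasts with Gaussian prediction intervals from the MA(∞)
  ψ-weights, residual diagnostics, and hold-out back-testing;
* a synthetic-data generator that simulates AR(p) processes with known
  parameters and a case-study-like pair of yearly price and EIL series
  (short, positive, short-memory, EIL level in the low single digits),
  so the whole pipeline is testable without proprietary price data.

## Worked example

Simulate a 15-year case study (years 1996–2010), check it, fit, forecast:

```
eilcast simulate --seed 7 --prices-out prices.csv --eil-out eils.csv
eilcast diagnose eils.csv --chart-out chart.csv --correlogram-out corr.csv
eilcast fit eils.csv --report-out model.json --table-out table.csv
eilcast forecast eils.csv --order 1 --horizon 5 --out forecast.csv
```

The diagnose step logs

```
I-MR: center=2.35089 sigma_hat=0.195247 outliers=1; correlogram to lag 5
```

— the EIL process runs near 2.35 pest specimens per sampling unit with one
point beyond the 3-sigma limits (year 2009 in `chart.csv`). The order
comparison in `table.csv` shows AIC rising with order, so AR(1) wins:

```
order,a_1,a_2,a_3,intercept,sigma2,loglik,aic
1,0.627740615943,,,0.886191455473,0.0503753696223,0.877332984203,4.24533403159
2,0.768077669277,-0.251765167486,,1.13996469197,0.0476546124265,1.2425541695,5.514891661
3,0.829495349426,-0.450755492145,0.265940527946,0.842975599809,0.0442849379044,1.68624480754,6.62751038491
```

The fitted AR(1) has a₁ ≈ 0.63 and process mean u/(1−a₁) ≈ 2.38, and
`forecast.csv` carries the five-year outlook with 95% intervals:

```
year,point,lower,upper,forecast_sd
2011,2.55166504706,2.11176175316,2.99156834095,0.224444580292
2012,2.48797524379,1.96858034591,3.00737014168,0.265002266359
...
2015,2.40714235649,1.84471213477,2.96957257821,0.286959467703
```

The point forecasts revert geometrically toward the process mean while the
interval width grows toward the stationary standard deviation — exactly the
behaviour a farmer-facing threshold forecast should show: next year's EIL
near 2.4–2.6 specimens per sampling unit, with honest uncertainty.

The same operations are available as library calls
(`eilcast.simulate_case_study`, `eilcast.imr_chart`, `eilcast.correlogram`,
`eilcast.fit_ar`, `eilcast.select_order`, `eilcast.forecast`, …).

## Limitations

Prediction intervals are Gaussian plug-in intervals: parameter-estimation
uncertainty is not propagated. The synthetic case study emulates the
statistical shape of a yearly commodity-price record, not any particular
market. See `docs/methods.md` for the model details, defaults, and design
choices.
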