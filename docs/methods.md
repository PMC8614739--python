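# Methods

This note records the models, conventions and numerical choices behind
`ratemc`, and what the synthetic benchmarks do and do not establish.

## Units and conventions

Time is in hours, volume in litres, flows in L/h, concentrations in g/L.
The "biomass" variable X is always *catalyst amount per litre in the unit the
specific rates are normalised to*: g/L dry weight for microbial processes
(rates in g/(g·h), µ in 1/h), and 1e8 cells/L for cell cultures (rates in
g/(1e8 cells·h)).  With that convention `dC/dt = q·X` holds without hidden
scale factors; any conversion (e.g. cells/mL from a counter) happens at
ingestion and never downstream.  Uptake rates are negative when consuming;
magnitudes are used only for display and as the regression abscissa
(`magnitude_x`, default on).  One sigma always means the 68.3 % two-sided
Gaussian interval; 3σ control limits are labelled with their conventional
99 % while the exact coverage (99.73 %) is reported alongside.

## Interval rate estimation

Between consecutive offline samples the biomass-specific rate is assumed
constant and identified by minimising the squared mismatch between the
integrated component balance and the measured end point(s).  Two dilution
forms are supported:

* `strict` (default): the dilution sink is `−D·cX` in every balance, i.e.
  proportional to biomass.
* `standard`: the dilution sink is `−D·c` for the balanced component itself.

For a fed-batch (no outflow) the physically standard form for a dissolved
component is `−D·c`; the strict form is kept as the default because it is
the form this evaluation chain is defined with for biomass-based (g/L)
processes, and the two differ little when `D` is small against `q·X/c`.  For
cell-count-based processes (CHO preset) the strict form is not dimensionally
meaningful, so that preset uses `standard`.  Round-trip tests always use the
same form on both the generating and estimating side.

Numerics: the balance ODE is solved by a Dormand–Prince 4(5) pair (rtol
1e-8, compiled with numba) whose steps never straddle a knot of the
piecewise-linear input profiles (biomass trajectory, dilution, feed term) —
the embedded error estimator cannot see a kink crossed mid-step, and
knot-aligned stepping restores the nominal accuracy.  The scalar search uses
a bounded minimiser (tolerance 1e-10 on q, |q| ≤ 10) bracketed around a
finite-difference initial guess, with the bracket widened geometrically if
the minimum lands on an edge; because the modelled end point is monotone in
q, a bracketed root polish on the signed mismatch guarantees mass-balance
closure (residual ≤ 1e-5 of the concentration scale, and the fit errors out
if it cannot close).  The growth fit also returns the continuous biomass
trajectory it implies — the exact solution `c0·exp(µ(t−t0) − ∫D)` with the
trapezoid integral on the dilution knots — which the uptake/production
balances consume, keeping the whole chain internally consistent (biomass is
never linearly interpolated between samples).

Intervals are consecutive sample pairs by default; a `group` parameter fits
one rate across several samples by minimising the summed mismatch at the
interior and end points.

## Measurement error model

Per-signal uncertainty specs are `absolute` (device accuracy, e.g. balances
±0.1 g, syringes ±3 mL), `relative` (e.g. ±3 % for enzymatic/HPLC
concentrations, ±2.5 % for product), or `replicate`.  `resolve_sigma` for
replicates returns the sample standard deviation (n−1 denominator) — the
uncertainty of an *individual* measurement; with duplicates this equals
|difference|/√2.  Because the stored series value is the replicate *mean*,
the resampling chain perturbs it with the standard error of the mean
(σ/√n_rep, `sigma_of_mean`); using the full replicate σ there would inflate
every propagated error by √n_rep, which the calibration study (below) rules
out.  An optional per-signal σ floor guards against spuriously zero
replicate spreads (default 0).

## Monte Carlo propagation

`propagate_chain` evaluates an acyclic graph of steps N times (default 500;
a config knob) under Gaussian resampling `x + σ·R`, without truncation at
physical bounds — clipping would bias the summaries; the rate of, say,
negative concentration draws is an input-quality signal, not something to
hide.  Two chaining variants:

* `chained` (default): each downstream node draws fresh Gaussians around the
  upstream ensemble's (mean, σ̄).  Only two moments travel between steps.
* `coupled`: realizations pass through unchanged, preserving correlations.

The two agree for linear chains (verified to 15 %); `chained` is the default
because per-step (mean, σ) summaries are what practitioners report, and the
per-rate nodes are made robust to its main weakness by refitting the growth
rate from their own biomass draws, so the biomass-trajectory error is
carried into the uptake/production rates rather than double-counted.

Randomness: one master seed; each node and raw signal gets a deterministic
substream keyed on its name (SHA-derived, below 2^31), so adding a node
never reshuffles the other draws and fixed-seed runs are bit-reproducible.
Realizations on which a node raises are dropped and counted; more than 5 %
failures abort the run.

Inside the Monte Carlo loop the derived dense series (dilution, feed term)
are block-averaged onto ~8 bins per sampling interval before entering the
ODE fits, and the solver runs at rtol 1e-6 with a 17-knot biomass
trajectory.  Point-wise white resampling noise on a 30-s grid carries no
information for interval-scale rates but forces tiny integrator steps;
averaging preserves the running integral (the quantity the balances respond
to).  The deterministic pass always uses the full-resolution profiles and
rtol 1e-8.

The reported `relative_error` of a step is the time-average of σ̄/|ȳ| over
positions with |ȳ| above a mask (1e-6 of the series maximum) — near zero
crossings the ratio is undefined and excluded.

## Errors-in-variables regression

`york_fit` minimises the weighted both-axes objective with weights 1/σ² per
point and axis, by York's iterative slope update (convergence |Δb| ≤
1e-12·|b|, at most 100 iterations), with standard errors and the a–b
covariance from the unified York (2004) formulas.  Zero σ on one axis is
capped at weight 1e12, recovering weighted least squares (verified against
OLS).  The error correlation r per point is exposed but defaults to 0.
`mc_regression` refits on jointly perturbed coordinates; the (intercept,
slope) cloud yields `cov_P`, per-parameter σ, prediction σ on a grid, the
68.3 % error ellipse (χ²(2) scaling, closed form −2 ln(1−p)), and k·σ
confidence bands.  Analytic York errors and the cloud spread agree within
25 % on well-conditioned data — York's solution is essentially unaffected by
resampling — whereas unweighted least squares under resampling scatters
strongly when a high-σ leverage point is present; both behaviours are
regression-tested.

## Decision support

Control limits are set-point ± k·σ with k = 3 by default, σ being the
propagated uncertainty of the controlled rate.  `critical_input` finds by
bisection (1e-10) the x at which the k·σ prediction bound meets a target
output, and refuses to produce a limit when the slope's sign is not
consistent in ≥95 % of the Monte Carlo cloud — an uncertain-sign relation
cannot support a control limit at the stated confidence.
`threshold_probability` uses the plain Gaussian measurement model
Φ((value−threshold)/σ) with the *measurement* σ of the signal (viability
duplicates), not a chain-propagated one.  `decide_time_point` returns the
latest compliant time (maximise culture time subject to certainty); an
`earliest` policy exists for threshold-entry events.

## Synthetic data

`simulate_truth` forward-integrates the selected balance form with
prescribed piecewise-constant rates aligned to the sampling grid (classic
RK4, steps ≤ 0.005 h, withdrawals as volume steps at the sampling instants;
a step-halving test pins the endpoint accuracy to ≤1e-6 relative).
`observe` applies the error model: replicate draws per signal (triplicate
dry weights/HPLC, duplicate cell counts and viability), balance-weight noise
(±0.1 g) on the online logging grid, and syringe noise (±3 mL) on the
withdrawn volumes.

Preset conditions (chosen once as realistic study conditions):

* `ecoli_like`: 12 h induction, 2-h sampling, V0 = 1 L, cX 8→18 g/L (µ
  0.12→0.04 1/h), exponential 500 g/L glycerol feed sized to the declining
  demand, small constant base flow, qP = 0.15·|qS| + 0.0005, 30-s balance
  logging, strict dilution form.
* `cho_like`: 10 days, daily sampling, V0 = 2 L, cells 3→69 (1e8/L),
  two-segment 50 g/L glutamine feed, qlac = 1.9·|qgln| − 0.004 (lactate
  production turns into consumption near |qgln| ≈ 0.0021 — the overflow
  shift), viability declining to 88 % with the 90 % crossing between days 9
  and 10, 5-min balance logging, standard dilution form.

What passing tests show: the estimator inverts the generator exactly on
noise-free aligned data; the propagated σ are *calibrated* (over 200 fresh
observations of the same truth, 1σ covers ≈68 % of the substrate-uptake
errors); the regression/limit/decision layers behave as designed under a
Gaussian error model.  What they do not show: robustness to model error the
generator does not emulate — rate drift within intervals, non-Gaussian or
correlated analytical errors, sampling-time uncertainty, evaporation or gas
stripping, or calibration drift of the analytical devices.

## Problem sizes

Defaults used by the test suite and the acceptance script: N = 500 Monte
Carlo repetitions per propagation (one figure-style convention uses 1000;
N is a knob), 200 replicates for the coverage/calibration studies, 100
random instances for the York-oracle property, 1e6 draws for the brute-force
nonlinear-propagation oracle.
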