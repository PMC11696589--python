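# Methods

## Data model and conventions

Monthly surveillance series are (unit, year, month, deaths, population)
rows; months must be consecutive, deaths non-negative integers,
population positive. Epidemic years follow the November–October
convention ("1889/90" = Nov 1889–Oct 1890). District flu mortality is
stored in deaths per 1 000 inhabitants; a `mortality_units` column with
`per_10000` triggers a ÷10 conversion on read, because historical
sources quote both scales. Percent columns (attack rate, population
shares) are stored as fractions on [0, 1] internally and written back
as percentages.

Monthly population denominators are linearly interpolated between
annual or census anchor values and held constant beyond the first and
last anchor. Anchors are pinned to mid-year (month 6); interpolation is
exact at anchors and monotone between adjacent ones. This is a
smoothness convention, not a demographic model.

## Seasonal Poisson baseline

The baseline is a log-linear Poisson rate model with log population as
offset and k sine/cosine harmonic pairs of period 12 (default k = 1;
the pair captures a single annual mortality cycle peaking in winter).
It is fitted by Newton–Raphson (equal to Fisher scoring under the
canonical log link) with a least-squares start on log(y + 0.5);
convergence is declared when the largest coefficient step falls below
1e-10, typically after 3–5 iterations. Coefficient covariance is the
inverse observed information at the optimum. All-zero count windows
are rejected (degenerate likelihood). The default fit window is the 60
months ending immediately before December 1889 — one pre-pandemic
baseline projected through the end of 1894, so the 1893/94 winter is
judged against the same counterfactual; a caller can instead supply
any window of at least 24 months.

The solver is authored here rather than wrapped from a GLM library
because the parametric bootstrap refits the same small design tens of
thousands of times; a batched Newton iteration (shared design matrix,
stacked 3×3 solves) runs the whole bootstrap in milliseconds. Unit
tests verify exact agreement with an independent GLM implementation
and with a brute-force likelihood grid search.

### Prediction intervals

The 95% PI for a future observed count is a parametric bootstrap: for
each of n_boot (default 1000) replicates, fit-window counts are
resampled from Poisson(mu_hat), the model refitted, means predicted on
the prediction window, and one future count drawn from
Poisson(mu_star). PI bounds are the empirical 2.5% and 97.5% quantiles,
so the interval carries both estimation and observation noise. Failed
refits (e.g. an all-zero resample at very low counts) are dropped and
counted; more than 5% failures aborts. Everything is deterministic
given the seed (default 1890). Replicate-level batching makes 500
series × 500 bootstrap replicates a few seconds of work.

Excess is observed − expected in counts and 100·(obs − exp)/exp in
percent; the percent CI is the prediction interval mapped through the
same transform (low = (obs − pi_high)/exp, high = (obs − pi_low)/exp).
A month is flagged a significant excess (deficit) when the observed
count exceeds (falls below) the PI. This PI-based flag matches the
interval semantics of the excess tables; it is one defensible mapping,
not the only one.

### A note on seasonal-form mismatch

The synthetic generator uses a linear-multiplicative seasonal factor,
lambda ∝ 1 + a·sin(2πm/12 + φ), while the model is log-linear. For
a = 0.3 a single log-scale harmonic overestimates the seasonal peak by
about a²/4 ≈ 2.5% (the missing higher Fourier terms of
log(1 + a sin θ)), which would depress a peak-month excess estimate by
the same amount. The calibration studies that measure shock recovery
therefore fit with k = 3 harmonics, which represents the generator's
seasonal shape to numerical precision and isolates the property being
measured (recovery of an injected shock) from harmonic truncation.
Prediction-interval coverage is insensitive to this at a = 0.3 and is
evaluated at the default k = 1. On real data the truncation question
is an empirical one; the k option is exposed for exactly that reason.

## Local G hotspot statistics

Gi (self excluded) with row-standardised binary contiguity weights is
the default; Gi* (self included) and raw binary weights are options.
z-values use the Ord–Getis normality approximation with the mean and
variance of the statistic under spatial randomness computed per unit
(excluding the unit itself under Gi). Conditional permutation p-values
are available separately. z is invariant to adding a constant to all
values and to positive rescaling. Districts with no neighbours get
z = NaN and are flagged; a constant surface is rejected as degenerate.
Cluster labels use |z| > 1.96 for tabulation; maps should bin z
continuously. No multiple-testing correction is applied across
districts — the labels are descriptive, and neighbouring z-values are
strongly correlated, so the family-wise false-positive rate over a
whole lattice is well above 5% (the permutation-calibration test bounds
the per-district rate only loosely).

## Robust ecological regressions

Univariable Huber M-estimates (c = 1.345, 95% Gaussian efficiency;
MAD residual scale re-estimated each IRLS iteration, statsmodels RLM
underneath; max 200 iterations, coefficient tolerance 1e-8).
Predictors enter on their natural scales, so slopes read as flu deaths
per 1 000 per metre of altitude, per person/km², per unit fraction of
the labour force, etc. CIs are ±1.96·SE; significance means the CI
excludes zero; no adjustment for multiple comparisons is made across
the determinant panel (exploratory semantics). MM-estimation would be
the natural upgrade if higher breakdown mattered more than efficiency.

The cross-protection analysis regresses 1893/94 district mortality on
first-wave burden (1889/90 mortality, cumulative 1889–1893 mortality,
or the physicians' 1890 attack-rate estimate). The headline slope is
the robust fit; the urban/rural scatter-plot lines are ordinary
least squares per stratum (omitted below 3 districts), and both are
reported because they answer different questions (resistant central
trend vs. stratum-wise visual summary).

## Synthetic generators

The monthly generator draws independent Poisson counts around the
rate above, with defaults mirroring the historical study conditions:
ten years from 1885, baseline rate 2e-3 deaths per person-month,
amplitude 0.3 with the peak in January, population 1e5 growing
linearly, and a ×1.589 shock in January 1890 (the headline first-wave
excess used as a scenario parameter). The district generator places
182 districts on a 13×14 rook lattice; first-wave mortality is a base
level of 8 per 1 000 plus centred linear covariate effects (negative
for altitude and agriculture, positive for density, age, industry and
rail, null for GDP and hospitals), a Gaussian hotspot surface (peak
10 per 1 000, length scale 2 cells) at the lattice centre, and
Gaussian noise (sd 2), truncated at zero. Later seasons are weak
(means 0.8–3 per 1 000) with the 1893/94 recurrence coupled to the
first wave (slope 0.35; set 0 for the independence null). Attack rates
are Beta-distributed with mean 0.61. Covariates are drawn mutually
independently, so univariable regressions are unbiased for the
injected slopes — a deliberate simplification: real ecological
covariates are collinear (urbanity, density, rail), and passing
recovery tests here say nothing about confounding in real data. Other
real-data features the generator does not emulate: overdispersion,
spatially correlated noise beyond the hotspot surface, demographic
trends other than linear population growth, and reporting artefacts.

The weekly generator exists to reproduce two phenomena as data
features (not statistics): a multiplicative birth dip centred a
configurable 9 months after the epidemic peak, and a postal-worker
incidence curve leading the population curve by a configurable 1–2
weeks.

Truncation at zero (rather than redrawing) is used for negative
mortality draws; it is rare under the default scenarios and keeps the
generators pure functions of (scenario, seed).

## Calibration studies and problem sizes

`fluexcess.experiments` packages the repeated-simulation studies: PI
coverage (500 series of 72 months, fit 60/hold out 12, n_boot 500),
shock recovery (200 series per shock size, k = 3 harmonics), robust-CI
coverage of the altitude and density slopes (200 district tables), and
the cross-protection null (200 tables with coupling 0). These sizes
give Monte-Carlo standard errors comfortably inside the properties
being asserted (e.g. ~0.6 percentage points for mean excess) while the
whole battery runs in well under a minute on one core.

## Known limitations

- Poisson (no overdispersion) by design; negative-binomial baselines
  are out of scope.
- The percent-scale excess CI is a transformed prediction interval,
  not a percentile-bootstrap CI of the excess ratio; the two differ
  slightly in small counts.
- Gi/Gi* variance uses the normality approximation; for very skewed
  surfaces prefer the permutation p-values.
- The GeoJSON contiguity builder is O(n²) pairwise intersection —
  fine for hundreds of districts, not for large polygon sets.
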