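# Methods

## The problem and the data model

Weekly surveillance of slaughter condemnations records, per plant, week,
and swine class, the head slaughtered (*N*) and the head condemned "dead"
(*Y*). Ambient conditions are not observed at the plant; they are
reconstructed from nearby weather stations. The analysis asks how much of
the week-to-week variation in the per-head "dead" rate is attributable to
heat (via the heat index) and cold (via the weekly mean daily minimum),
and what the attributable condemnations cost in foregone revenue.

## Weather linkage

Plants are matched to stations by great-circle (haversine) distance on a
sphere of radius 3,958.8 statute miles (fixed so distances are
bit-reproducible). Each plant keeps its closest one to three stations
within 100 miles; station assignment is per plant, not re-ranked per week.
Daily observations from the assigned stations are pooled by unweighted
mean within ISO-8601 weeks (Monday start) into weekly average temperature,
weekly mean daily minimum, and weekly mean relative humidity. Unweighted
pooling is the simplest reading of "closest 1–3 stations"; no distance
weighting or spatial interpolation is attempted. Plants with no qualifying
station are excluded with a logged head count, never imputed. Weeks with
at least one daily observation are used by default; a `min_days`
configuration can require more.

## Exposure categories

The heat index is the NWS Rothfusz 9-coefficient regression in °F and %RH
with the two standard adjustments (a low-humidity subtraction for RH < 13%
and 80–112 °F; a high-humidity addition for RH > 85% and 80–87 °F). It is
computed from the weekly average temperature and humidity (not averaged
over daily HI values) and treated as defined only for weekly averages of
80 °F and above.

Category bounds are compared on °F rounded half-up to integers, matching
the integer-labelled bins; the scheme is:
baseline 54–79 °F weekly average (minimum above 50 °F); HI moderate
80–84, hot 85–92, very hot 93–106; minimum-temperature cool 40–50, cold
10–39, very cold −17–9. Warm-minimum weeks whose rounded average falls in
79–80 °F are kept in baseline (the alternative — a sliver of excluded
weeks between the bins — serves nothing). HI above 106 °F or minima below
−17 °F are outside the calibrated range and are excluded with a logged
reason rather than extrapolated. The assignment is exhaustive and disjoint
on the modelled set; a rare warm-minimum week with rounded average below
54 °F is excluded (physically near-impossible, since the average bounds
the minimum).

The exploratory spline smooths the per-head rate *y/N* against a
continuous predictor with head-count weights — the offset-as-weight
reading of a log-total offset, which makes high-volume plant-weeks
proportionally more influential. Smoothing uses a cubic smoothing spline
with the penalty chosen by generalized cross-validation unless fixed.
Duplicate abscissae are collapsed to weighted means (the smoother needs
strictly increasing x); fitted intensities are clipped at zero. Suggested
cutpoints sit at the largest-curvature grid positions (quantile fallback
on a flat curve, separated by a minimum spacing); they are advisory — the
pipeline always uses the fixed published bounds.

## The count model

For row *i* in volume-category group *g*:

    Y_i | u_g ~ ZINB(mu_i, theta, pi),   mu_i = exp(x_i'beta + log N_i + u_g)
    u_g ~ Normal(0, sigma_u^2)

NB2 parameterization (conditional variance mu + mu²/theta); the zero part
is an intercept-only mixing probability pi shared by all rows; the random
intercept enters the count part only. The fixed design is cell means over
swine class × exposure category (nested coding: each class's baseline is
its own reference), which is full-rank by construction.

Estimation maximizes the exact marginal likelihood: the per-group
integral over u is evaluated by adaptive Gauss–Hermite quadrature — the
integrand is re-centred at its mode (damped Newton with analytic first and
second u-derivatives) and rescaled by its curvature before applying the
rule; one node is exactly the Laplace approximation. The default 15 nodes
agree with 31 nodes to < 1e−4 log-likelihood per observation on the
recovery regime. Optimization is L-BFGS-B on (beta, log theta, logit pi,
log sigma_u) with analytic gradients via Fisher's identity (the score of a
marginal likelihood is the posterior expectation of the complete-data
score, evaluated with the same quadrature rule); starting values come from
per-cell Poisson rates and a crude zero-fraction split, with up to three
jittered restarts on non-convergence, and a failed fit is returned flagged,
never silently. The Wald covariance is the inverse of a
finite-difference Hessian of the negative marginal log-likelihood
(central differences of the analytic gradient); the coefficient block is
projected to the nearest positive semidefinite matrix to absorb
finite-difference noise.

The condemnation rate reported for a cell is population-level:
CR = (1 − pi)·exp(beta_cell), with the random effect at zero and the
offset removed. This treats the weekly count rate per head as a per-head
probability — a Poisson-thinning approximation that is excellent at rates
of a few per thousand. Risk ratios within a class reduce to
exp(beta_exposed − beta_baseline) exactly (the zero part cancels), so
their delta-method standard errors need only the coefficient covariance.
CIs are Wald intervals on the log scale.

With only five random-effect groups, the mean of one realized draw of
intercepts is not separable from the fixed effects; fixed-effect
uncertainty therefore carries a large between-group component (this is
visible in the coefficient SEs) and coverage of Wald intervals was
verified by simulation (93% pooled at nominal 95% over 50 replicates).

## Risk metrics and revenue attribution

EIR rounds CR × 10,000 half-up to an integer; AR and RR are computed on
unrounded CRs and rounded only for display (CR display precision follows
the class convention: five decimals for roasters, four otherwise). DLR is
condemned/total × 100.

The counterfactual model for revenue is the same mixed model with swine
class as the only fixed effect, fitted to baseline-temperature weeks.
Expected counts on extreme weeks use the estimated random-effect mode of
the week's volume category (prediction for the observed groups;
`population` mode sets u = 0). Residuals are summed signed — negative
category totals are possible and reported as such. Pricing: each ISO week
is priced at its majority calendar month (the month of its Thursday);
market and cull sows at that month's price per head; roasters at
(70 lb / 100) × the market dressed price per hundredweight, i.e. the
median roaster carcass valued at the dressed $/cwt — the multiplication
reading of the pricing rule, since a division would not yield dollars.

## The synthetic generator

The generator emulates the study conditions: 149 plants over 6 years
(2010–2015) with the five-level volume mix dominated by small plants but
most head at the few very large ones; very large plants are market-only,
and roasters come almost entirely from the smallest plants. Weekly head
counts are log-uniform within the published per-category ranges with
15% lognormal week-to-week variation.

Weather is a smooth function of location (annual mean cooling and seasonal
amplitude growing with latitude, sinusoidal seasonality peaking in July)
plus a spatially coherent regional daily anomaly field: a national
anomaly (SD 5 °F) with gentle north–south and east–west gradient terms,
shared by all locations on a given day, plus instrument-scale station
noise (0.2 °F). Spatial coherence is essential, not cosmetic: a plant's
closest stations may belong to a neighbouring plant, and with independent
per-plant noise that pooling would misassign ~8% of weeks and attenuate
every recovered risk ratio; with a coherent field the pipeline's pooled
weekly exposure reproduces the generating category in about 98% of weeks
(residual disagreement is knife-edge rounding and the real climate
difference carried by stations up to 90 miles away).

Counts are drawn from the model's own process with the published per-cell
CRs as truth: the NB mean is N·CR·exp(u_g)/(1 − pi), so the unconditional
per-head mean at u = 0 equals the declared CR, and the fitted
population-level CR estimates it directly. The five realized group
intercepts are centred to zero mean (their mean is unidentifiable from the
fixed effects with five groups; sigma_u remains the dispersion); the truth
category drives the draw through the real exposure code, never a shortcut
label. With pi = 0.45 roughly half of plant-weeks record zero
condemnations, as in the emulated setting. Prices follow seasonal shapes
(market price per head and dressed $/cwt peaking in July, cull sows
peaking in June with a different amplitude) with small noise, extended one
month beyond the record span because boundary ISO weeks price into the
neighbouring calendar year. A configurable fraction of plants is placed
on a remote, widely spaced grid with stations 120–150 miles away to
exercise the exclusion path deterministically.

What the generator does **not** emulate: spatial heterogeneity of weather
within a plant's 100-mile station radius beyond a smooth gradient (real
station scatter would attenuate risk ratios toward 1 through exposure
misclassification), serial correlation of weekly counts, transport-level
covariates (journey length, trailer type, stocking density), disease
outbreaks, and price–supply feedback. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated
model, not robustness to these real-data features.

## Problem sizes and numerical choices

The default test suite runs the full default-scale pipeline once
(~150 plants × 6 years, ≈113k records; about a minute) and uses
scaled-down replicate studies elsewhere: Wald coverage over 50 replicates
of 400 rows; risk-ratio CI coverage over 50 replicates of 600 rows;
end-to-end pooled CI coverage over 6 pipeline replicates of 30 plants ×
2 years; null calibration of the excess attribution over 20 replicates of
1,200 rows. The baseline-model recovery example uses 12,000 rows so that
its Monte-Carlo error (2 SE ≈ 4%) sits inside the 5% comparison
tolerance. Optimizer bounds keep log theta in [−8, 12], logit pi in
[−12, 8], and log sigma_u in [−8, 3]; degenerate data (pi = 0,
sigma_u = 0) push the estimates to those boundaries and reproduce a plain
NB regression to 1e−3, which the suite cross-checks against an
independent implementation.

## Known limitations

- Exact reproduction of the original study's fitted tables is impossible
  without the non-public inspection records; the reproducible part is the
  definitional arithmetic connecting the published per-cell rates to the
  published risk ratios, attributable risks, incidence rates, percentages
  and dollar totals, which the suite checks cell by cell. (Five printed
  percent cells in the revenue table are internally inconsistent with
  their own row values — two are transposed and three reflect unrounded
  inputs — and are tested as such.)
- The zero part is intercept-only; exposure-dependent zero inflation is
  not modelled.
- No spatial or temporal autocorrelation; no plant-level random effects
  beyond the five-level volume grouping.
- Foregone revenue is gross, not net, and ignores price responses to
  changed supply.
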