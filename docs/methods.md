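# Methods

This note records the models implemented, their assumptions, the defaults
that matter, and the choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Distance-effect models

Responses observed at distance `d` from the nearest seamount summit are
modelled as

    g(E(y_i)) = b0 + f_s(d_i) + b1 x_i ,

where `f_s` is a low-rank thin-plate regression spline and `x` holds
optional parametric covariates (survey season, CTD instrument). In one
dimension the thin-plate spline is the cubic smoothing spline: the basis is
built from the radial kernel |r|^3/12 on quantile knots with the order-2
polynomial null space absorbed by a QR constraint, so the penalty equals
the integral of the squared second derivative (verified against numerical
quadrature in the tests). The smooth term carries its own (unpenalized)
linear column; the model intercept is separate. Covariates are
standardized to [0, 1] inside the basis so smoothing parameters are
dimensionless.

Families: Gaussian (identity link), negative binomial, Tweedie
(variance power p in (1,2), default 1.5), quasi-Poisson and quasi-binomial
(log/logit links). Fitting is penalized IRLS with step-halving; smoothing
parameters minimize a working-model REML score (penalized working RSS,
log-determinants of the penalized information and the penalty, dispersion
profiled where the family has one). The negative-binomial shape `theta` is
profiled in an outer loop that matches the Pearson statistic to the
residual degrees of freedom. The reported coefficient covariance is the
Bayesian posterior `phi * (X'WX + S)^-1`, which conditions on the selected
smoothing parameters (smoothing-parameter uncertainty is not propagated —
a known, deliberate limitation shared with standard practice).

Structure selection compares a single global smooth, per-seamount smooths
and depth-group smooths: by AICc (with effective degrees of freedom as the
parameter count) for likelihood families, and by the smooth-difference
criterion for quasi families — candidate smooths are merged whenever the
95% band on their pointwise difference covers zero along the entire
100-point grid.

Random transect intercepts are a ridge-penalized indicator block whose
penalty weight is selected by the same REML score (equivalent to an i.i.d.
Gaussian random effect). Within-transect AR(1) residuals are handled by
estimated-rho Prais–Winsten whitening for Gaussian responses, with rows
ordered along the transect by distance; count families use an independence
working model (the whitening request is recorded with a warning rather
than silently honoured).

### Radius of influence and enrichment magnitude

The first derivative of the smooth is evaluated by central finite
differences (grid of 100 points, step = range/1000) with a pointwise 95%
interval propagated through the difference operator from the coefficient
posterior. Scanning from the far field toward the summit, `R` is the
largest grid distance whose derivative interval excludes zero; if no point
is significant the result is an explicit "no effect". The magnitude is
`E(y|d=0) / mean(E(y|d>R))` on the response scale, its interval the
2.5/97.5 percentiles of the same ratio recomputed over (seeded)
multivariate-normal posterior draws.

For non-Gaussian fits whose far-field predicted response falls below 0.05,
an enrichment cannot be separated from a monotone trend on the link scale;
the estimator then switches to baseline-crossing mode: `R` is the furthest
distance at which the predicted response exceeds
`max(oceanic reference mean, 0.05)`, gated on a Wald-type test of the
smooth term, and no magnitude is reported. The derivative scan direction
reads "furthest point at which a significant change was first detected" as
the largest significant distance.

Two design facts about this estimand, established with the package's own
simulations and cross-checked by refitting identical datasets with an
independent GAM implementation (R mgcv, REML, same scan): the significant-
slope region extends beyond the true kernel support by roughly the smooth's
resolution scale, so `R` is an upper-bounded-bias estimator; and resolving
a ~5-km feature requires knot spacing around 1 km. The recovery
experiments therefore use basis dimension k = 20 over a 20-km survey
extent — the extent of the seamount deployments themselves — while the
generator's default distance range for generic use remains 0–40 km.

### Two-proportion contrast

`two_proportion_test` is the continuity-corrected (Yates) 1-df chi-square
on the 2x2 presence table (scipy's `chi2_contingency`); an uncorrected
mode is available.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of a frozen config dataclass containing
the seed; identical configs give identical output, and each generator
returns its planted truth.

- **Radial surveys**: distances uniform over the survey extent (the
  sampling-density design is not dictated by the survey protocol; uniform
  is the neutral choice). The mean follows a compact-support enrichment
  kernel: exactly `baseline * multiplier` at the summit and exactly
  `baseline` beyond the true radius, so the estimand of the recovery tests
  is unambiguous. The default "compact-logistic" shape uses steepness
  0.2R — a smooth shoulder, as a biological aggregation gradient would
  have; a near-step shoulder is both unrealistic and unresolvable by any
  spline basis. Noise families: negative binomial (theta default 1.5,
  matching strongly overdispersed predator counts), compound
  Poisson–gamma Tweedie, Gaussian. Continuous-survey modes add lognormal
  transect intercepts and within-transect AR(1) on the link scale.
- **Hydroacoustic fields**: 500-m distance bins, 50-m strata to 300 m. A
  Gaussian-in-depth scattering layer (default centre 100 m) weakens near
  the summit and is replaced by a deeper accumulation (default 200 m);
  each cell's class is drawn with probability proportional to the class
  intensity at that depth, and its Sv carries the class ΔSv(120−38)
  signature. Class competition means the classified summit:baseline ratio
  only equals the planted fish multiplier when one class dominates; the
  pipeline test controls for this explicitly.
- **Detection histories**: residents persist all study (daily detection
  probability 0.97); transient departure days are exponential (mean 45 d).
  Hourly detections follow a cosine diel modulation; detections on the
  first two days are guaranteed so the track-start rule is exercised
  deterministically. Times are generated in UTC; diel phase uses a
  configured local offset.
- **Tracks**: gamma step lengths (12-h steps, shape 2, scale 8 km) and
  wrapped-Cauchy turning angles (rho 0.7). `attraction = 0` is an
  unbiased CRW; positive attraction rotates headings toward the summit,
  and site-attached animals shorten steps inside a 5-km settlement zone
  (area-restricted search). Default duration 60 steps (a 30-day
  deployment, matching the tracking-duration subset for which fidelity is
  testable).
- **Environment**: chlorophyll scenes are a latitudinal gradient plus
  spatially correlated noise, an optional summit bump and a smooth cloud
  mask, on ~4-km cells stored as plain cell tables; CTD profiles have a
  two-layer thermal structure (mixed layer 65 m) and a Gaussian DCM
  (100 m); the moored temperature series is a seasonal trend plus an M2
  sinusoid (12.4206 h) plus Gaussian noise at comparable amplitude,
  default 10-minute resolution over 595 days; range tests are binomial
  detections per 180-s bin under logistic distance decay (midpoint 600 m,
  scale 80 m, 18 pings per bin).

None of this emulates hydrodynamics, bathymetry, tag physics or real
spatial covariance structure. Passing recovery tests therefore show that
the estimators retrieve known truth under the assumed statistical
structure — not that the structure matches any particular ocean.

## Residency analytics

Day boundaries are taken in local time (configurable UTC offset), since
diel statistics are local-time phenomena. The RI denominator runs from the
track start (first detection on two consecutive days) to the study end,
matching a fixed common tracking period; tag-specific windows are
supported. "Still present" for the attrition curve means any detection on
or after the day (same-day mode available). Diel profiles use a cyclic
cubic P-spline (periodic B-spline columns with a wrapped second-difference
penalty; value and slope continuous across midnight) plus animal random
intercepts under a quasi-binomial variance. Receiver-use intervals
bootstrap animals, not detections, preserving within-animal dependence
(1,000 seeded resamples). PAM clustering solves the k-medoid objective
exactly by enumeration whenever C(n,k) <= 5000 and by BUILD+SWAP beyond,
with lowest-index tie-breaking — this guarantees agreement with
brute-force enumeration at the small n where that oracle is computable.
AMDR fits a binomial penalized spline of detection probability against
distance per site, averages predicted curves across sites and reports the
first distance below the 5% threshold, censored at the maximum tested
distance when never reached. RI comparisons use a quasi-binomial GLM with
Pearson-estimated dispersion and F-tests from dispersion-scaled deviance
drops.

## Dispersal

The fidelity null resamples the observed empirical step and turn samples
with replacement (a nonparametric reading of "same movement parameters";
parametric gamma/wrapped-Cauchy is available in the generator), starts at
the tagging location with uniform initial bearing, and propagates with
local-tangent-plane steps re-projected each move — adequate at the
few-hundred-km scales involved. The one-sided p-value counts simulations
ending at least as close to the summit as the observed final position
(ties as closer, conservative, with a 1e-6 relative tolerance absorbing
floating-point propagation noise). Isopleth curves report per-day distance
quantiles of the simulated ensemble. Utilisation distributions merge by
deployment-length weights and renormalize; volume contours take cells in
descending density until the requested mass is enclosed, which makes masks
nested in the level.

## Oceanography

The DCM is the chlorophyll maximum below a 5-m surface-exclusion cap
(ties report the shallower depth, flagged; monotone profiles are flagged
surface-type). The MLD criterion is a 0.2 °C drop below the 10-m reference
temperature — the profile data give only an "isothermal layer", so the
threshold is configurable. CEI uses per-cell 30–90 km haversine annuli
(Earth radius 6371 km) over unmasked cells, and scenes above 50% cloud are
rejected outright. Radial bins are half-open [i, i+1) km with a 1e-9
epsilon guarding boundary cells. Tidal spectra: block-average to 10-minute
means (full resolution supported), loess detrend with a span covering
~30 days, Hann-tapered periodogram smoothed over 3 Fourier bins, peak
reported within the 2–26 h period band. At 595 days the Fourier period
resolution near 12.4 h is ~0.01 h, comfortably inside one printed decimal.

## Numerical choices and degenerate inputs

Penalties are Frobenius-normalized so log-lambda is searched over a fixed
bracket (scalar bounded search for one penalty, Nelder–Mead for several);
IRLS uses a 1e-10 ridge jitter and step-halving; posterior covariance is
symmetrized and draws fall back to eigen-decomposition with jitter bounded
by a PSD check. Empty survey sets return zeros with warnings; censored
results (AMDR never below threshold, isothermal MLD) are flagged rather
than guessed. All stochastic steps take explicit seeds; generator configs
can be written to YAML run manifests.

## Known limitations

- Smoothing-parameter uncertainty is not propagated into derivative bands,
  so `R` intervals are slightly anticonservative; `R` itself carries
  positive bias of order the smooth's resolution.
- PQL-style quasi-family fits have no true likelihood; their structure
  selection relies on the smooth-difference criterion only.
- The Tweedie power is fixed (default 1.5), not profiled.
- AR(1) whitening applies to Gaussian responses only.
- Radial bin means inherit the spatial autocorrelation of the underlying
  raster: in a single scene, correlated noise is indistinguishable from
  radial structure and the distance model will flag it. Climatological
  (multi-scene) averaging and cell-count weighting are the intended use;
  the no-effect calibration property is only guaranteed under independent
  cell noise.
- The CRW fidelity test loses power for animals that settle immediately
  (their own small steps make the null walk equally sedentary) — a
  property of the resampling null itself, visible in the power
  experiments.
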