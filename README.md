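# seamount-oasis

Statistical machinery for quantifying how seamounts aggregate pelagic life —
from plankton to sharks — built for radial ("distance-from-summit") survey
designs, acoustic telemetry arrays and satellite tracking.

Shallow seamounts act as abundance oases and activity hubs for pelagic
predators. Testing that quantitatively requires a common inferential
backbone across very different data streams: baited-video counts, visual
transects, hydroacoustic backscatter, CTD and ocean-colour fields, receiver
detection logs and animal tracks. This package implements that backbone:

- **Distance-effect models** (`distance_effects`): penalized thin-plate
  regression splines of distance from the summit,

  `g(E(yᵢ)) = β₀ + f_s(distanceᵢ) + β₁xᵢ`

  with negative-binomial, Tweedie, Gaussian, quasi-Poisson and
  quasi-binomial families, transect random intercepts, AR(1) whitening,
  tensor-product `f(distance, depth)` smooths, and AICc /
  smooth-difference structure selection.
- **Radius of influence**: `R` is the furthest distance at which the 95%
  pointwise interval on the finite-difference first derivative of the
  fitted smooth excludes zero; the **enrichment magnitude** is
  `E(y|d=0) / mean(E(y|d>R))` with a credible interval from posterior
  coefficient simulation. A baseline-crossing fallback (oceanic reference
  mean, floored at 0.05) handles near-zero-baseline count data.
- **Survey reduction** (`surveys`): MaxN, maximum combined biomass via
  weight–length relations `W = a·FLᵇ`, trophic-filtered species richness,
  5-minute visual-transect binning.
- **Hydroacoustics** (`acoustics`): dB-difference (ΔSv₁₂₀₋₃₈) fish /
  zooplankton classification with −70 / −80 dB export floors and NASC
  echo-integration (`4π·1852²·Σ10^(Sv/10)Δz`) per 500-m distance bin and
  50-m depth stratum.
- **Oceanography** (`oceanography`): deep-chlorophyll-maximum and
  mixed-layer depth extraction, the Chlorophyll Enrichment Index (percent
  deviation from a 30–90 km reference annulus, scenes >50% cloud
  rejected), 1-km radial binning, and loess-detrend + periodogram tidal
  spectra (M2 ≈ 12.4 h).
- **Residency analytics** (`residency`): two-consecutive-day track starts,
  residency indices (RI), ≥14-day residency periods, attrition curves,
  cyclic-spline diel profiles, bootstrap receiver-use summaries, exact PAM
  clustering of RIs, inter-seamount movement counts, detection-range
  (AMDR, 5% threshold) estimation and quasi-binomial RI comparisons.
- **Dispersal** (`dispersal`): correlated-random-walk null tests of site
  fidelity (10,000 walks resampling observed step lengths and turning
  angles; one-sided p), distance series, deployment-weighted utilisation
  distributions and volume contours.
- **Synthetic data** (`synthetic`): seeded generators for every input —
  overdispersed counts under compact-support enrichment kernels,
  Tweedie-like backscatter with a deep scattering layer,
  resident/transient detection histories with diel cycling, biased and
  unbiased correlated random walks, latitudinally graded chlorophyll
  scenes, CTD profiles, tidal temperature series and logistic range
  tests — each emitting its planted ground truth for recovery testing.

## Worked example

Recover a planted oasis effect from a synthetic baited-video survey:

```python
from seamount_oasis import synthetic as syn, distance_effects as de

kernel = syn.EnrichmentKernel(baseline_mean=2.0, summit_multiplier=20.0,
                              radius_true=5.0)
cfg = syn.SurveyConfig(seed=42, n_samples=400, max_distance_km=20.0)
samples = syn.gen_radial_survey(cfg, kernel, family="nb")

model = de.fit_distance_gam(samples, family="nb", k=20)
band = de.derivative_band(model)
est = de.radius_of_influence(model, band)
mag, ci = de.enrichment_magnitude(model, est.R_km, n_draws=1000, seed=0)
```

which prints

```
family: negative binomial (theta = 1.55)
effective degrees of freedom: 11.4
radius of influence: R = 5.5 km (derivative-scan)
summit prediction E(y|d=0): 34.5
baseline mean E(y|d>R):     1.79
enrichment magnitude: 19.3x (95% CI 11.3-32.8)
```

The survey was simulated with a true radius of 5 km and a 20× summit
enrichment over a baseline mean count of 2: the derivative scan places the
edge of the seamount's influence at 5.5 km, and the summit-to-baseline
ratio (19.3×, CI 11.3–32.8) brackets the planted multiplier.

A thin CLI mirrors the main analyses:

```sh
oasis distance-effect samples.csv --family nb
oasis cei scene.csv --summit -14.42,-8.77 --annulus 30,90
oasis residency detections.csv --period-min 14
oasis fidelity track.csv --summit -14.42,-8.77 --sims 10000 --seed 1
```

## Layout

```
src/seamount_oasis/
  families.py          GLM families (NB, Tweedie, quasi-likelihood)
  smoothing.py         penalized spline engine (TPRS, cyclic, tensor, REML)
  distance_effects.py  distance GAMs, derivative bands, R and magnitude
  surveys.py           MaxN / biomass / richness / visual binning
  acoustics.py         dSv classification and NASC integration
  oceanography.py      DCM, MLD, CEI, radial bins, tidal spectra
  residency.py         RI, periods, diel, receiver use, PAM, AMDR
  dispersal.py         CRW null tests, UDs, volume contours
  synthetic.py         seeded generators with planted ground truth
  cli.py               `oasis` console entry point
```

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
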