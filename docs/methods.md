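# Methods

This note documents the models and procedures implemented in `bloomflux`,
the assumptions behind them, the parameters that matter, and what the
synthetic data generator does and does not emulate.

## The analysis

The scientific question is whether weekly fluctuations of surface
chlorophyll (SChl) during the winter–spring bloom are in phase with
atmospheric modulations of upper-ocean vertical stability.  Two
atmospheric quantities serve as stability proxies: the net air–sea heat
flux NHF (sum of shortwave, longwave, latent and sensible fluxes; positive
means the ocean gains heat and stratifies) and the wind stress WS
(computed from 10 m wind components with the bulk formula
τ = ρ_air·c_d·|u|², ρ_air = 1.22 kg m⁻³, c_d = 1.3×10⁻³).  Their one-step
derivatives, and the net growth rate r = d ln(SChl)/dt, are formed between
consecutive 8-day composite steps and reported per day.  Using the log
derivative makes r invariant to any constant calibration factor in the
chlorophyll product; a derivative interval is attributed to the season of
its first step, on the reasoning that the forcing change precedes the
biological response.

Three complementary views of the coupling are computed inside the
January–April analysis window:

1. **Lag composite.**  For each pixel-year, the *last persistent*
   negative-to-positive NHF crossing (NHF ≥ 0 from that step through the
   end of the window) defines t = 0.  The growth interval at lag 0 spans
   the crossing — it ends at the first step with NHF ≥ 0 — and lags of
   ±1..3 steps (±8..24 days) shift that interval.  The convention that
   lag 0 *spans* the crossing is a documented choice; the alternative
   (the interval following the crossing) shifts the composite by one lag.
2. **Phase-binned relations.**  Each consecutive-step pair is classified
   by the NHF signs: winter-unstable (−,−), transition shutdown (−,+),
   transition resume (+,−), spring-stable (+,+).  Exactly zero NHF counts
   as "stable": shutdown means buoyancy loss has ceased.  Growth is
   bin-averaged against d(NHF)/dt (or d(WS)/dt) per phase, default nine
   equal-width bins spanning the central 98% of driver values; bins with
   fewer than 10 intervals are flagged unreliable.
3. **Sign-agreement maps.**  Per pixel and season (winter = Jan–Feb,
   spring = Mar–Apr, by window-center month), the percentage of intervals
   on which d(NHF)/dt and r share a sign.  Zero-valued derivatives or
   growth rates are sign-ambiguous and excluded from numerator and
   denominator; pixels with fewer than five valid intervals are masked.
   For the WS driver, agreement means *opposite* signs (a wind drop goes
   with growth).  The bloom region is defined by climatological spring
   SChl > 0.65 mg Chl m⁻³ (strict inequality).

## X-11 decomposition

The intraseasonal component of SChl is isolated with an additive,
two-pass Census X-11 scheme for period p = 46 steps per year:

1. initial trend T₁: centered 2×p moving average (p+1 points, end weights
   1/2p);
2. seasonal S₁: per-phase 3×3 composite filter across years (weights
   1/9, 2/9, 3/9, 2/9, 1/9), centered by subtracting its own 2×p moving
   average;
3. refined trend T₂: 23-term Henderson filter (classical closed-form
   weights; exactly reproduces cubics) applied to X − S₁;
4. second pass from T₂ with the smoother 3×5 seasonal filter (weights
   1/15, 2/15, 3/15, 3/15, 3/15, 2/15, 1/15), as in the classical X-11
   iteration; the final trend is the Henderson filter of X − S, and the
   irregular is the exact residual I = X − T − S.

At series ends and around gaps every kernel is truncated to the available
points and renormalized, so the whole decomposition is linear and the
additive reconstruction is exact everywhere.  The cost of this simple end
rule is that the usual small-sample properties (seasonal year-means ≈ 0,
idempotence of deseasonalization) hold to high precision only away from
the first/last ~3 years; the tests check them on series interiors.
The irregular component carries the sub-seasonal, non-seasonal
variability (roughly periods below six months).  An additive rather than
multiplicative decomposition is applied to SChl directly; growth rates are
handled separately in log space.  On white noise the measured variance
split is roughly 15% trend, 30% seasonal+cross-terms, 54% irregular: the
prescribed filter pair passes an irreducible share of noise into trend and
seasonal, so the irregular is the dominant but not the sole noise carrier.

## The synthetic forcing-and-bloom simulator

The generator's role is to produce datasets with the statistical structure
the analysis assumes, so the pipeline can be validated mechanistically:
a known coupling is built in, and the analysis must recover it.

### Atmospheric forcing

- Seasonal cycle: NHF_sea(doy) = A·sin(2π(doy − d₀)/365) with amplitude
  A = 200 W m⁻² and cooling-to-heating crossing d₀ = day 74 (mid-March).
- Storms: per-step Bernoulli events with a winter-peaked probability
  envelope ((1+cos)/2)⁵ between 0.25 (mid-January peak) and a 0.05 summer
  floor.  Each storm occupies exactly one 8-day step; its stress anomaly
  is lognormal with mean 0.15 N m⁻² and shape σ = 1.2, and it depresses
  NHF by γ = 800 W m⁻² per N m⁻² — storms raise WS and cut NHF together.
- Synoptic noise: Gaussian NHF noise with a winter-peaked standard
  deviation (80 W m⁻² at the storm peak, envelope variance floor 0.1 in
  summer), representing weekly latent/sensible-flux variability beyond
  discrete storms.  Half of its variance is mirrored into WS through the
  same γ coupling, so weekly NHF and WS changes are anticorrelated both
  through storms and through synoptic weather (simulated correlation of
  one-step changes ≈ −0.87).  In late winter this noise makes NHF
  oscillate across zero before the final seasonal transition — brief
  shutdown/resume events with SChl responses, the phenomenology the
  analysis is designed to detect.

### Slab mixed layer

The ocean response is a slab of depth h with surface chlorophyll P.

Under cooling (NHF < 0), h relaxes (time scale τ_mix = 25 d) toward a
forced equilibrium depth h_eq = h_conv + γ_h·|NHF|, with a convective
floor h_conv = 120 m and slope γ_h = 0.3 m per W m⁻², capped at
h_max = 500 m; deepening is additionally rate-limited by the buoyancy-work
coefficient c_e = 0.02 m per (W m⁻²·day).  The equilibrium-depth form
encodes convection competing with background (eddy-driven)
restratification: storms deepen the layer, calm cooling spells let it
shoal.  Deepening entrains deep water with chlorophyll P_d = 0.05
mg Chl m⁻³, conserving the column inventory exactly
(P'h_new = P·h_old + P_d(h_new − h_old)) — the dilution mechanism;
shoaling detrains and leaves P unchanged.

Under heating (NHF ≥ 0), h relaxes toward h_min = 15 m with an e-folding
time τ_r·NHF_ref/NHF (τ_r = 10 d at NHF_ref = 25 W m⁻²): stronger heating
restratifies faster.  This makes the SChl response roughly proportional
to the NHF change — weak positive excursions shoal the layer only
partially — while the sustained seasonal transition collapses it within
one step, producing the sharp growth peak at t = 0.

The biological update is P ← max(P_floor, P·exp((μ − m)Δt)) with Δt = 8 d,

- growth μ = μ_max·Ī/(K_I + Ī), μ_max = 0.8 d⁻¹, K_I = 30 W m⁻², where
  Ī = I₀(doy)·(1 − e^{−k_w h})/(k_w h) is the depth-averaged irradiance
  (attenuation k_w = 0.08 m⁻¹);
- losses m = m₀ + m_g·P/(P + K_P), background m₀ = 0.02 d⁻¹, grazing
  m_g = 1.0 d⁻¹ saturating at K_P = 1.5 mg Chl m⁻³.

The effective surface irradiance is an annual harmonic (mean 140,
amplitude 30 W m⁻², solstice minimum) plus a semiannual term (36 W m⁻²,
late-winter minimum) representing the region's late-winter cloudiness.
The harmonic amplitudes were calibrated, before the test suite was
frozen, so that the simulated January–February chlorophyll climatology is
flat: the observed winter plateau implies near-neutral winter balance
between light-limited growth, losses and dilution, and an unbalanced
winter would imprint a spurious drift on the near-zero-forcing growth
statistics.  With these choices the winter balance sits at SChl ≈ 0.3
(above P_d, so dilution lowers surface chlorophyll as the mechanism
requires), the spring bloom equilibrates at 2–3 mg Chl m⁻³ under grazing
control, and the mature bloom decays after its peak through the grazing
term rather than nutrient exhaustion — there are no nutrients in the
model, a deliberate simplification: the January–April mechanism under
study is light and dilution.

### Observation layer

Per pixel, the slab solution is multiplied by (i) a spring-peaked
multiplicative AR(1) log-anomaly (sd 0.9 at its day-105 peak, gaussian
envelope of width 30 d, persistence 0.6 per step) representing
(sub-)mesoscale eddy variability and patchiness — strongest around the
bloom apex, when restratification eddies and biomass gradients peak, and
the main reason real pixels decorrelate from the local forcing in spring —
and (ii) independent lognormal observation noise (sd 0.05).  A per-pixel
μ_max scaling field (default a linear 0.5–1.2 gradient across the grid)
emulates the cross-shore productivity gradient and makes the bloom mask a
proper subset of the domain.  All pixels share one forcing realisation
and one mixed-layer history.  A one-year spin-up on the first year's
forcing removes the initial transient.  All random draws derive from a
single seeded generator, so identical seeds give bit-identical datasets.

### What the generator does and does not emulate

It reproduces: the seasonal NHF cycle and its early-spring sign change;
one-step storms anticorrelated between NHF and WS; winter mini-blooms and
dilution events in phase with stability changes; a sharp growth peak at
the persistent crossing with near-zero growth at other lags; growth
roughly proportional to d(NHF)/dt during transitions; winter sign
agreement (~67%) exceeding spring (~62%); and large spring intraseasonal
SChl variance.  It does not emulate: nutrient drawdown and summer
oligotrophy (the modelled summer holds a grazing-capped plateau rather
than collapsing, so the deterministic annual maximum falls in early
summer, not April); advection or coherent spatial structure (pixels
differ only by productivity scaling and noise); in-water heating
feedbacks; or retrieval gaps.  Passing tests therefore demonstrate that
the pipeline recovers a known forcing–response coupling under realistic
noise, not that the slab model is an adequate ocean model.

## Numerical choices and degenerate inputs

- 8-day windows are anchored to January 1 (46 per year, the last window
  5–6 days); a window's month, season and day-of-year come from its
  center date.
- Temporal aggregation masks windows with fewer than 4 valid daily values
  (or any missing value when the source has coarser-than-daily sampling);
  spatial regridding is bilinear with conservative mask propagation (any
  masked stencil corner masks the output) and nearest-edge clamping.
- Zero NHF counts as stable/positive everywhere (a measure-zero case in
  practice).
- Years in which NHF never goes negative inside the window contribute no
  composite events; this is logged, not an error.
- Composite lags that fall outside the data or the event's Jan–Apr window
  are recorded as missing and excluded from that lag's count.
- The growth rate rejects non-positive chlorophyll at unmasked steps with
  the offending step index; masked steps propagate NaN intervals.
- Pipeline outputs are never overwritten: existing artifact names get a
  versioned suffix.  The manifest stores a SHA-256 checksum per artifact;
  end-to-end determinism is checksum equality.

## Problem sizes

The reference analyses use 50 simulated years at one pixel for event
statistics (2 300 steps, ~50 composite events) and an 8×8 pixel grid for
the maps; both run in seconds.  These sizes put the standard errors of
the composite and binned statistics well below the effects being tested
while keeping the whole suite fast.

## Known limitations

- The slab closure (equilibrium mixing depth linear in |NHF|) is one
  plausible parameterisation of a link that is not quantitatively
  constrained; conclusions about the *pipeline* are insensitive to it,
  conclusions about the *ocean* should not be drawn from it.
- The X-11 end rule (truncated renormalized kernels) trades the standard
  asymmetric end weights for linearity and testability; the first and
  last ~2–3 years of the irregular component are less reliable.
- Percentages in sign-agreement maps exclude exactly-zero derivatives;
  with real data containing ties the denominator definition matters.
- No significance testing of composite differences is performed.
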