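# bloomflux

Weekly fluctuations in satellite surface chlorophyll (SChl) during the
winter–spring bloom of deep-convection regions are strongly tied to the
atmosphere: storms deepen the mixed layer, diluting surface biomass and
cutting light exposure, while calm spells and the seasonal switch of the net
air–sea heat flux (NHF) from cooling to heating restratify the column and
let biomass accumulate.  `bloomflux` is a tested pipeline for quantifying
this coupling at 8-day resolution, together with a stochastic
forcing-and-bloom simulator that stands in for the satellite ocean-colour
and atmospheric-reanalysis products, so every step of the analysis can be
exercised and validated end to end without external downloads.

It is aimed at biological oceanographers and anyone studying bloom
phenology, convection-shutdown bloom onset, or subseasonal air–sea
coupling in gridded time series.

## What it computes

For co-registered 8-day series of SChl (mg Chl m⁻³), NHF (W m⁻², positive
= ocean heat gain) and wind stress WS (N m⁻²), per 0.125° pixel:

- **Net growth rate** `r_t = d ln(SChl)/dt`, and one-step forcing
  derivatives `d(NHF)/dt`, `d(WS)/dt` (all per day, between consecutive
  8-day steps).
- **Census X-11 decomposition** of SChl into trend + seasonal + irregular
  (intraseasonal) components with exact additive reconstruction, and maps
  of normalized intraseasonal variability.
- **NHF-sign phases** of each consecutive-step pair inside the
  January–April window: winter-unstable (−,−), transition shutdown (−,+) /
  resume (+,−), spring-stable (+,+); **zero-crossing events** with a
  persistence flag, and the **lag composite** of `r` about the last
  persistent cooling-to-heating crossing (t = 0, lags ±24 d).
- **Bin-averaged growth–forcing relations** per phase, and per-pixel
  **sign-agreement maps**: the percentage of in-season intervals on which
  `d(NHF)/dt` and `r` share a sign.
- The **bloom-region mask**: pixels whose climatological spring (Mar–Apr)
  SChl exceeds 0.65 mg Chl m⁻³.

The simulator couples a seasonal NHF cycle, one-step storm events
anticorrelated between NHF and WS, synoptic flux noise, and a slab mixed
layer with light-limited growth, grazing losses, entrainment dilution and
heating-driven restratification.  See `docs/methods.md` for the model, its
assumptions and every parameter.

## Worked example

```python
from bloomflux import SimConfig, simulate_dataset, derive_series
from bloomflux.events import (find_zero_crossings, last_persistent_crossing,
                              composite_about_crossing, aggregate_composite)
import numpy as np

cfg = SimConfig(seed=1, n_years=50)          # one pixel, 50 years
bundle = simulate_dataset(cfg)
axis = bundle.axis
schl = bundle.schl.values[:, 0, 0]
nhf = bundle.nhf.values[:, 0, 0]
ws = bundle.ws.values[:, 0, 0]

d = derive_series(schl, nhf, ws, axis)
print(round(float(np.corrcoef(d.dnhf, d.dws)[0, 1]), 3))   # -0.874

events = find_zero_crossings(nhf, axis)
contribs = []
for year in np.unique(axis.years):
    ev = last_persistent_crossing([e for e in events if e.year == year])
    if ev is not None:
        contribs.append(composite_about_crossing(d.growth, ev, axis))
comp = aggregate_composite(contribs)
for lag, mean in zip(comp.lags_days, comp.mean):
    print(f"lag {lag:+.0f} d: mean growth {mean:+.3f} /day")
```

which prints

```
-0.874
lag -24 d: mean growth +0.000 /day
lag -16 d: mean growth +0.017 /day
lag -8 d: mean growth -0.038 /day
lag +0 d: mean growth +0.151 /day
lag +8 d: mean growth -0.019 /day
lag +16 d: mean growth +0.052 /day
lag +24 d: mean growth -0.031 /day
```

Weekly NHF and WS changes are strongly anticorrelated (−0.87), and the mean
net growth rate peaks sharply (+0.15 day⁻¹) on the interval spanning the
last persistent cooling-to-heating crossing — the convection-shutdown
signature — while it is near zero at every other lag.

The same analysis runs from the shell:

```sh
bloomflux all --config examples/synthetic.toml --out run1
```

writing the forcing bundle, decomposition, derived series, composite and
binned tables, agreement maps, bloom mask and a checksummed `manifest.json`
(identical seeds give identical checksums).

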