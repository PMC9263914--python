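# isopart

Partitioning plant root water uptake among soil layers from stable water
isotopes (δ¹⁸O, δD).

## The problem

Where in the soil profile does a crop take its water? Because water moves
from soil into roots without isotopic fractionation, the δ¹⁸O and δD of stem
water are a mass-balance mixture of the soil waters the roots tapped. With
the soil profile divided into N layers,

    δD_stem   = Σᵢ fᵢ · δDᵢ
    δ¹⁸O_stem = Σᵢ fᵢ · δ¹⁸Oᵢ ,     Σᵢ fᵢ = 1,  fᵢ ≥ 0,

where fᵢ is the fraction of transpiration drawn from layer i. With four
layers and two isotopes the system is under-determined, so `isopart` infers
the fractions in a Bayesian way: a symmetric Dirichlet prior on the simplex
times a Gaussian likelihood for the measured stem isotopes (measurement
variance optionally inflated by the within-layer source spread,
σ_t² = σ_meas,t² + Σᵢ fᵢ²·sd_{t,i}²), sampled by random-walk Metropolis in
log-ratio coordinates, with R̂/ESS convergence diagnostics.

Around that core, the package provides the rest of the inference chain such
a study needs:

- **δ-notation utilities and meteoric water lines** — δ = (R_s/R_ref − 1)·10³
  (‰ VSMOW), OLS fits of δD on δ¹⁸O for local meteoric water lines, and soil
  water grouping by a δ¹⁸O threshold;
- **the intersection method** — uptake depth as the crossing of the stem
  isotope value with the piecewise-linear soil isotope–depth profile;
- **the saturating uptake–root-length-density model** — y = kS/(A+S) fitted
  by nonlinear least squares, with RLD profile normalization;
- **FAO-56 Penman–Monteith reference evapotranspiration** from daily weather;
- **a seeded synthetic-data generator** that emulates a full field campaign
  (depth-declining soil δ¹⁸O with evaporative surface enrichment, stem water
  as a known convex mixture of layers, precipitation scattered about a local
  meteoric water line, exponential RLD profiles, daily weather) so that
  every stage can be validated against known ground truth.

It is aimed at ecophysiologists and isotope hydrologists who want a tested,
scriptable version of this workflow rather than a GUI or a black box.

## Worked example

```python
import numpy as np
from isopart import (SyntheticConfig, generate_dataset, MCMCConfig,
                     IsotopeMixingModel)
from isopart.pipeline import lmwl_from_precipitation, uptake_depths_all_groups

cfg = SyntheticConfig(seed=1, n_dates=2, treatments=("P1-N120", "P2-N240"))
ds = generate_dataset(cfg, "demo")

line, n = lmwl_from_precipitation(ds.water_samples)
print(f"LMWL: dD = {line.slope:.4f} d18O + {line.intercept:.4f}"
      f"  (R2 = {line.r_squared:.3f}, n = {n})")

soils = [s for s in ds.water_samples if s.kind.value == "soil"
         and s.date.isoformat() == "2016-06-24" and s.treatment == "P1-N120"]
stem = next(s for s in ds.water_samples if s.kind.value == "stem"
            and s.date.isoformat() == "2016-06-24" and s.treatment == "P1-N120")
res = IsotopeMixingModel.from_samples(stem, soils).fit(MCMCConfig(seed=1))
print(res.summary().round(3).to_string(index=False))
```

prints

```
LMWL: dD = 7.1982 d18O + 5.1919  (R2 = 0.945, n = 15)
   layer  mean  lo95  hi95  rhat      ess
   0-5cm 0.335 0.041 0.563 1.001 1336.624
  5-20cm 0.222 0.007 0.668 1.002 1442.311
 20-60cm 0.277 0.012 0.633 1.001  992.033
60-100cm 0.166 0.009 0.363 1.001  720.526
```

The meteoric-line fit is made on the 15 synthetic rain events larger than
5 mm (small events are dropped, as they are unsampleable and strongly
fractionated in the field). The mixing-model table gives, per soil layer,
the posterior mean uptake fraction, its 95 % credible interval and the
convergence diagnostics; here the plant draws about a third of its water
from the top 5 cm. Under measurement noise (±0.1 ‰ δ¹⁸O, ±1.4 ‰ δD) the
posterior mean is a shrinkage estimate — the generating truth for this group
was (0.151, 0.383, 0.361, 0.105) — which is why the credible intervals are
wide; noiseless data recover configured fractions to within a few percent
(see `tests/test_acceptance.py`).

The intersection method and the saturating uptake fit run the same way:

```python
print(uptake_depths_all_groups(ds.water_samples).to_string(index=False))
#       date treatment isotope  n_crossings  depth_cm flags
# 2016-06-24   P1-N120    d18O            1 17.680045
# ...
from isopart import fit_saturating
fit = fit_saturating(ds.uptake_points)
print(f"k = {fit.k:.2f}, A = {fit.A:.2f}")   # k = 241.70, A = 228.80
```

A command-line interface mirrors these stages
(`isopart generate | lmwl | mix | depth | fit-uptake | et0`); see
`isopart --help`.

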