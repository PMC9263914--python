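# Methods

This note documents the models implemented in `isopart`, their assumptions,
the numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate about real field data.

## δ-notation and meteoric water lines

Isotope abundances are carried as per-mil δ values relative to VSMOW,
δ = (R_sample/R_reference − 1)·10³; raw ratios appear only at the conversion
boundary (`delta_from_ratio` / `delta_to_ratio`), which avoids 10⁻³-scale
bugs. Values outside [−100, +50] ‰ (δ¹⁸O) or [−500, +100] ‰ (δD) are
rejected as physically implausible for natural waters.

Meteoric water lines are ordinary least squares of δD on δ¹⁸O — the y-on-x
form in which such lines are conventionally reported — not orthogonal or
Deming regression. Soil-water grouping by a δ¹⁸O threshold (default −10 ‰)
uses a strict inequality for the "above" group; a sample exactly on the
threshold goes below. Both choices are configurable.

## The Bayesian mixing model

**Model.** Stem water is a convex mixture of N soil-layer sources:
y_t(f) = Σᵢ fᵢ·μ_{t,i} for isotope t ∈ {δ¹⁸O, δD}, with f on the simplex.
The measured stem isotopes are modelled as independent Gaussians around
y_t(f). The likelihood is the standard Gaussian log-density; the per-isotope
variance is either

- `measurement_only`: σ_t² = σ_meas,t² (defaults ±0.1 ‰ δ¹⁸O, ±1.4 ‰ δD, the
  analyser precisions), or
- `siar_propagated` (default): σ_t² = σ_meas,t² + Σᵢ fᵢ²·sd_{t,i}², which
  propagates the within-layer spread of the source waters into the mixture,
  as the SIAR family of mixing models does.

The prior is symmetric Dirichlet(α = 1), i.e. uniform on the simplex.

**Sources.** Layer sources are the mean and sample sd of the soil samples
falling in each layer. Depth membership is lower-open, upper-closed
(top, bottom], with the first layer including its own top: a core taken at
exactly 20 cm caps the 5–20 cm layer. This convention maps the campaign
depths 5, 10, 20, 40, 60, 80, 100 cm onto the default four-layer scheme
0–5 / 5–20 / 20–60 / 60–100 cm with no empty layer. A gapped variant of the scheme (0–5, 5–20, 20–60, 80–100 cm, leaving
60–80 cm unmonitored) is available as `GAPPED_LAYER_BOUNDS`.

**Sampler.** Random-walk Metropolis in additive-log-ratio coordinates
(f = softmax(z, 0), z ∈ ℝ^{N−1}), which is unconstrained so no projection or
rejection at the simplex boundary is needed. The softmax map's Jacobian
determinant ∏ᵢ fᵢ is included in the target, so with α = 1 the z-space
density is L(f|Y)·∏fᵢ. All chains advance in lockstep as vectorised numpy
operations. The per-chain step size starts at 0.5 and is rescaled every 50
burn-in iterations by exp(rate − 0.3), steering acceptance into the 20–50 %
band, then frozen so the post-burn-in chain is a valid Metropolis sampler.
Defaults: 4 chains × 20 000 iterations, 5 000 burn-in, thinning 5 (12 000
retained draws). R̂ and bulk ESS are computed per component with arviz; any
R̂ > 1.1 attaches a convergence warning to the results (non-fatal).
Determinism: one `numpy` Generator seeded from `MCMCConfig.seed` drives
initialisation, proposals and acceptances, so identical inputs and seed give
identical draws.

**Identifiability.** With four layers and two isotopes the likelihood
constrains at most two directions of the 3-simplex, so the posterior
concentrates on a solution manifold, not a point; the posterior mean is a
shrinkage estimate pulled toward the prior centroid. Recovery of a known
truth to within ~0.1 is therefore only expected when the sources are well
separated in both isotopes and the truth is compatible with that geometry —
which is exactly the regime the validation scenarios use. Per-group fits are
independent (no hierarchy across dates or treatments).

## The intersection method

The soil isotope–depth profile is interpolated piecewise-linearly between
measured depths; with only ~7 sampling depths, splines would invent extrema
and hence spurious crossings. Crossings of the stem value are enumerated
per segment: strict sign changes are inverted analytically; a node the
profile merely touches counts as one crossing (matching a graphical
reading); a segment lying entirely on the stem value reports its midpoint
with a `flat_segment` flag. No extrapolation beyond the sampled depth range.
Two ambiguity policies: `strict` errors unless exactly one crossing exists
(reporting all crossings), `shallowest` returns the first with a flag.
δ¹⁸O is the default isotope; δD is available by flag.

## Saturating uptake vs. root-length density

Root length per 10-cm bin is normalized by the profile total (absolute RLD
uses the 375.0 cm³ core volume). Uptake rate vs. normalized RLD is fitted to
y = kS/(A+S) by Levenberg–Marquardt-style nonlinear least squares
(`scipy.optimize.curve_fit`, positivity bounds), initialised from the
double-reciprocal linearisation 1/y = (A/k)(1/S) + 1/k on points with
S, y > 0, with a fallback guess (k₀ = 2·max y, A₀ = median S) when the
linearisation is unusable. The half-saturation constant A is only well
determined when the data cover the curved region S ≲ 2A as well as the
asymptote; the noise-recovery test uses such a design (40 points on
S ∈ [10, 400] plus 20 on [500, 5000], σ = 5 % of k). The pooling join
between mixing-model layer fractions and layer-aggregated normalized RLD
matches RLD bins to layers by bin midpoint; both axes are scaled ×1000 by
default (per-mil-style normalization), which is where saturating parameters
of magnitude ~200 live — the fit itself is scale-agnostic.

## Reference evapotranspiration

The FAO-56 Penman–Monteith form
ET0 = [0.408Δ(Rn−G) + γ(900/(T+273))u₂(es−ea)] / [Δ + γ(1+0.34u₂)],
with the standard auxiliary formulas for Δ(T), es(T), ea from relative
humidity, and γ from barometric pressure at the station altitude (default
81 m). Negative computed ET0 (possible with strongly negative Rn−G) is
clamped to zero with a warning. Rn is taken as an input, not derived from
sunshine hours.

## Synthetic data generator

The generator emulates a two-factor field campaign (default six dates × six
treatments) with known ground truth:

- **Soil profiles:** δ¹⁸O(d) = δ₀ + g·d + E·exp(−d/ℓ) with surface value
  δ₀ = −6 ‰, gradient g = −0.05 ‰ cm⁻¹, surface evaporative enrichment
  E = 3 ‰ decaying with ℓ = 7 cm (negligible below ~20 cm), plus Gaussian
  jitter (0.3 ‰). The profile is strictly decreasing with depth, so exactly
  one intersection-method crossing exists.
- **Soil δD:** an evaporation-displaced line δD = 5.5·δ¹⁸O − 8 (slope below
  the meteoric line, as for evaporated soil water), plus a deuterium-excess
  term +5‰·(1 − e^{−d/30 cm}): surface evaporation strips d-excess, deep
  water retains it. This gives δD depth information independent of δ¹⁸O,
  without which the two "isotope equations" would be collinear and the
  mixing problem maximally degenerate.
- **Stem water:** the configured (or Dirichlet-drawn) true fractions applied
  to the layer means, plus measurement noise 0.1/1.4 ‰.
- **Precipitation:** 15 events with amounts uniform on [1, 60] mm —
  deliberately straddling the 5 mm filter — δ¹⁸O uniform on [−9.4, −3.2] ‰
  and δD on the configured meteoric line (default slope 6.7935, intercept
  2.0593) with 3 ‰ scatter.
- **RLD:** bin weights ∝ exp(−0.03·depth_mid) with lognormal jitter
  (CV 10 %); uptake points from y = kS/(A+S) with k = 234.24, A = 207.72 on
  S ∈ [1, 1000], noise σ = 5 % of k.
- **Weather:** 100 days with T ∈ [20, 32] °C, Rn ∈ [10, 18] MJ m⁻² d⁻¹,
  u₂ ∈ [0.3, 3] m s⁻¹, RH ∈ [40, 90] % (so ea ≤ es always holds).

All randomness derives from one seed through named `SeedSequence` substreams
(soil, stem, rld, precip, weather, fractions), so changing, say, the number
of rain events cannot perturb the soil profiles. `noiseless()` silences
every noise source for exact round-trip checks.

**What passing tests show — and don't.** The synthetic data share the real
data's structure (depth-declining profiles, mixture-generated stem water,
line-scattered precipitation) but not its failure modes: no isotope
fractionation during sampling or extraction, no within-plot spatial
heterogeneity beyond iid jitter, no temporal autocorrelation of weather, no
correlation between rain amount and isotope content, and layer sources that
truly are Gaussian. Recovery on synthetic data validates the inference
machinery, not the field applicability of the mixing assumptions.

## Numerical choices and edge cases

- Fractions are validated to the simplex within 10⁻⁹ at API boundaries;
  retained MCMC draws are renormalized to sum to 1 within 10⁻¹².
- Exactly collinear regression inputs give R² clipped into [0, 1].
- `build_sources` fails loudly, naming the layer, when a layer receives no
  sample; sd is 0 for single-sample layers.
- Posterior summaries use empirical quantiles (numpy linear interpolation).
- Test problem sizes: unit tests run 4 × 6 000-iteration chains; acceptance
  checks use the default 4 × 20 000 configuration, 20 replicates for the
  recovery study, and a 0.005-step grid (~20 000 nodes) for the 2-simplex
  oracle.

## Known limitations

- One stem observation (or the group mean) per fit; replicate stems are
  averaged rather than modelled hierarchically.
- No concentration dependence or trophic discrimination offsets; sources
  enter as plain Gaussians.
- The intersection method reports depths only where the profile is sampled;
  real profiles with non-monotone structure can legitimately yield several
  crossings, which the strict policy surfaces as an error by design.
- Craig–Gordon evaporation-line modelling is out of scope; evaporative
  enrichment is emulated phenomenologically in the generator only.
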