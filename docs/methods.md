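# Methods

## The model in brief

`divempa` couples three components on an abstract lattice of ~50 km × 50 km
ocean pixels (great-circle centroid distances, areas carried as data, no CRS
machinery):

1. **Metapopulation biomass.** Each commercially fished stock carries an
   intrinsic growth rate `r`, a total carrying capacity `K` spread
   homogeneously over a contiguous geographic range, and dispersal structure
   derived from two traits: home range (km²) and pelagic larval duration
   (PLD, days). Protected pixels follow the synchronous update

   `B_i(t+1) = Σ_j s_{j→i} B_j(t) + (Σ_j ρ_{j→i}) · r · B_i(t) (1 − B_i(t)/K_i)`

   while fished pixels are pinned at their business-as-usual (BAU) density
   `depletion × K_i` — the assumption that fishers capture all adult spillover
   and larval subsidy, so biomass builds up only inside MPAs. The growth term
   is implemented exactly in the printed form of the source model: the
   immigrant-settlement weights `ρ_{j→i}` multiply production evaluated at the
   *destination* pixel, i.e. a settlement-weighted local production
   `(Σ_j ρ_{j→i}) r B_i (1 − B_i/K_i)`. We deliberately do not "correct" this
   to source-pixel production; the asymmetry is noted here rather than
   silently altered.

2. **Biodiversity persistence.** The biodiversity score is
   `Σ_s w_s (1 − q_s (1 − p_s) − u_s)^z` over scored species, where `p_s` is
   the fraction of the species' range in fully/highly protected pixels, `q_s`
   the abatable (fishing) impact share, `u_s` an optional unabatable share
   (default 0), and `z = 0.25` a concavity exponent. The power-law form is a
   documented reconstruction: the persistence curves of the upstream
   conservation-planning method are not reproduced in the text we build from,
   so the function and `z` are pluggable (`persistence_fn` argument). Weights
   are uniform within taxa and aggregate to the printed taxon table
   (Elasmobranchii 0.340, Actinopterygii 0.273, Anthozoa 0.165, birds 0.052,
   mammals 0.050, Malacostraca 0.038, cephalopods 0.021, other 0.061).

3. **Dive-market economics.** Linear demand per pixel anchored at the observed
   equilibrium and a global choke price (99th-percentile observed price,
   nearest-rank). Protection shifts willingness to pay by
   `ΣWTP = P*(0.04·1{MPA} + f_bio(ΔB) + f_div(ΔS))`; fees move along the
   shifted curve. ΔCS is evaluated in the cancellation-free form
   `0.5 (C−P*) ΔQ (2Q*+ΔQ)/Q*` so a neutral fee gives exactly zero. Producer
   surplus is identically zero (horizontal supply) and is not modelled.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| pixel area | 2500 | km² | nominal 50 km pixels; exposed as data |
| protection threshold | 0.5 | fraction | pixel is fully/highly iff ≥ 50% covered |
| choke percentile | 99 | — | empirical choke-price rule |
| MPA name effect | 0.04 | share of P* | WTP premium for the MPA label |
| biomass WTP cap / half-sat | 0.84 / 1.1 | share of P* / fractional gain | saturating response |
| biodiversity WTP cap / half-sat | 0.82 / 0.026 | share of P* / score gain | saturating response |
| persistence exponent z | 0.25 | — | concave gains; config-exposed |
| equilibration | 100 | iterations | fixed-horizon equilibrium; optional tolerance stop (off) |
| casual diver share | 0.7278 | — | solves 9M divers × (4, 10 dives/yr) → 50.7M dives |
| marine fraction | 0.653 | — | share of dives in the marine environment |
| random forest | 500 trees | — | default split rules, seeded; only the model family is prescribed |

The WTP half-saturation constants are the genuinely open part of the demand
parameterization (the underlying synthesis curves live in supplementary
material we do not consume). They are fixed once so that at the central
modelled effects — a 113% biomass gain and a 0.03 biodiversity-score gain —
the three components split ≈47/49/4 and total ≈US$53 at the US$58.75 median
price, matching the published attribution of the analysis this package
re-implements. They are configuration, not fitted quantities.

## Protection-status rules

A pixel is `fully_highly` iff its summed fully/highly coverage fraction
reaches the 0.5 threshold; otherwise the highest-ranked *non-fully*
designation with positive coverage wins (rank: fully_highly > less_unknown >
designated_unimplemented > proposed_committed > unprotected), else
`unprotected`. Sub-threshold fully/highly coverage alone confers no status.
At the site level, overlapping designations resolve to the highest protection
class, ties to the oldest designation year.

## Dispersal discretization

Adult movement: uniform redistribution over range pixels within the radius
`ζ = √(HR/π)` km (always including the source; a distance-weighted variant is
a natural hook but the uniform rule is the default since only the radius
constraint is prescribed). Rows are nudged on their last nonzero entry so they
sum to exactly 1 in floating point.

Larvae: the isotropic Gaussian kernel `exp(−d²/2σ²)/(2πσ²)` with
`σ = 1.33 √(π/2) PLD^1.3` is evaluated at centroid distances and multiplied by
destination area. At 50 km pixels this badly under-resolves small σ (the
self-settlement entry can exceed 1), so rows are renormalized to sum to 1 by
default, preserving each source's larval output within the range;
renormalization is config-switchable because the original discretization
choice is unstated. Drift is neglected (symmetric spread). Elasmobranchs have
no pelagic stage: their PLD is removed and settlement is natal-pixel-only —
our documented choice for a case the source leaves open.

Stocks that end up with neither an empirical nor a predictable trait are
dropped with a logged warning, mirroring the "complete biological parameters"
retention rule of the original stock database.

## Synthetic worlds: what they emulate and what they don't

`synth` generates, from one master seed (per-generator streams at fixed spawn
keys 0/1/2):

* a land/ocean mask by thresholding a smoothed Gaussian field (ocean fraction
  0.66), with dive pixels (1.2% of ocean, the published areal share) sampled
  near the coast with a clustered weighting;
* MPA coverage hitting the published dive-site targets — 67.35% of dive
  pixels in MPAs, 15.48% fully/highly — plus background ocean MPAs;
* heavy-tailed (lognormal, log-sd 1.5) annual dive counts, integerized by
  largest-remainder so they sum exactly to the configured total, default
  33.1e6 × (dive pixels / 1816), preserving the real per-pixel dive intensity;
  every dive pixel gets at least one dive;
* price observations with an exact lognormal quantile profile (median
  US$58.75, log-sd 0.5) randomly assigned to operators, so the sample median
  and the 99th-percentile choke price are stable across seeds;
* stocks with lognormal r, K, length, uniform trophic level, ordered movement
  keyword, 10% elasmobranchs, contiguous 4-connected ranges seeded at dive
  pixels, BAU depletion `B/K ~ U(0.1, 0.9)`, and **log-linear trait ground
  truth**: `log(trait) = β₀ + βᵀ(features) (+ noise on "empirical" labels)`,
  giving the trait imputer a recoverable target;
* species allocated to taxa in proportion to the aggregate weight table, with
  blob ranges and abatable impact `q ~ U(0.3, 1)`.

Not emulated: realistic coastlines or bathymetry, depth limits, ocean-current
anisotropy, spatially varying K within ranges, per-species threat covariates,
cross-site substitution in demand. Passing tests therefore demonstrate the
*method* — equilibrium logic, dispersal contracts, score properties, demand
identities, fee optimization — not a calibration to any real seascape; the
absolute biomass/score levels of synthetic worlds are not calibrated to the
published global values, and BAU depletion is a synthetic stand-in for the
externally derived stock states of the real analysis.

## Numerical choices

* Synchronous updates; equilibria after a fixed 100 iterations (the final-step
  max change is reported as a diagnostic; on default worlds it is ≪ 1e-6·K).
* Biomass clamped at ≥ 0; fished densities are written back verbatim, so they
  are bit-identical before and after equilibration.
* Dive-number clamp at zero when a fee exceeds the choke margin, with a
  logged warning.
* Movement rows sum to exactly 1; larval rows to 1 ± 1e-9 after
  renormalization; carrying capacity vectors sum exactly to K (last-element
  pinning).
* The biodiversity score is clipped to [0, 1] against few-ulp weight-sum
  drift.
* Monte-Carlo dive totals rescale all pixel dive counts proportionally (the
  reallocation rule is unstated in the source; proportional scaling keeps the
  spatial pattern fixed).
* Problem sizes: the default world is 40×40 with 50 stocks and 200 species;
  scenario-level tests use 20×20–24×24 worlds with 4–8 all-empirical stocks.
  These sizes were chosen so the full pipeline and its tests run comfortably
  on a single CPU while leaving every mechanism exercised.

## Known limitations

* The per-pixel WTP biodiversity input is the *global* score gain (the score
  is a global quantity; no per-pixel biodiversity change is defined), so
  biodiversity-driven demand shifts are spatially uniform.
* The persistence functional form and the WTP response curves are
  reconstructions (see above); absolute levels depend on them even though the
  qualitative orderings (monotonicity, caps, dominance results) do not.
* Single-species logistic dynamics: no age structure, species interactions, or
  fishing-effort reallocation.
* The `$0–$neutral-fee` window in which fees raise revenue while still
  increasing surplus can be read per-pixel or globally; both are computable
  (per-pixel neutral fees and their dive-weighted mean are reported).
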