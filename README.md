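# divempa

Coupled ecological–economic simulation of what happens when all recreational
dive sites are placed in fully/highly protected marine protected areas (MPAs):
a gridded metapopulation biomass model with adult-movement and larval
dispersal, a weighted biodiversity-persistence score, and a linear-demand
dive-tourism market with willingness-to-pay (WTP) demand shifts and per-dive
user-fee optimization.

The package is aimed at marine-conservation and resource economists who want
to explore the protection–tourism feedback: protection raises fish biomass and
biodiversity inside MPAs, divers are willing to pay more for better diving (and
for the "MPA" label itself), demand for dives rises, and a well-chosen dive fee
can capture part of that surplus to fund management. Because the real analysis
is built on global dive-site, price, MPA-boundary and stock databases, the
package ships a first-class synthetic-data generator that reproduces the
*statistical structure* of those inputs (clustered coastal dive pixels,
heavy-tailed dive counts, lognormal prices with a US$58.75 median, MPA coverage
targets of 67.35% / 15.48%, stocks with log-linear trait ground truth), so the
whole method is testable end to end from a seed.

## Model

**Demand.** Each ~50 km dive pixel *i* has linear demand
`Q_d = a − b P`, anchored at the observed equilibrium `(Q*_i, P*_i)` and the
choke price `C_i` (99th percentile of observed prices), so `b = Q*/(C − P*)`.
Protection shifts WTP by `ΣWTP = P*·(name + f_bio(ΔB) + f_div(ΔS))` — a 4%
MPA name effect plus saturating responses to the modelled biomass gain ΔB and
biodiversity-score gain ΔS, capped at 84% and 82% of the price. With a per-dive
fee F:

```
ΔQ      = Q* (ΣWTP − F) / (C − P*)
ΔRev    = P* ΔQ
FeeRev  = F (Q* + ΔQ)
ΔCS     = 0.5 (Q*+ΔQ)² (C−P*)/Q* − 0.5 Q* (C−P*)
```

The fee `F = ΣWTP` is *neutral*: dives, industry revenue and consumer surplus
are unchanged while `ΣWTP · Q*` is collected.

**Biology.** Stock *x* in protected pixel *i* follows

```
B_{x,i,t+1} = Σ_j s_{x,j→i} B_{x,j,t} + (Σ_j ρ_{x,j→i}) r_x B_{x,i,t} (1 − B_{x,i,t}/K_{x,i})
```

with uniform adult redistribution within the home-range radius
`ζ = √(HR/π)`, a Gaussian larval kernel whose spread is
`σ = 1.33 √(π/2) PLD^1.3`, carrying capacity spread homogeneously over the
stock range, and fished pixels pinned at their business-as-usual density
(fishers capture all spillover). Home range and pelagic larval duration are
imputed with a random-forest regressor where no empirical value exists;
elasmobranchs have no larval stage and settle natally. The biodiversity score
is `Σ_s w_s (1 − q_s (1 − p_s))^z` over species with taxon-aggregate weights
(Elasmobranchii 34.0%, Actinopterygii 27.3%, …).

## Worked example

```python
from divempa import ScenarioConfig, scenarios, synth

bundle = synth.generate_bundle(seed=1)          # 40x40 world, 50 stocks, 200 species
cfg = ScenarioConfig(seed=1)
prep = scenarios.prepare_world(bundle, cfg)     # traits, biomass, scores, market
res = scenarios.run_scenario(bundle, cfg, prepared=prep)

print(res.aggregates["pct_change_dives"])       # 31.2
print(res.biomass_mean_pct, res.biomass_sd_pct) # 152.8  127.3
print(res.score_bau, res.score_new)             # 0.727  0.736
fees, mean_fee = scenarios.neutral_fee(prep)
print(mean_fee)                                 # 39.47
```

On this seeded world (13 dive pixels, 236,949 dives/yr, US$13.9M baseline
revenue), protecting every dive pixel raises equilibrium biomass in dive
pixels by a K-weighted mean of 152.8% (±127.3% s.d.), lifts the biodiversity
score from 0.727 to 0.736, and — through the WTP shift — increases dives by
31.2%, industry revenue by US$4.3M/yr and consumer surplus by US$10.9M/yr at a
zero fee. A per-pixel neutral fee (dive-weighted mean US$39.47) instead holds
dive numbers constant while collecting fee revenue.

The same pipeline is scriptable from a shell:

```
divempa synth --out world/ --seed 1
divempa run --world world/ --out run/ --policy protect-all --fee 0 --seed 1
divempa fee-sweep --world world/ --out sweep/ --seed 1
divempa monte-carlo --world world/ --out mc/ --runs 500 --seed 1
```

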