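# Methods

## Model structure and assumptions

`krillmpa` is a model of intermediate complexity: it carries exactly the
state needed to study competition between a krill fishery and krill-
dependent predators under spatial closures — krill biomass per zone-unit
and predator abundance per (group, breeding SSMU) — and nothing else (no
age structure beyond the delay-difference lag, no fleet dynamics, no
environmental forcing).  Two seasons per year; summer is the breeding
season.  Predators are central-place foragers: each (group, breeding SSMU,
season) has a foraging row `p_{k,i←j,s}` over zone-units that sums to one.

The seasonal krill update is, in order: summer recruitment; availability
assessment; demand and proportional competition; natural mortality as
survival `exp(−M_s)`; movement.  Ordering matters and is part of the model
definition: the fishery and predators consume from start-of-season
availability (biomass plus fresh recruitment), survivors then die and
drift.  When combined demand at a unit exceeds availability, every
consumer — fishery included — is scaled by the same factor
`availability / total demand`; there is no priority ordering among
consumers.  Consumption can therefore take all available biomass in a
season; persistence then rests on recruitment, which is the intended
behaviour of a recruitment-driven forage stock.

The published delay-difference equations this family of models descends
from are not reproduced verbatim anywhere in this package; the
formulation here is the package's own, honoring the documented structural
properties (delay-difference form, two seasons, start-of-step
availability, proportional competition, two breeder-response modes), with
every functional-form constant exposed in configuration so alternative
published constants can be dropped in.

### Predator dynamics

Annual update `N′ = N·(S + (1−S)·φ(x))`, with `S = exp(−M_k)` and `x` the
realized fraction of summer demand (demand-weighted over foraged units;
`x = 1` where demand is zero).  Recruits are proportional to effective
breeders `N·φ(x)` and calibrated so that a fully satisfied population is
exactly stationary — the model measures *relative* outcomes (MPA vs
No-MPA), so a drift-free baseline is the right null.  Response modes:

- linear: `φ(x) = x`;
- hyperstable: `φ(x) = x(1+h)/(x+h)` with shape `h = 0.2` — equal to the
  linear response at 0 and 1, above it in between, so breeder numbers
  erode slower than prey availability.

A recruitment lag of one year is implicit (recruits from year *t*'s
breeders enter at *t+1*); longer lags would need an explicit queue and are
not implemented.

### Movement

Instantaneous rates `v_{i→j,s}` form a generator `A_s` (columns sum to
zero) and the seasonal operator is `expm(A_s)`, computed once per
parameterization and cached.  This choice is what makes decomposition
exact: if `P` aggregates zones to parent SSMUs, the zone-level generator
`A′` constructed by the decomposition satisfies `P·A′ = A·P`, hence
`P·expm(A′) = expm(A)·P` — aggregation commutes with transport for *any*
within-SSMU biomass distribution, including the internal open↔closed
exchange.  A discrete per-season transfer fraction would not have this
property.

## MPA decomposition

Areas, initial biomass, maximum recruitment and annual catch shares split
linearly by the scenario's closed fractions (`closed = value × fraction`),
reflecting the assumption that krill and catches are spatially random
within an SSMU.  Seasonal catch splits are inherited from the parent.
Movement between distinct SSMUs is carried by every source zone with
inflow split across destination zones by area share.  Foraging rows split
two ways:

- **area-proportional default** (no telemetry percentages supplied): each
  foraged SSMU's contribution divides between its zones by area share;
- **scalar inside-percentage** `f` per (group, breeding SSMU, season): the
  closed mass `f` is spread over closed zones in proportion to the
  original row restricted to SSMUs owning a closed zone (renormalized),
  the open mass `1−f` likewise over SSMUs owning an open zone.  When every
  foraged SSMU has both zones this is exactly `closed_j = f·p_j`,
  `open_j = (1−f)·p_j`; the renormalization only matters when some foraged
  SSMU has no closure, where a literal proportional rule would strand
  probability mass.

Under the drift hypothesis an internal open↔closed exchange is added
within each split SSMU, with rate equal to the SSMU's largest seasonal
outflow rate (configurable) and destination weights equal to area shares,
so each zone's long-run biomass share tends to its area share.  Without
it, a no-take zone would be artificially sealed off from its own SSMU.
Under the no-movement hypothesis there is no internal exchange either —
the hypothesis is taken literally.

**Decomposition identity.**  With the area-proportional foraging default
and `closed_catch_fraction = closed_area_fraction`, a decomposed run with
fishing left in place reproduces the undecomposed run exactly (machine
precision; the test budget allows 1e-6 relative).  The identity is stated
for this basic decomposition: once telemetry-style inside-percentages
detach foraging pressure from area shares, zone-level competition can bind
asymmetrically and aggregate dynamics legitimately differ — that
difference is signal, not error.

## Fishery allocation

Overall limit = initial arena biomass × harvest rate (default 0.093, the
regional precautionary rate).  Baseline tonnage(unit, season) = limit ×
annual share × seasonal split.  Displaced catch per SSMU is its annual
allocation times the closed-catch fraction — implemented as exactly that
product ("up to" shortfalls are expressed later through competition and
threshold violations, since there are no fleet dynamics to withhold
effort.)  Alternatives:

- *Regional*: each SSMU's displaced tonnage goes to the open zones of its
  own subarea, weighted by baseline open-zone shares (renormalized).
  Baseline-share weighting is the default because it collapses to the
  status quo as closures vanish; area-share weighting is available via
  `regional_weighting="area"`, and is also the automatic fallback when a
  subarea's entire recent catch lies inside closures (zero baseline
  weights would otherwise make the rule degenerate).
- *Local*: displaced tonnage goes entirely to the open zone of the
  originating SSMU; a fully closed SSMU with displaced catch is an error.
- *Current*: pooled displaced tonnage spreads over all open zones of the
  arena in proportion to the recent catch distribution restricted to open
  zones.

Redistributed tonnage is split seasonally by the *receiving* unit's
seasonal pattern ("the recent pattern where the catch lands").  Closed
zones end with zero tonnage; the limit is conserved to 1e-6 t.

## Experiment design and metrics

Per (parameterization, trial), recruitment deviates are drawn from a seed
sequence keyed `(experiment seed, parameterization index, trial)`; deviates
are drawn per parent SSMU and shared by its zones, and the MPA and No-MPA
arms replay the identical deviates, so paired differences isolate the
intervention.  Defaults follow the study design: 1001 trials, 30 years,
four parameterizations, harvest rate 0.093, threshold 15 g·m⁻².

- *Relative abundance*: ratio of mean final-year abundance (MPA / No-MPA)
  at SSMU, subarea or arena scale; the arena ratio is abundance-weighted,
  which is why arena-scale results can mask SSMU-scale declines.
  Dispersion is the standard deviation of per-simulation paired ratios.
  With equal trial counts, pooling simulations and averaging
  per-parameterization means coincide.
- *Total catch*: final-year realized catch and its paired ratio, down to
  zone scale.
- *Violation probability*: densities are evaluated on start-of-season
  availability (the biomass the fishery encounters), over zone-seasons
  with positive allocated tonnage.  Default mode counts seasons with at
  least one violating fished zone, divided by the 60 seasons of a 30-year
  run; `per_area_season` normalizes the per-(zone, season) count by fished
  zone-seasons instead.  Both are reported because "how often densities
  fell below the threshold in open areas" is ambiguous between the two
  readings; the 60-season denominator motivates the per-season default.
- *Foraging-protection profile*: one row per (scenario, alternative,
  group, breeding SSMU) relating the summer foraging-inside percentage to
  the SSMU-scale abundance ratio and catch — the scatter used to ask how
  much protection suffices.

## Synthetic data and the toy world

The generator emulates structure, not geography: 15 SSMUs with the
standard subarea membership by default, lognormal areas around
3×10¹⁰ m², initial densities uniform on 5–60 g·m⁻² with both sides of the
15 g·m⁻² threshold guaranteed, ring-topology drift rates up to 0.15 per
season, Dirichlet foraging rows peaked on the home neighborhood,
concentrated Dirichlet catch shares with Beta(2,2) seasonal splits, and
mean-1 lognormal recruitment deviates with σ = 0.5 (krill recruitment is
notoriously variable).  Predator abundances are set so each group demands
about 10% of the biomass it can reach per season.  What it does *not*
emulate: real bathymetry and coastline adjacency, historically conditioned
initial states, correlated recruitment between SSMUs, and the actual
magnitudes of the Scotia Sea inputs beyond order of magnitude — so passing
tests demonstrate the *mechanics* (conservation, identity, pairing,
monotonicity), not quantitative agreement with any real system.

The deterministic toy (3 SSMUs, penguins in 1–2, seals in 3) is designed
in the fishery-dominant regime: predator demand is small relative to the
krill standing stock, while SSMU 3 — a low-recruitment sink holding 60% of
the catch — is outstripped by the fishery every year.  In this regime
competition scales are set by the fishery alone, so sweeping foraging
protection produces a cleanly monotone abundance response and the paired
ratio is exactly 1 at full protection.  With predator demand large enough
to crowd closed zones, strict monotonicity genuinely fails (protection
concentrates predators onto the protected biomass); the toy deliberately
sits where the profile logic is sharp.  Its two-year expected trajectory
ships as a CSV produced by an independent scalar-loop ledger
(`tests/_oracle.py`), giving a dual-route check on the vectorized engine.

## Numerical choices and degenerate inputs

- Tolerances: foraging/catch normalization 1e-9; allocation conservation
  1e-6 t; mass-balance ledger 1e-9 relative; linear splits exact to one
  ulp.
- Zero-demand consumers get scale 1 (no 0/0); zero-area zones are
  rejected at layout construction; zero-biomass units are carried, never
  dropped, so indices stay aligned across scenarios.
- SSMUs with closed fraction 0 pass through decomposition as a single
  open zone; fraction 1 yields a single closed zone, and a partially
  displaced catch there is rejected as inconsistent.
- Deterministic mode (dispersion 0) is bit-reproducible given the seed
  policy; the experiment runner never consumes global random state.

## Problem sizes

The shipped tests run the full 1001-trial, 30-year paired experiment on
the toy; property suites use 200 randomized cases for conservation checks
and 20 for the run-level decomposition identity, with arenas of 2–15
SSMUs.  These sizes were chosen to exercise every code path at full trial
count while keeping the whole suite around ten seconds.

## Known limitations

- The delay-difference constants are this package's calibration, not
  fitted values; absolute trajectories are illustrative, paired ratios are
  the supported output.
- Winter foraging outside the model arena is absorbed into winter
  foraging rows rather than modeled.
- The internal open↔closed exchange rate under drift is a modeling choice
  (the magnitude is not identified by aggregate dynamics, which are
  invariant to it under the basic decomposition).
- No statistical testing on ensemble differences and no map rendering;
  outputs are tidy tables.
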