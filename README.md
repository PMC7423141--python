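# krillmpa

A spatially explicit, minimally realistic simulator of the Antarctic krill
(*Euphausia superba*) fishery and krill-dependent predators in the Scotia
Sea, built to evaluate marine protected area (MPA) scenarios that displace
fishing from closed areas.  It is aimed at ecosystem-based fisheries
scientists who want to profile the benefits and costs of candidate closures
— who gains (predator groups whose foraging is protected), who pays (the
fishery, through forgone or riskier catches), and how the answer changes
with the rule used to reallocate displaced catch.

## The model

The arena is a set of small-scale management units (SSMUs) grouped into
statistical subareas (the standard layout has 15 SSMUs in Subareas
48.1–48.3).  Each model year has two seasons.  Per season and zone-unit
*j*, krill biomass follows a delay-difference update:

1. recruitment `R_j = R̄_j · ε` is added in summer, with `ε` a mean-1
   lognormal deviate shared by the zones of a parent SSMU;
2. availability `A_j = B_j + R_j` is assessed at the start of the step;
3. every consumer states its demand — predator group *k* breeding in SSMU
   *i* demands `N_{k,i} · d_{k,s}` spread over units by its foraging
   proportions `p_{k,i←j,s}`, and the fishery demands its seasonal catch
   allocation — and when combined demand exceeds `A_j` all consumers are
   scaled by the common factor `A_j / ΣD_j` (proportional competition);
4. natural mortality acts as survival `exp(−M_s)`;
5. movement applies the matrix exponential of the instantaneous-rate
   generator `v_{i→j,s}` (zero under the no-movement hypothesis).

Predators update annually: the effective number of breeders is
`N · φ(x)` where `x` is the realized fraction of summer demand and `φ` is
either linear (`φ(x) = x`) or hyperstable (`φ(x) = x(1+h)/(x+h)`,
`h = 0.2`); abundance follows `N′ = N·(S + (1−S)·φ(x))` with annual
survival `S = exp(−M_k)`, so fully fed populations are stationary.  Four
reference parameterizations bracket the key uncertainties: {no movement,
passive drift} × {hyperstable, linear}.

An MPA scenario closes a fraction of each SSMU's area and of its recent
(2009–2017-style) catch.  The five spatial parameter classes — initial
krill biomass, maximum recruitment, movement, catch history, foraging —
are decomposed into open/closed zones such that an undisplaced run
aggregates exactly back to the whole-SSMU model.  The overall catch limit
is initial arena biomass × the regional harvest rate (0.093).  Displaced
catch (SSMU allocation × closed-catch fraction; 100 t with 20% inside ⇒
20 t) is reallocated under one of three alternatives: **Regional** (within
the originating subarea), **Local** ("fishing the line": to the open zone
of the originating SSMU), or **Current** (across all open zones in
proportion to the recent catch distribution).  Outcomes are measured
against a paired No-MPA counterfactual run on identical recruitment draws:
final-year predator abundance ratios at zone/SSMU/subarea/arena scales,
final-year total catch, and the probability that krill density in fished
areas falls below 15 g·m⁻² (a "threshold violation", counted per season
out of the 60 seasons of a 30-year run).

The telemetry-derived foraging-inside percentages of the two published
Scotia Sea scenarios (D1MPA and US10) ship as a fixture
(`krillmpa.load_table1_fixture()`).

## Worked example

A deliberately small three-SSMU world ships with the package: SSMUs 1–2
are comfortable, SSMU 3 is a low-recruitment sink carrying most of the
catch, penguins breed in SSMUs 1–2 and seals in SSMU 3.  The `ToyMPA`
scenario closes half of every SSMU and protects 80% of penguin and 70% of
seal summer foraging:

```python
import dataclasses
import krillmpa as km
from krillmpa.synth import toy_scenarios

par = dataclasses.replace(km.toy_parameterization(),
                          recruitment_noise=km.RecruitmentNoise("lognormal", 0.5))
scenario = toy_scenarios()["ToyMPA"]
cfg = km.RunConfig(n_trials=1001, n_years=30, seed=42)
res = km.run_experiment([par], scenario, cfg)

print(km.relative_abundance(res.mpa, res.no_mpa, scale="arena").to_string(index=False))
print(km.total_catch(res.mpa, res.no_mpa, scale="arena").to_string(index=False))
print("violation probability, MPA:   ", round(km.violation_probability(res.mpa), 3))
print("violation probability, No MPA:", round(km.violation_probability(res.no_mpa), 3))
```

prints

```
   group scale  unit    ratio      std  defined
penguins arena arena 1.024545 0.001501     True
   seals arena arena 1.379395 0.037237     True
scale  unit  catch_tonnes    ratio      std  defined
arena arena  30493.662195 0.896376 0.038235     True
violation probability, MPA:    1.0
violation probability, No MPA: 1.0
```

Predators whose foraging the closure protects gain (penguins +2.5%, seals
+38% relative to the No-MPA reference; `std` is the spread of the paired
per-trial ratios across the 1001 simulations).  The fishery pays: realized
catch falls to 0.90× the reference because displaced catch lands in the
open half of krill-poor SSMU 3.  Density violations saturate at 1.0 here
because SSMU 3 sits below 15 g·m⁻² every season; the per-(area, season)
normalization (`km.violation_probability(res.mpa, "per_area_season")` →
0.339 vs 0.337 without the MPA) resolves the finer difference.

The same pipeline runs from the shell — `krillmpa synth | decompose |
allocate | simulate | report` — see `krillmpa --help`.

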