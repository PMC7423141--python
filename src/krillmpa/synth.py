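"""Synthetic parameterizations, scenarios and the deterministic toy world.

The generator emulates the statistical structure of the Scotia Sea inputs —
central-place foraging rows normalized per (group, breeding SSMU, season),
ring-structured drift movement, concentrated 2009–2017-style catch
distributions with per-SSMU seasonal splits, and initial krill densities
spanning both sides of the 15 g·m⁻² threshold — without claiming the real
geography beyond orders of magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .params import (
    SUMMER, WINTER, SEASONS, DEFAULT_GROUPS, SUBAREA_OF_SSMU, Layout,
    RecruitmentNoise, ReferenceParameterization, ScenarioDefinition,
    ValidationError,
)

__all__ = ["SynthConfig", "generate_parameterization", "generate_scenario",
           "make_toy_fixture", "toy_parameterization"]

#: per-capita seasonal krill demand, tonnes per animal (summer, winter)
_DEMAND_PER_CAPITA = {
    "penguins": (0.08, 0.04),
    "seals": (0.8, 0.4),
    "whales": (12.0, 5.0),
    "fish": (0.01, 0.01),
}

#: annual instantaneous natural mortality by group
_PREDATOR_MORTALITY = {
    "penguins": 0.10, "seals": 0.12, "whales": 0.05, "fish": 0.30,
}


@dataclass
class SynthConfig:
    """Knobs of the synthetic world.

    Defaults mirror the study conditions: a 15-SSMU arena with the standard
    subarea membership, four predator groups, initial densities spanning
    the 15 g·m⁻² threshold, and mean-1 lognormal recruitment deviates with
    σ = 0.5 (high interannual krill recruitment variability).
    """

    n_ssmu: int = 15
    seed: int = 0
    movement_mode: str = "drift"
    response_mode: str = "hyperstable"
    groups: tuple = DEFAULT_GROUPS
    area_scale: float = 3.0e10            # m², typical SSMU surface
    density_range: tuple = (5.0, 60.0)    # g·m⁻² initial krill density
    krill_mortality: tuple = (0.4, 0.4)   # per season
    occupancy_prob: float = 0.6           # chance a group breeds in an SSMU
    foraging_concentration: float = 6.0   # how peaked rows are on the home SSMU
    movement_intensity: float = 0.15      # max drift rate per season
    catch_concentration: float = 0.8      # Dirichlet α for catch shares
    recruitment_dispersion: float = 0.5   # lognormal σ
    demand_to_biomass: float = 0.10       # per-group demand vs foraged biomass

    def validate(self) -> "SynthConfig":
        if self.n_ssmu < 1:
            raise ValidationError("n_ssmu must be >= 1")
        if self.recruitment_dispersion < 0:
            raise ValidationError("recruitment_dispersion must be >= 0")
        if not self.groups:
            raise ValidationError("at least one predator group required")
        return self


def _ssmu_ids_and_subareas(n_ssmu: int) -> tuple[np.ndarray, dict]:
    ids = np.arange(1, n_ssmu + 1)
    if n_ssmu == 15:
        return ids, dict(SUBAREA_OF_SSMU)
    # small arenas: first ~2/3 of SSMUs in 48.1, remainder in 48.2
    cut = max(1, (2 * n_ssmu) // 3)
    return ids, {int(s): ("48.1" if s <= cut else "48.2") for s in ids}


def generate_parameterization(cfg: SynthConfig) -> ReferenceParameterization:
    """Draw a validated parameterization with the structure the pipeline
    assumes.  Seed-deterministic."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_ssmu
    ids, subareas = _ssmu_ids_and_subareas(m)

    areas = cfg.area_scale * rng.lognormal(mean=0.0, sigma=0.4, size=m)
    lo, hi = cfg.density_range
    # guarantee densities on both sides of the 15 g/m² threshold
    dens = rng.uniform(lo, hi, size=m)
    if m >= 2:
        dens[rng.integers(m)] = rng.uniform(lo, min(14.0, hi))
        dens[rng.integers(m)] = rng.uniform(max(16.0, lo), hi)
    layout = Layout.whole(ids, areas, subareas)
    order = np.argsort(ids)  # Layout.whole sorts; keep arrays aligned
    krill_init = dens[order] * layout.area / 1.0e6  # g/m² × m² → tonnes

    # steady-state recruitment for the no-fishing, no-predator system
    annual_m = float(np.sum(cfg.krill_mortality))
    max_rec = krill_init * np.expm1(annual_m) * rng.uniform(0.8, 1.2, size=m)

    movement = np.zeros((2, m, m))
    if cfg.movement_mode == "drift" and m > 1:
        for s in (SUMMER, WINTER):
            for i in range(m):
                for j in ((i + 1) % m, (i - 1) % m):
                    if i != j:
                        movement[s, i, j] = rng.uniform(0, cfg.movement_intensity)
            np.fill_diagonal(movement[s], 0.0)

    g = len(cfg.groups)
    occupancy = rng.random((g, m)) < cfg.occupancy_prob
    for k in range(g):
        if not occupancy[k].any():
            occupancy[k, rng.integers(m)] = True

    # central-place foraging: Dirichlet rows peaked on the home neighborhood
    foraging = np.zeros((2, g, m, m))
    pos = np.arange(m)
    for k in range(g):
        for i in range(m):
            if not occupancy[k, i]:
                continue
            dist = np.minimum(np.abs(pos - i), m - np.abs(pos - i))
            w = np.exp(-dist / 2.0)
            alpha = cfg.foraging_concentration * w / w.sum() + 0.15
            for s in (SUMMER, WINTER):
                row = rng.dirichlet(alpha)
                foraging[s, k, i] = row / row.sum()

    demand = np.array([_DEMAND_PER_CAPITA.get(gname, (0.1, 0.05))
                       for gname in cfg.groups])
    pred_mort = np.array([_PREDATOR_MORTALITY.get(gname, 0.15)
                          for gname in cfg.groups])
    predator_init = np.zeros((g, m))
    for k in range(g):
        for i in range(m):
            if occupancy[k, i]:
                foraged = float(foraging[SUMMER, k, i] @ krill_init)
                predator_init[k, i] = (cfg.demand_to_biomass * foraged
                                       / demand[k, SUMMER])

    catch_annual = rng.dirichlet(np.full(m, cfg.catch_concentration))
    summer_frac = rng.beta(2.0, 2.0, size=m)
    catch_seasonal = np.column_stack([summer_frac, 1.0 - summer_frac])

    par = ReferenceParameterization(
        movement_mode=cfg.movement_mode, response_mode=cfg.response_mode,
        layout=layout, krill_init=krill_init, max_recruitment=max_rec,
        movement=movement, groups=tuple(cfg.groups),
        predator_init=predator_init, foraging=foraging,
        demand_per_capita=demand, krill_mortality=np.asarray(cfg.krill_mortality),
        predator_mortality=pred_mort, catch_annual=catch_annual,
        catch_seasonal=catch_seasonal,
        recruitment_noise=RecruitmentNoise("lognormal", cfg.recruitment_dispersion),
    )
    return par.validate()


def generate_scenario(cfg: SynthConfig, target_protection,
                      name: str = "synthMPA",
                      redistribution: str = "regional",
                      par: ReferenceParameterization | None = None
                      ) -> ScenarioDefinition:
    """A scenario whose decomposed closed-zone foraging equals the
    requested protection percentages.

    ``target_protection`` is a percentage in [0, 100], scalar or per-group
    mapping.  Every SSMU receives a partial closure (so any target is
    feasible under the scalar decomposition rule); a uniformly zero target
    returns the No-MPA scenario.
    """
    cfg.validate()
    if par is None:
        par = generate_parameterization(cfg)
    if np.isscalar(target_protection):
        targets = {gname: float(target_protection) for gname in par.groups}
    else:
        targets = {str(k): float(v) for k, v in dict(target_protection).items()}
    for gname, t in targets.items():
        if gname not in par.groups:
            raise ValidationError(f"target names unknown group {gname!r}")
        if not (0.0 <= t <= 100.0):
            raise ValidationError(f"target protection {t} outside [0, 100]")

    ssmus = [int(s) for s in par.layout.ssmus]
    if all(t == 0.0 for t in targets.values()):
        return ScenarioDefinition.no_mpa(ssmus)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(97,)))
    caf = {s: float(rng.uniform(0.3, 0.7)) for s in ssmus}
    ccf = dict(caf)
    fi = {}
    occ = par.occupancy
    for k, gname in enumerate(par.groups):
        t = targets.get(gname, 0.0)
        for i, s in enumerate(ssmus):
            if occ[k, i]:
                fi[(gname, s, "summer")] = t
                fi[(gname, s, "winter")] = t
    return ScenarioDefinition(name=name, closed_area_fraction=caf,
                              closed_catch_fraction=ccf, foraging_inside=fi,
                              redistribution=redistribution).validate(par)


# ---------------------------------------------------------------------------
# Deterministic toy world
# ---------------------------------------------------------------------------

def toy_parameterization() -> ReferenceParameterization:
    """A hand-sized 3-SSMU, 2-group, dispersion-0 world.

    SSMU 3 starts below the 15 g·m⁻² density threshold and carries most of
    the catch, so the fishery drives competition there and the
    protection/violation logic is exercised; SSMUs 1–2 are comfortable.
    Predator demand is kept small relative to the krill standing stock, so
    predators respond to scarcity without themselves driving it — the
    regime in which foraging protection maps cleanly onto outcomes.
    """
    layout = Layout.whole([1, 2, 3], [1.0e10, 2.0e10, 1.0e10],
                          {1: "48.1", 2: "48.1", 3: "48.2"})
    dens = np.array([30.0, 20.0, 2.0])             # g/m²
    krill_init = dens * layout.area / 1.0e6        # 300k, 400k, 20k t
    krill_mortality = np.array([0.4, 0.4])
    # SSMUs 1-2 at steady state absent harvest; SSMU 3 is a low-recruitment
    # sink whose availability the fishery outstrips (scarcity regime)
    max_rec = krill_init * np.expm1(0.8) * np.array([1.0, 1.0, 0.3])

    groups = ("penguins", "seals")
    predator_init = np.array([
        [2.0e4, 1.5e4, 0.0],
        [0.0, 0.0, 1.2e3],
    ])
    foraging = np.zeros((2, 2, 3, 3))
    foraging[SUMMER, 0, 0] = (0.70, 0.20, 0.10)
    foraging[SUMMER, 0, 1] = (0.15, 0.75, 0.10)
    foraging[SUMMER, 1, 2] = (0.10, 0.20, 0.70)
    foraging[WINTER, 0, 0] = (0.50, 0.30, 0.20)
    foraging[WINTER, 0, 1] = (0.20, 0.60, 0.20)
    foraging[WINTER, 1, 2] = (0.20, 0.30, 0.50)

    par = ReferenceParameterization(
        movement_mode="none", response_mode="hyperstable", layout=layout,
        krill_init=krill_init, max_recruitment=max_rec,
        movement=np.zeros((2, 3, 3)), groups=groups,
        predator_init=predator_init, foraging=foraging,
        demand_per_capita=np.array([[0.08, 0.04], [0.8, 0.4]]),
        krill_mortality=krill_mortality,
        predator_mortality=np.array([0.10, 0.12]),
        catch_annual=np.array([0.2, 0.2, 0.6]),
        catch_seasonal=np.array([[0.7, 0.3], [0.6, 0.4], [0.5, 0.5]]),
        recruitment_noise=RecruitmentNoise("lognormal", 0.0),
    )
    return par.validate()


def toy_scenarios() -> dict:
    """The toy MPA (half of every SSMU closed) and its No-MPA reference."""
    mpa = ScenarioDefinition(
        name="ToyMPA",
        closed_area_fraction={1: 0.5, 2: 0.5, 3: 0.5},
        closed_catch_fraction={1: 0.5, 2: 0.5, 3: 0.5},
        foraging_inside={
            ("penguins", 1, "summer"): 80.0, ("penguins", 1, "winter"): 60.0,
            ("penguins", 2, "summer"): 80.0, ("penguins", 2, "winter"): 60.0,
            ("seals", 3, "summer"): 70.0, ("seals", 3, "winter"): 50.0,
        },
        redistribution="regional",
    )
    return {"ToyMPA": mpa, "NoMPA": ScenarioDefinition.no_mpa([1, 2, 3])}


def make_toy_fixture() -> tuple[ReferenceParameterization, dict, pd.DataFrame]:
    """The toy world, its scenarios, and frozen expected trajectories.

    The expectation CSV holds a two-year baseline (undisplaced) run of the
    toy, produced by an independently hand-stepped ledger: end-of-season
    krill biomass and realized catch per unit, and predator abundance per
    (group, breeding SSMU) at each year boundary.
    """
    par = toy_parameterization()
    with resources.files("krillmpa.data").joinpath("toy_expected.csv").open() as fh:
        expected = pd.read_csv(fh)
    return par, toy_scenarios(), expected
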