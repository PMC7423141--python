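"""Seasonal delay-difference dynamics for krill and predator groups.

Each model year has two seasons (summer, then winter).  The seasonal krill
update, per zone-unit, is:

1. recruitment ``R = max_recruitment × ε`` added (summer only by default),
   with ε a mean-1 multiplicative deviate shared by both zones of a parent
   SSMU so that decomposed and whole-SSMU runs consume identical noise;
2. available biomass assessed: ``A = B + R``;
3. demand computed for every consumer (predator groups via the foraging
   matrix, the fishery via its seasonal allocation) and consumption
   allocated — when combined demand exceeds availability every consumer,
   fishery included, is scaled by the common factor ``A / demand``;
4. natural mortality applied as survival ``exp(−M_s)``;
5. movement applied as the matrix exponential of the instantaneous-rate
   generator (mass-conserving; identity when rates are zero).

Predator groups update at the year boundary: the effective number of
breeders is the abundance times a response φ(x) of the realized fraction x
of summer (breeding season) demand — φ(x) = x for the linear response,
φ(x) = x(1+h)/(x+h) for the hyperstable response — and next abundance
follows the delay-difference survival-plus-recruits form
``N' = N·(S + (1−S)·φ(x))`` with annual survival ``S = exp(−M_k)``, so a
fully satisfied population (x = 1) is stationary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .params import (
    SUMMER, WINTER, SEASONS, ReferenceParameterization, ValidationError,
    GRAMS_PER_TONNE,
)

__all__ = [
    "ModelState", "DemandLedger", "StepLedger", "Trajectory",
    "transition_matrices", "krill_recruitment", "compute_demand",
    "allocate_consumption", "breeder_response", "predator_update",
    "step_season", "run_trial", "initial_state",
]


@dataclass
class ModelState:
    """Krill biomass per zone-unit and predator abundance per (group,
    breeding SSMU) at one season boundary."""

    krill: np.ndarray          # (n_units,) tonnes
    predators: np.ndarray      # (n_groups, n_ssmu) animals
    year: int = 0
    season: int = SUMMER

    def copy(self) -> "ModelState":
        return ModelState(self.krill.copy(), self.predators.copy(),
                          self.year, self.season)


@dataclass
class DemandLedger:
    """Demand and realized consumption per consumer and zone-unit for one
    season.  Consumers are the predator groups plus the fishery (last
    row)."""

    consumers: tuple
    demand: np.ndarray    # (n_groups + 1, n_units)
    realized: np.ndarray  # same shape; filled by allocate_consumption
    scale: np.ndarray | None = None  # (n_units,) common competition factor

    @property
    def fishery_row(self) -> int:
        return len(self.consumers) - 1


@dataclass
class StepLedger:
    """Mass-balance bookkeeping for one seasonal step."""

    season: int
    recruits: np.ndarray          # (n_units,)
    available: np.ndarray         # (n_units,) biomass after recruitment
    demand: DemandLedger
    mortality_loss: np.ndarray    # (n_units,)
    net_movement: np.ndarray      # (n_units,)
    realized_fraction: np.ndarray  # (n_groups, n_ssmu) x per breeding row


@dataclass
class Trajectory:
    """Per-season krill biomass and realized catch, and per-year predator
    abundance, for one trial."""

    krill: np.ndarray            # (n_years, 2, n_units) end-of-season biomass
    available: np.ndarray        # (n_years, 2, n_units) start-of-season availability
    realized_catch: np.ndarray   # (n_years, 2, n_units)
    predators: np.ndarray        # (n_years + 1, n_groups, n_ssmu) (index 0 = initial)


def initial_state(par: ReferenceParameterization) -> ModelState:
    return ModelState(krill=par.krill_init.copy(),
                      predators=par.predator_init.copy())


def transition_matrices(par: ReferenceParameterization) -> np.ndarray:
    """(2, n, n) seasonal movement operators ``T_s = expm(A_s)`` with
    generator ``A[j, i] = v[s, i, j]`` off-diagonal and columns summing to
    zero (mass conservation)."""
    n = par.n_units
    T = np.empty((2, n, n))
    for s in (SUMMER, WINTER):
        if not par.movement[s].any():
            T[s] = np.eye(n)
            continue
        A = par.movement[s].T.copy()
        np.fill_diagonal(A, -par.movement[s].sum(axis=1))
        T[s] = expm(A)
    return T


def krill_recruitment(par: ReferenceParameterization, rng: np.random.Generator,
                      size=None) -> np.ndarray:
    """Recruitment deviates ε (mean 1) drawn per parent SSMU; tonnes
    recruited in a unit are ``max_recruitment × ε[parent]``."""
    if size is None:
        size = par.layout.n_ssmu
    return par.recruitment_noise.draw(rng, size)


def compute_demand(state: ModelState, par: ReferenceParameterization,
                   allocation: np.ndarray, season: int) -> DemandLedger:
    """Krill demand per consumer and zone-unit for one season.

    Predator demand on unit j is Σ_k Σ_i N[k,i]·d[k,s]·p[s,k,i,j]; fishery
    demand is the seasonal allocation (zero on closed zones by
    construction of any redistributed allocation).
    """
    n, g = par.n_units, par.n_groups
    occ = par.occupancy
    if np.any(par.foraging[season][occ].sum(axis=-1) == 0):
        raise ValidationError("missing foraging row for an occupied breeding unit")
    # per-group demand: (n_ssmu,) totals through (n_ssmu, n_units) proportions
    demand = np.zeros((g + 1, n))
    for k in range(g):
        totals = state.predators[k] * par.demand_per_capita[k, season]
        demand[k] = totals @ par.foraging[season, k]
    alloc = np.asarray(allocation, dtype=float)
    if alloc.shape != (n,):
        raise ValidationError(f"allocation must have shape ({n},)")
    demand[g] = alloc
    return DemandLedger(consumers=par.groups + ("fishery",),
                        demand=demand, realized=np.zeros_like(demand))


def allocate_consumption(ledger: DemandLedger, available: np.ndarray
                         ) -> DemandLedger:
    """Fill realized consumption: full demand where availability suffices,
    otherwise all consumers scaled proportionally by available/demand."""
    available = np.asarray(available, dtype=float)
    if np.any(available < 0):
        raise ValidationError("available biomass must be nonnegative")
    total = ledger.demand.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(total > available,
                         np.divide(available, total, out=np.ones_like(total),
                                   where=total > 0),
                         1.0)
    ledger.scale = scale
    ledger.realized = ledger.demand * scale
    return ledger


def breeder_response(x: np.ndarray, response_mode: str,
                     shape: float = 0.2) -> np.ndarray:
    """φ(x): effective-breeder fraction given realized demand fraction x.

    Linear: φ(x) = x.  Hyperstable: φ(x) = x(1+h)/(x+h), which equals the
    linear response at 0 and 1 and exceeds it in between (shallower decline
    of effective breeders as krill availability falls).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < -1e-12) | (x > 1 + 1e-12)):
        raise ValidationError("realized fraction must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    if response_mode == "linear":
        return x
    if response_mode == "hyperstable":
        if shape <= 0:
            raise ValidationError("hyperstability shape must be > 0")
        return x * (1.0 + shape) / (x + shape)
    raise ValidationError(f"unknown response mode {response_mode!r}")


def predator_update(abundance: np.ndarray, realized_fraction: np.ndarray,
                    response_mode: str, annual_mortality: np.ndarray,
                    shape: float = 0.2) -> np.ndarray:
    """Annual delay-difference update ``N' = N·(S + (1−S)·φ(x))`` with
    ``S = exp(−M)``; recruits are proportional to effective breeders
    ``N·φ(x)`` and exactly replace losses when demand is fully met."""
    phi = breeder_response(realized_fraction, response_mode, shape)
    S = np.exp(-np.asarray(annual_mortality, dtype=float))[:, None]
    return abundance * (S + (1.0 - S) * phi)


def step_season(state: ModelState, par: ReferenceParameterization,
                allocation: np.ndarray, eps: np.ndarray | float = 1.0,
                transition: np.ndarray | None = None,
                recruit_in: int = SUMMER) -> tuple[ModelState, StepLedger]:
    """Advance one season; returns the next state and a mass-balance
    ledger.  ``eps`` is the per-parent-SSMU recruitment deviate for this
    season (ignored outside the recruiting season)."""
    s = state.season
    lay = par.layout
    if transition is None:
        transition = transition_matrices(par)
    T = transition[s]

    if s == recruit_in:
        eps_arr = np.broadcast_to(np.asarray(eps, dtype=float), (lay.n_ssmu,))
        recruits = par.max_recruitment * eps_arr[lay.parent_index]
    else:
        recruits = np.zeros(lay.n_units)
    available = state.krill + recruits

    ledger = compute_demand(state, par, allocation, s)
    allocate_consumption(ledger, available)
    consumed = ledger.realized.sum(axis=0)

    after_consumption = available - consumed
    # guard round-off: consumption never exceeds availability analytically
    after_consumption = np.maximum(after_consumption, 0.0)
    survival = np.exp(-par.krill_mortality[s])
    after_mortality = after_consumption * survival
    moved = T @ after_mortality

    if not np.all(np.isfinite(moved)):
        bad = np.flatnonzero(~np.isfinite(moved))[0]
        raise ValidationError(
            f"non-finite krill biomass in unit (SSMU {lay.ssmu_id[bad]}, "
            f"{lay.zone[bad]}) after movement in {SEASONS[s]}")

    # realized demand fraction per breeding row: Σ_j p[s,k,i,j]·scale_j
    x = np.einsum("kij,j->ki", par.foraging[s], ledger.scale)
    x = np.where(par.occupancy, x, 1.0)

    step = StepLedger(season=s, recruits=recruits, available=available,
                      demand=ledger, mortality_loss=after_consumption - after_mortality,
                      net_movement=moved - after_mortality, realized_fraction=x)

    nxt = ModelState(krill=moved, predators=state.predators.copy(),
                     year=state.year, season=s)
    if s == SUMMER:
        nxt.season = WINTER
    else:
        nxt.season = SUMMER
        nxt.year = state.year + 1
    return nxt, step


def run_trial(par: ReferenceParameterization, allocation: np.ndarray,
              n_years: int, eps: np.ndarray | None = None,
              transition: np.ndarray | None = None) -> Trajectory:
    """Run one trial of ``n_years`` (two seasons each).

    ``allocation`` is the (n_units, 2) seasonal catch allocation applied
    every year; ``eps`` the (n_years, n_ssmu) recruitment deviates (ones if
    omitted).  Predators update annually from the summer realized demand
    fraction.
    """
    par_t = transition if transition is not None else transition_matrices(par)
    lay = par.layout
    if eps is None:
        eps = np.ones((n_years, lay.n_ssmu))
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (n_years, lay.n_ssmu):
        raise ValidationError(
            f"eps must have shape ({n_years}, {lay.n_ssmu}), got {eps.shape}")
    alloc = np.asarray(allocation, dtype=float)
    if alloc.shape != (lay.n_units, 2):
        raise ValidationError("allocation must have shape (n_units, 2)")

    state = initial_state(par)
    traj = Trajectory(
        krill=np.zeros((n_years, 2, lay.n_units)),
        available=np.zeros((n_years, 2, lay.n_units)),
        realized_catch=np.zeros((n_years, 2, lay.n_units)),
        predators=np.zeros((n_years + 1, par.n_groups, lay.n_ssmu)),
    )
    traj.predators[0] = state.predators
    for y in range(n_years):
        x_summer = None
        for s in (SUMMER, WINTER):
            state, step = step_season(state, par, alloc[:, s], eps[y],
                                      transition=par_t)
            traj.krill[y, s] = state.krill
            traj.available[y, s] = step.available
            traj.realized_catch[y, s] = step.demand.realized[step.demand.fishery_row]
            if s == SUMMER:
                x_summer = step.realized_fraction
        state.predators = predator_update(
            state.predators, x_summer, par.response_mode,
            par.predator_mortality, par.hyperstability_shape)
        traj.predators[y + 1] = state.predators
    return traj


def densities(traj_biomass: np.ndarray, layout) -> np.ndarray:
    """Convert tonnes per unit to g·m⁻² (broadcast over leading axes)."""
    return traj_biomass * GRAMS_PER_TONNE / layout.area
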