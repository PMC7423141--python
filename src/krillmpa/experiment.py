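"""Monte Carlo experiment runner and tradeoff metrics.

An experiment pairs an MPA run (displaced catch redistributed, closed zones
unfished) with a No-MPA counterfactual (same decomposed arena, fishing *not*
displaced) on identical recruitment draws, for each reference
parameterization and trial.  Metrics follow the study design: final-year
predator abundance ratios (MPA / No MPA) at arena, subarea or SSMU scale;
final-year total catch ratios down to zone scale; and the probability that
season-specific krill density in fished areas falls below a threshold
(15 g·m⁻² by default), using the 60-season denominator of a 30-year run.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics
from .allocation import (CatchAllocation, baseline_allocation, displaced_catch,
                         overall_catch_limit, redistribute)
from .decompose import decompose_parameterization
from .params import (
    SUMMER, WINTER, SEASONS, GRAMS_PER_TONNE, ReferenceParameterization,
    RunConfig, ScenarioDefinition, ValidationError,
)

__all__ = [
    "EnsembleResult", "ExperimentResult", "run_ensemble", "run_experiment",
    "relative_abundance", "total_catch", "count_threshold_violations",
    "violation_probability", "foraging_protection_profile",
]

SCALES = ("zone", "ssmu", "subarea", "arena")


@dataclass
class EnsembleResult:
    """Final-year state and violation tallies over trials ×
    parameterizations for one arm (MPA or No-MPA) of an experiment."""

    layout: object
    groups: tuple
    parameterizations: tuple          # (movement_mode, response_mode) labels
    n_years: int
    threshold: float
    final_abundance: np.ndarray       # (n_par, n_trials, n_groups, n_ssmu)
    final_krill: np.ndarray           # (n_par, n_trials, n_units) end-of-run biomass
    final_catch: np.ndarray           # (n_par, n_trials, n_units, 2)
    violations_any: np.ndarray        # (n_par, n_trials) seasons with >=1 violating zone
    violations_zone: np.ndarray       # (n_par, n_trials) violating (zone, season) pairs
    fished_zone_seasons: np.ndarray   # (n_par,) fished zone-season count per run
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.final_abundance.shape[1]

    @property
    def n_seasons(self) -> int:
        return 2 * self.n_years


@dataclass
class ExperimentResult:
    """Paired MPA and No-MPA ensembles plus the inputs that produced them."""

    scenario: ScenarioDefinition
    alternative: str
    config: RunConfig
    mpa: EnsembleResult
    no_mpa: EnsembleResult
    decomposed: list = field(default_factory=list)
    allocations_mpa: list = field(default_factory=list)
    allocations_ref: list = field(default_factory=list)


def count_threshold_violations(density: np.ndarray, fished: np.ndarray,
                               threshold: float,
                               mode: str = "any_area_per_season"
                               ) -> int:
    """Count threshold violations in one trial.

    ``density`` is (n_years, 2, n_units) in g·m⁻²; ``fished`` a boolean
    (n_units, 2) mask of zone-seasons open to (and allocated) fishing.
    ``any_area_per_season`` counts seasons with at least one fished zone
    below threshold (max 2·n_years); ``per_area_season`` counts violating
    (zone, season) pairs.
    """
    density = np.asarray(density, dtype=float)
    mask = np.asarray(fished, dtype=bool).T[None, :, :]  # (1, 2, n_units)
    below = (density < threshold) & mask
    if mode == "any_area_per_season":
        return int(below.any(axis=2).sum())
    if mode == "per_area_season":
        return int(below.sum())
    raise ValidationError(f"unknown violation mode {mode!r}")


def _trial_seeds(seed: int, p_idx: int, trial: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(p_idx, trial))
    return np.random.default_rng(ss)


def run_ensemble(pars: list, allocations: list, config: RunConfig,
                 eps_for=None) -> EnsembleResult:
    """Run ``config.n_trials`` trials for each (parameterization,
    allocation) pair, with recruitment deviates drawn by ``eps_for(p, t)``
    (defaults to seeds derived from ``config.seed``)."""
    lay = pars[0].layout
    n_par, n_trials = len(pars), config.n_trials
    res = EnsembleResult(
        layout=lay, groups=pars[0].groups,
        parameterizations=tuple((p.movement_mode, p.response_mode) for p in pars),
        n_years=config.n_years, threshold=config.density_threshold,
        final_abundance=np.zeros((n_par, n_trials, pars[0].n_groups, lay.n_ssmu)),
        final_krill=np.zeros((n_par, n_trials, lay.n_units)),
        final_catch=np.zeros((n_par, n_trials, lay.n_units, 2)),
        violations_any=np.zeros((n_par, n_trials)),
        violations_zone=np.zeros((n_par, n_trials)),
        fished_zone_seasons=np.zeros(n_par), seed=config.seed,
    )
    for p_idx, (par, alloc) in enumerate(zip(pars, allocations)):
        T = dynamics.transition_matrices(par)
        fished = alloc.tonnage > 0
        res.fished_zone_seasons[p_idx] = fished.sum() * config.n_years
        for t in range(n_trials):
            if eps_for is None:
                rng = _trial_seeds(config.seed, p_idx, t)
                eps = par.recruitment_noise.draw(rng, (config.n_years, lay.n_ssmu))
            else:
                eps = eps_for(p_idx, t)
            traj = dynamics.run_trial(par, alloc.tonnage, config.n_years,
                                      eps=eps, transition=T)
            res.final_abundance[p_idx, t] = traj.predators[-1]
            res.final_krill[p_idx, t] = traj.krill[-1, WINTER]
            res.final_catch[p_idx, t] = traj.realized_catch[-1].T
            dens = traj.available * GRAMS_PER_TONNE / lay.area
            res.violations_any[p_idx, t] = count_threshold_violations(
                dens, fished, config.density_threshold, "any_area_per_season")
            res.violations_zone[p_idx, t] = count_threshold_violations(
                dens, fished, config.density_threshold, "per_area_season")
    return res


def run_experiment(base_pars: list, scenario: ScenarioDefinition,
                   config: RunConfig, alternative: str | None = None,
                   internal_exchange_rate: float | None = None
                   ) -> ExperimentResult:
    """Decompose, allocate, and run the paired MPA / No-MPA ensembles.

    ``base_pars`` are undecomposed reference parameterizations (one per
    model hypothesis).  The No-MPA arm keeps the baseline allocation —
    closed-zone catches retained in place — while the MPA arm applies the
    scenario's redistribution alternative.  Both arms share trial-by-trial
    recruitment draws so metric noise reflects only the intervention.
    """
    config.validate()
    alternative = alternative or scenario.redistribution
    decomposed, alloc_mpa, alloc_ref = [], [], []
    for par in base_pars:
        dec = decompose_parameterization(par, scenario,
                                         internal_exchange_rate=internal_exchange_rate)
        limit = overall_catch_limit(par.total_krill_init(), config.harvest_rate)
        baseline = baseline_allocation(limit, dec)
        displaced = displaced_catch(baseline, scenario)
        redistributed = redistribute(displaced, baseline, alternative, dec)
        decomposed.append(dec)
        alloc_ref.append(baseline)
        alloc_mpa.append(redistributed)

    # shared recruitment draws: both arms replay identical deviates
    lay = decomposed[0].layout
    def eps_for(p_idx, t):
        rng = _trial_seeds(config.seed, p_idx, t)
        return decomposed[p_idx].recruitment_noise.draw(
            rng, (config.n_years, lay.n_ssmu))

    mpa = run_ensemble(decomposed, alloc_mpa, config, eps_for=eps_for)
    ref = run_ensemble(decomposed, alloc_ref, config, eps_for=eps_for)
    return ExperimentResult(scenario=scenario, alternative=alternative,
                            config=config, mpa=mpa, no_mpa=ref,
                            decomposed=decomposed, allocations_mpa=alloc_mpa,
                            allocations_ref=alloc_ref)


# ---------------------------------------------------------------------------
# Aggregation and tradeoff metrics
# ---------------------------------------------------------------------------

def _ssmu_groups(layout, scale: str) -> list[tuple[str, np.ndarray]]:
    """(label, ssmu-position indices) pairs for one aggregation scale."""
    ssmus = layout.ssmus
    if scale == "ssmu":
        return [(str(int(s)), np.array([i])) for i, s in enumerate(ssmus)]
    if scale == "subarea":
        subs = layout.subarea_of_ssmu
        labels = sorted(set(subs.values()))
        return [(lab, np.array([i for i, s in enumerate(ssmus) if subs[int(s)] == lab]))
                for lab in labels]
    if scale == "arena":
        return [("arena", np.arange(len(ssmus)))]
    raise ValidationError(f"unknown scale {scale!r} (predator scales: ssmu, subarea, arena)")


def _unit_groups(layout, scale: str) -> list[tuple[str, np.ndarray]]:
    if scale == "zone":
        return [(f"{s}:{z}", np.array([u]))
                for u, (s, z) in enumerate(zip(layout.ssmu_id, layout.zone))]
    groups = _ssmu_groups(layout, scale)
    parent = layout.parent_index
    return [(lab, np.flatnonzero(np.isin(parent, idx))) for lab, idx in groups]


def relative_abundance(mpa: EnsembleResult, ref: EnsembleResult,
                       scale: str = "ssmu") -> pd.DataFrame:
    """Final-year abundance ratio (MPA / No-MPA) per group at one scale.

    The ratio divides mean final-year abundances over all simulations
    (trials × parameterizations); ``std`` is the standard deviation of the
    per-simulation paired ratios.  Cells with a zero No-MPA mean are
    flagged (``defined = False``, ratio NaN).
    """
    if mpa.final_abundance.shape != ref.final_abundance.shape:
        raise ValidationError("ensembles are not paired (shape mismatch)")
    rows = []
    for lab, idx in _ssmu_groups(mpa.layout, scale):
        a = mpa.final_abundance[..., idx].sum(axis=-1)   # (n_par, n_trials, g)
        b = ref.final_abundance[..., idx].sum(axis=-1)
        for k, gname in enumerate(mpa.groups):
            denom = b[..., k].mean()
            defined = denom > 0
            ratio = a[..., k].mean() / denom if defined else np.nan
            with np.errstate(divide="ignore", invalid="ignore"):
                per_sim = np.where(b[..., k] > 0, a[..., k] / b[..., k], np.nan)
            std = float(np.nanstd(per_sim)) if defined else np.nan
            rows.append((gname, scale, lab, ratio, std, defined))
    return pd.DataFrame(rows, columns=["group", "scale", "unit", "ratio",
                                       "std", "defined"])


def total_catch(mpa: EnsembleResult, ref: EnsembleResult,
                scale: str = "arena") -> pd.DataFrame:
    """Final-year realized catch (tonnes) and its MPA / No-MPA ratio at one
    scale (zone, ssmu, subarea or arena)."""
    rows = []
    annual_mpa = mpa.final_catch.sum(axis=-1)   # (n_par, n_trials, n_units)
    annual_ref = ref.final_catch.sum(axis=-1)
    for lab, idx in _unit_groups(mpa.layout, scale):
        a = annual_mpa[..., idx].sum(axis=-1)
        b = annual_ref[..., idx].sum(axis=-1)
        denom = b.mean()
        defined = denom > 0
        ratio = a.mean() / denom if defined else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            per_sim = np.where(b > 0, a / b, np.nan)
        std = float(np.nanstd(per_sim)) if defined else np.nan
        rows.append((scale, lab, float(a.mean()), ratio, std, defined))
    return pd.DataFrame(rows, columns=["scale", "unit", "catch_tonnes",
                                       "ratio", "std", "defined"])


def violation_probability(ensemble: EnsembleResult,
                          mode: str = "any_area_per_season") -> float:
    """Probability of a threshold violation.

    Default mode: a violation is a season with at least one fished zone
    below threshold; the mean per-trial count is divided by the number of
    seasons in a run (60 for 30 years).  ``per_area_season`` normalizes the
    per-(zone, season) count by the number of fished zone-seasons.
    """
    if mode == "any_area_per_season":
        return float(ensemble.violations_any.mean() / ensemble.n_seasons)
    if mode == "per_area_season":
        denom = ensemble.fished_zone_seasons[:, None]
        if np.any(denom == 0):
            return 0.0
        return float((ensemble.violations_zone / denom).mean())
    raise ValidationError(f"unknown violation mode {mode!r}")


def foraging_protection_profile(results: list[ExperimentResult]
                                ) -> pd.DataFrame:
    """Scatter data relating summer foraging protection to outcomes.

    One row per (scenario, alternative, group, breeding SSMU): the summer
    foraging-inside percentage, the SSMU-scale final-year abundance ratio,
    and the SSMU's final-year catch — the profile used to ask whether
    predators decline when their foraging areas are insufficiently closed.
    """
    rows = []
    for res in results:
        summary = relative_abundance(res.mpa, res.no_mpa, scale="ssmu")
        catch = total_catch(res.mpa, res.no_mpa, scale="ssmu").set_index("unit")
        dec = res.decomposed[0]
        lay = dec.layout
        closed = lay.zone == "closed"
        for k, gname in enumerate(dec.groups):
            for i, ssmu in enumerate(lay.ssmus):
                if not dec.occupancy[k, i]:
                    continue
                pct = res.scenario.inside_percent(gname, int(ssmu), SUMMER)
                if pct is None:
                    pct = 100.0 * dec.foraging[SUMMER, k, i, closed].sum()
                cell = summary[(summary.group == gname)
                               & (summary.unit == str(int(ssmu)))]
                rows.append((res.scenario.name, res.alternative, gname, int(ssmu),
                             float(pct), float(cell.ratio.iloc[0]),
                             float(catch.loc[str(int(ssmu)), "catch_tonnes"])))
    return pd.DataFrame(rows, columns=["scenario", "alternative", "group", "ssmu",
                                       "foraging_inside_summer_pct",
                                       "abundance_ratio", "catch_tonnes"])
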