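"""Split each SSMU of a parameterization into open and closed zones.

An MPA scenario supplies, per SSMU, the fraction of area and of recent catch
lying inside the closure, and (optionally) telemetry-derived percentages of
each predator group's seasonal demand drawn from inside closures.  The five
spatially dependent parameter classes — initial krill biomass, maximum
recruitment, movement rates, catch history and foraging proportions — are
decomposed so that zone-level dynamics aggregate back to the SSMU-level
model exactly when no fishing is displaced.  Non-spatial parameters are
unchanged.

Krill quantities split area-proportionally by default, reflecting the
assumption of spatially random within-SSMU distributions of krill and
catches.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .params import (
    SUMMER, WINTER, SEASONS, Layout, ReferenceParameterization,
    ScenarioDefinition, ValidationError,
)

__all__ = [
    "split_scalar", "decomposed_layout", "decompose_foraging",
    "decompose_movement", "decompose_catch_history", "decompose_parameterization",
]


def split_scalar(value: float, closed_area_fraction: float) -> tuple[float, float]:
    """Split a nonnegative quantity into (open, closed) parts.

    The closed part is ``value × fraction``; open + closed equals ``value``
    exactly.
    """
    if not np.isfinite(value) or not np.isfinite(closed_area_fraction):
        raise ValidationError("split_scalar: inputs must be finite")
    if not (0.0 <= closed_area_fraction <= 1.0):
        raise ValidationError(
            f"closed fraction {closed_area_fraction} outside [0, 1]")
    closed = value * closed_area_fraction
    return value - closed, closed


def decomposed_layout(layout: Layout, scenario: ScenarioDefinition) -> Layout:
    """Zone-level layout implied by a scenario's closed area fractions.

    SSMUs with fraction 0 pass through as a single open zone; fraction 1
    yields a single closed zone; anything in between yields both.
    """
    if np.any(layout.zone != "whole"):
        raise ValidationError("decompose expects an undecomposed ('whole') layout")
    ssmu, zone, sub, area = [], [], [], []
    for k in range(layout.n_units):
        s = int(layout.ssmu_id[k])
        a_open, a_closed = split_scalar(float(layout.area[k]), scenario.area_fraction(s))
        for z, a in (("open", a_open), ("closed", a_closed)):
            if a > 0:
                ssmu.append(s)
                zone.append(z)
                sub.append(layout.subarea[k])
                area.append(a)
    return Layout(ssmu_id=np.array(ssmu), zone=np.array(zone, dtype=object),
                  subarea=np.array(sub, dtype=object), area=np.array(area))


def _split_per_unit(values: np.ndarray, layout: Layout, new: Layout,
                    fraction_of: dict) -> np.ndarray:
    """Split a per-'whole'-unit vector onto a decomposed layout using a
    per-SSMU closed fraction."""
    by_ssmu = {int(s): float(v) for s, v in zip(layout.ssmu_id, values)}
    out = np.zeros(new.n_units)
    for u in range(new.n_units):
        s = int(new.ssmu_id[u])
        op, cl = split_scalar(by_ssmu[s], fraction_of.get(s, 0.0))
        out[u] = cl if new.zone[u] == "closed" else op
    return out


def decompose_foraging(par: ReferenceParameterization, scenario: ScenarioDefinition,
                       new: Layout) -> np.ndarray:
    """Zone-level foraging proportions honouring the scenario's
    foraging-inside percentages.

    With ``scenario.foraging_inside is None`` the split is area-proportional:
    each foraged SSMU's contribution p_j divides between its zones by area
    share.  With a scalar inside-percentage f per (group, breeding SSMU,
    season), the closed mass f·Σp is distributed over closed zones in
    proportion to the original row restricted to SSMUs owning a closed zone,
    and the open mass (1−f)·Σp likewise over SSMUs owning an open zone; when
    every foraged SSMU has both zones this reduces to closed_j = f·p_j,
    open_j = (1−f)·p_j.
    """
    lay = par.layout
    m, g = lay.n_ssmu, par.n_groups
    p_new = np.zeros((2, g, m, new.n_units))
    occ = par.occupancy
    ssmus = list(lay.ssmus)
    # per-new-unit parent position in the old (whole) layout
    old_pos = {int(s): k for k, s in enumerate(lay.ssmu_id)}

    open_units = {int(s): None for s in lay.ssmu_id}
    closed_units = dict(open_units)
    for u in range(new.n_units):
        s = int(new.ssmu_id[u])
        if new.zone[u] == "closed":
            closed_units[s] = u
        else:
            open_units[s] = u

    for s in (SUMMER, WINTER):
        for k in range(g):
            for i, breed_ssmu in enumerate(ssmus):
                if not occ[k, i]:
                    continue
                row = par.foraging[s, k, i]
                f_pct = scenario.inside_percent(par.groups[k], breed_ssmu, s)
                if f_pct is None:
                    # area-proportional default
                    for j_ssmu, p_j in zip(lay.ssmu_id, row):
                        j_ssmu = int(j_ssmu)
                        if p_j == 0:
                            continue
                        op, cl = split_scalar(p_j, scenario.area_fraction(j_ssmu))
                        if cl > 0:
                            p_new[s, k, i, closed_units[j_ssmu]] = cl
                        if op > 0 or cl == 0:
                            p_new[s, k, i, open_units[j_ssmu]] = op
                    continue
                f = f_pct / 100.0
                has_closed = np.array([closed_units[int(j)] is not None for j in lay.ssmu_id])
                has_open = np.array([open_units[int(j)] is not None for j in lay.ssmu_id])
                p_closed_reach = float(row[has_closed].sum())
                p_open_reach = float(row[has_open].sum())
                if f > 0 and p_closed_reach <= 0:
                    raise ValidationError(
                        f"({par.groups[k]}, SSMU {breed_ssmu}, {SEASONS[s]}): inside "
                        f"percentage {f_pct} infeasible — no foraged SSMU has a closed zone"
                    )
                if f < 1 and p_open_reach <= 0:
                    raise ValidationError(
                        f"({par.groups[k]}, SSMU {breed_ssmu}, {SEASONS[s]}): outside "
                        f"percentage {100 - f_pct} infeasible — no foraged SSMU has an open zone"
                    )
                total = float(row.sum())
                for j_pos, j_ssmu in enumerate(lay.ssmu_id):
                    j_ssmu = int(j_ssmu)
                    p_j = row[j_pos]
                    if p_j == 0:
                        continue
                    if closed_units[j_ssmu] is not None and f > 0:
                        p_new[s, k, i, closed_units[j_ssmu]] += total * f * p_j / p_closed_reach
                    if open_units[j_ssmu] is not None and f < 1:
                        p_new[s, k, i, open_units[j_ssmu]] += total * (1 - f) * p_j / p_open_reach
    return p_new


def decompose_movement(par: ReferenceParameterization, scenario: ScenarioDefinition,
                       new: Layout, internal_exchange_rate: float | None = None
                       ) -> np.ndarray:
    """Zone-level instantaneous movement rates.

    Between distinct SSMUs the parent rate is carried by every source zone
    and the inflow splits across destination zones by area share, which
    preserves parent-to-parent flow for any within-SSMU biomass
    distribution.  Under the drift hypothesis an open↔closed exchange is
    added within each split SSMU so each zone's long-run biomass share tends
    to its area share; its magnitude defaults to the SSMU's largest seasonal
    outflow rate (``internal_exchange_rate`` overrides).  Under the
    no-movement hypothesis all rates stay zero.
    """
    if np.any(par.movement < 0):
        raise ValidationError("movement rates must be nonnegative")
    n_new = new.n_units
    v_new = np.zeros((2, n_new, n_new))
    if par.movement_mode == "none":
        return v_new
    lay = par.layout
    pos_of = {int(s): k for k, s in enumerate(lay.ssmu_id)}
    share = new.area_share
    for s in (SUMMER, WINTER):
        for a in range(n_new):
            ia = pos_of[int(new.ssmu_id[a])]
            for b in range(n_new):
                if new.ssmu_id[a] == new.ssmu_id[b]:
                    continue
                jb = pos_of[int(new.ssmu_id[b])]
                v_new[s, a, b] = par.movement[s, ia, jb] * share[b]
        # internal open<->closed exchange per split SSMU
        for ssmu in lay.ssmus:
            units = np.flatnonzero(new.ssmu_id == ssmu)
            if len(units) != 2:
                continue
            r = internal_exchange_rate
            if r is None:
                r = float(par.movement[s, pos_of[int(ssmu)]].max())
            for a in units:
                for b in units:
                    if a != b:
                        v_new[s, a, b] = r * share[b]
    return v_new


def decompose_catch_history(par: ReferenceParameterization,
                            scenario: ScenarioDefinition, new: Layout
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Split annual catch proportions by the closed *catch* fraction; the
    seasonal split of each zone is inherited from its parent SSMU."""
    lay = par.layout
    annual_by_ssmu = {int(s): float(v) for s, v in zip(lay.ssmu_id, par.catch_annual)}
    for s in lay.ssmus:
        if scenario.catch_fraction(s) > 0 and scenario.area_fraction(s) == 0:
            raise ValidationError(
                f"SSMU {s}: closed_catch_fraction > 0 but closed_area_fraction is 0")
        if (scenario.area_fraction(s) == 1.0 and scenario.catch_fraction(s) < 1.0
                and annual_by_ssmu[int(s)] > 0):
            raise ValidationError(
                f"SSMU {s}: fully closed but closed_catch_fraction < 1 leaves catch "
                "with no open zone to sit in")
    annual = _split_per_unit(par.catch_annual, lay, new, scenario.closed_catch_fraction)
    seasonal_by_ssmu = {int(s): par.catch_seasonal[k]
                        for k, s in enumerate(lay.ssmu_id)}
    seasonal = np.array([seasonal_by_ssmu[int(s)] for s in new.ssmu_id])
    return annual, seasonal


def decompose_parameterization(par: ReferenceParameterization,
                               scenario: ScenarioDefinition,
                               internal_exchange_rate: float | None = None
                               ) -> ReferenceParameterization:
    """Apply the full decomposition, returning a zone-level
    parameterization on the scenario's open/closed layout.

    SSMUs with closed fraction 0 pass through as a single open zone; a
    No-MPA scenario returns a structurally equivalent copy (zones relabelled
    'open').  Non-spatial parameters are unchanged.
    """
    par.validate()
    scenario.validate(par)
    new = decomposed_layout(par.layout, scenario)
    caf = scenario.closed_area_fraction
    krill_init = _split_per_unit(par.krill_init, par.layout, new, caf)
    max_rec = _split_per_unit(par.max_recruitment, par.layout, new, caf)
    annual, seasonal = decompose_catch_history(par, scenario, new)
    foraging = decompose_foraging(par, scenario, new)
    movement = decompose_movement(par, scenario, new, internal_exchange_rate)
    out = dataclasses.replace(
        par, layout=new, krill_init=krill_init, max_recruitment=max_rec,
        movement=movement, foraging=foraging, catch_annual=annual,
        catch_seasonal=seasonal,
    )
    return out.validate()
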