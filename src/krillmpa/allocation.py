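"""Catch limit, baseline spatio-seasonal allocation, displaced catch, and
its redistribution under the Regional, Local and Current alternatives.

The overall catch limit is initial arena krill biomass × the regional
harvest rate (0.093 by default).  The baseline allocation spreads the limit
over zone-units by the 2009–2017 annual catch distribution and each unit's
seasonal split.  A scenario displaces, from each SSMU, the share of its
allocation historically taken inside the closure; the three alternatives
reallocate that tonnage to open zones:

* ``regional`` — within the originating statistical subarea, in proportion
  to the open zones' baseline shares;
* ``local`` — entirely to the open zone of the originating SSMU ("fishing
  the line");
* ``current`` — pooled, then across all open zones of the arena in
  proportion to the 2009–2017 distribution restricted to open zones.

Redistributed tonnage is split seasonally by the receiving unit's recent
seasonal catch pattern.  Closed zones carry zero tonnage after
redistribution and the overall limit is conserved.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    SUMMER, WINTER, Layout, ReferenceParameterization, ScenarioDefinition,
    ValidationError,
)

__all__ = [
    "AllocationError", "CatchAllocation", "overall_catch_limit",
    "baseline_allocation", "displaced_catch", "redistribute",
]


class AllocationError(ValueError):
    """A redistribution has an empty or degenerate receiving set."""


@dataclass
class CatchAllocation:
    """Tonnage per (zone-unit, season) plus provenance."""

    layout: Layout
    tonnage: np.ndarray  # (n_units, 2)
    total_limit: float
    provenance: str = "baseline"

    def __post_init__(self):
        self.tonnage = np.asarray(self.tonnage, dtype=float)
        if self.tonnage.shape != (self.layout.n_units, 2):
            raise ValidationError(
                f"tonnage shape {self.tonnage.shape} != ({self.layout.n_units}, 2)")
        if np.any(self.tonnage < 0):
            raise ValidationError("allocation tonnage must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.tonnage.sum())

    def annual_by_unit(self) -> np.ndarray:
        return self.tonnage.sum(axis=1)

    def annual_by_ssmu(self) -> np.ndarray:
        """(n_ssmu,) annual tonnage aggregated over each SSMU's zones."""
        return self.layout.aggregation_matrix @ self.annual_by_unit()


def overall_catch_limit(initial_krill_biomass_total: float,
                        harvest_rate: float) -> float:
    """Overall limit = initial arena krill biomass × harvest rate, tonnes."""
    if initial_krill_biomass_total < 0:
        raise ValidationError("initial biomass must be nonnegative")
    if harvest_rate < 0:
        raise ValidationError("harvest rate must be nonnegative")
    return initial_krill_biomass_total * harvest_rate


def baseline_allocation(limit: float, par: ReferenceParameterization,
                        atol: float = 1e-9) -> CatchAllocation:
    """Spread the overall limit over (unit, season) by the recent catch
    distribution: tonnage = limit × annual(unit) × seasonal(unit, season)."""
    if limit < 0:
        raise ValidationError("catch limit must be nonnegative")
    if abs(par.catch_annual.sum() - 1.0) > atol:
        raise ValidationError(
            f"annual catch proportions sum to {par.catch_annual.sum():.6g}, expected 1")
    rows = par.catch_seasonal.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > atol):
        raise ValidationError("seasonal catch splits must each sum to 1")
    tonnage = limit * par.catch_annual[:, None] * par.catch_seasonal
    return CatchAllocation(layout=par.layout, tonnage=tonnage,
                           total_limit=limit, provenance="baseline")


def displaced_catch(baseline: CatchAllocation,
                    scenario: ScenarioDefinition) -> dict:
    """Tonnes displaced per SSMU: the SSMU's annual allocation times the
    share of its recent catch lying inside the closure."""
    lay = baseline.layout
    per_ssmu = baseline.annual_by_ssmu()
    out = {}
    for i, s in enumerate(lay.ssmus):
        frac = scenario.catch_fraction(s)
        if not (0.0 <= frac <= 1.0):
            raise ValidationError(f"closed_catch_fraction[{s}] = {frac} outside [0, 1]")
        out[int(s)] = float(per_ssmu[i] * frac)
    return out


def _seasonal_split(layout: Layout, par: ReferenceParameterization,
                    annual_extra: np.ndarray) -> np.ndarray:
    """Split per-unit annual tonnage by each receiving unit's seasonal
    pattern of recent catches."""
    return annual_extra[:, None] * par.catch_seasonal


def redistribute(displaced: dict, baseline: CatchAllocation,
                 alternative: str, par: ReferenceParameterization,
                 regional_weighting: str = "baseline") -> CatchAllocation:
    """Reallocate displaced tonnage to open zones under one alternative.

    The result starts from the baseline with closed-zone tonnage removed
    (that tonnage *is* the displaced catch), adds the redistributed annual
    amounts to open zones, and splits additions seasonally by the receiving
    unit's seasonal distribution.  Conserves the overall limit to
    round-off.
    """
    lay = baseline.layout
    if alternative not in ScenarioDefinition.REDISTRIBUTIONS:
        raise ValidationError(
            f"unknown redistribution alternative {alternative!r}")
    if regional_weighting not in ("baseline", "area"):
        raise ValidationError("regional_weighting must be 'baseline' or 'area'")

    open_mask = lay.zone != "closed"  # 'whole' units are open to fishing
    annual_unit = baseline.annual_by_unit()
    annual_extra = np.zeros(lay.n_units)

    def receiver_weights(unit_idx: np.ndarray, label: str) -> np.ndarray:
        if len(unit_idx) == 0:
            raise AllocationError(f"no open zone available {label}")
        if alternative == "current" or regional_weighting == "baseline":
            w = annual_unit[unit_idx]
        else:
            w = lay.area[unit_idx]
        if w.sum() <= 0 and alternative == "regional":
            # a subarea whose recent catch lies wholly inside closures
            # still receives: spread by area instead
            w = lay.area[unit_idx]
        tot = w.sum()
        if tot <= 0:
            raise AllocationError(
                f"receiving open zones {label} all carry zero weight")
        return w / tot

    if alternative == "local":
        for ssmu, amount in displaced.items():
            if amount == 0:
                continue
            units = np.flatnonzero((lay.ssmu_id == ssmu) & open_mask)
            if len(units) == 0:
                raise AllocationError(
                    f"Local redistribution impossible: SSMU {ssmu} is fully closed")
            # one open zone per SSMU by construction
            annual_extra[units[0]] += amount
    elif alternative == "regional":
        sub_of = lay.subarea_of_ssmu
        for ssmu, amount in displaced.items():
            if amount == 0:
                continue
            sub = sub_of[int(ssmu)]
            units = np.flatnonzero((lay.subarea == sub) & open_mask)
            w = receiver_weights(units, f"in subarea {sub}")
            annual_extra[units] += amount * w
    else:  # current
        pooled = float(sum(displaced.values()))
        if pooled > 0:
            units = np.flatnonzero(open_mask)
            w = receiver_weights(units, "in the arena")
            annual_extra[units] += pooled * w

    tonnage = baseline.tonnage.copy()
    tonnage[~open_mask] = 0.0
    tonnage += _seasonal_split(lay, par, annual_extra)
    return CatchAllocation(layout=lay, tonnage=tonnage,
                           total_limit=baseline.total_limit,
                           provenance="redistributed")
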