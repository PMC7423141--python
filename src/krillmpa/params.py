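"""Domain types, validation and tabular I/O for model parameterizations.

The spatial arena is a set of small-scale management units (SSMUs) grouped
into statistical subareas.  A *layout* lists the zone-units actually carried
by the model: one ``whole`` unit per SSMU for an undecomposed
parameterization, or an ``open`` and/or ``closed`` zone per SSMU once an MPA
scenario has been superimposed.

Quantities are stored in field-standard units: krill biomass in tonnes,
areas in m², densities in g·m⁻² (1 t = 10⁶ g), movement as instantaneous
rates per season, predator demand in tonnes of krill per animal per season.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

SUMMER, WINTER = 0, 1
SEASONS = ("summer", "winter")
ZONES = ("whole", "open", "closed")
_ZONE_ORDER = {z: k for k, z in enumerate(ZONES)}

DEFAULT_GROUPS = ("penguins", "seals", "whales", "fish")

#: Fixed subarea membership of the 15-SSMU Scotia Sea arena.
SUBAREA_OF_SSMU = {
    **{i: "48.1" for i in range(1, 9)},
    **{i: "48.2" for i in range(9, 13)},
    **{i: "48.3" for i in range(13, 16)},
}

MOVEMENT_MODES = ("none", "drift")
RESPONSE_MODES = ("hyperstable", "linear")

GRAMS_PER_TONNE = 1.0e6


class ValidationError(ValueError):
    """A parameterization, scenario or table violates a stated invariant."""


def season_index(season) -> int:
    """Accept 0/1 or 'summer'/'winter' and return the season index."""
    if season in (SUMMER, WINTER):
        return int(season)
    try:
        return SEASONS.index(season)
    except ValueError:
        raise ValidationError(f"unknown season {season!r}; expected one of {SEASONS}")


# ---------------------------------------------------------------------------
# Spatial layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Layout:
    """The zone-units of the arena, each tied to a parent SSMU.

    Attributes
    ----------
    ssmu_id : (n_units,) int array — parent SSMU of each zone-unit.
    zone : (n_units,) str array — 'whole', 'open' or 'closed'.
    subarea : (n_units,) str array — statistical subarea label.
    area : (n_units,) float array — surface in m².
    """

    ssmu_id: np.ndarray
    zone: np.ndarray
    subarea: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        for name in ("ssmu_id", "zone", "subarea", "area"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.ssmu_id) == len(self.zone) == len(self.subarea) == len(self.area)):
            raise ValidationError("layout arrays must have equal length")
        if np.any(self.area <= 0):
            bad = self.ssmu_id[self.area <= 0]
            raise ValidationError(f"unit area must be > 0 (SSMU {bad.tolist()})")
        seen = set()
        for s, z in zip(self.ssmu_id, self.zone):
            if z not in ZONES:
                raise ValidationError(f"unknown zone label {z!r}")
            if (int(s), str(z)) in seen:
                raise ValidationError(f"duplicate unit (SSMU {s}, zone {z})")
            seen.add((int(s), str(z)))
        for s in np.unique(self.ssmu_id):
            zones = set(self.zone[self.ssmu_id == s])
            if "whole" in zones and len(zones) > 1:
                raise ValidationError(f"SSMU {s}: 'whole' cannot coexist with open/closed zones")
        # Fixed subarea membership of the standard 15-SSMU arena.
        if len(np.unique(self.ssmu_id)) == 15 and set(np.unique(self.ssmu_id)) == set(range(1, 16)):
            for s, sub in zip(self.ssmu_id, self.subarea):
                if SUBAREA_OF_SSMU[int(s)] != str(sub):
                    raise ValidationError(
                        f"SSMU {s} must lie in subarea {SUBAREA_OF_SSMU[int(s)]}, got {sub}"
                    )

    # -- sizes and indices -------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.ssmu_id)

    @property
    def ssmus(self) -> np.ndarray:
        """Sorted parent SSMU ids."""
        return np.unique(self.ssmu_id)

    @property
    def n_ssmu(self) -> int:
        return len(self.ssmus)

    @property
    def parent_index(self) -> np.ndarray:
        """(n_units,) position of each unit's parent in :attr:`ssmus`."""
        pos = {s: k for k, s in enumerate(self.ssmus)}
        return np.array([pos[int(s)] for s in self.ssmu_id])

    @property
    def aggregation_matrix(self) -> np.ndarray:
        """(n_ssmu, n_units) 0/1 matrix summing zone-units to SSMUs."""
        P = np.zeros((self.n_ssmu, self.n_units))
        P[self.parent_index, np.arange(self.n_units)] = 1.0
        return P

    @property
    def parent_area(self) -> np.ndarray:
        """(n_ssmu,) total area of each parent SSMU."""
        return self.aggregation_matrix @ self.area

    @property
    def area_share(self) -> np.ndarray:
        """(n_units,) each unit's share of its parent SSMU's area."""
        return self.area / self.parent_area[self.parent_index]

    @property
    def subarea_of_ssmu(self) -> dict:
        return {int(s): str(self.subarea[self.ssmu_id == s][0]) for s in self.ssmus}

    def units_of(self, ssmu: int, zone: str | None = None) -> np.ndarray:
        """Indices of the zone-units of one SSMU (optionally one zone)."""
        mask = self.ssmu_id == ssmu
        if zone is not None:
            mask &= self.zone == zone
        return np.flatnonzero(mask)

    def unit_labels(self) -> list[str]:
        return [f"{s}:{z}" for s, z in zip(self.ssmu_id, self.zone)]

    def aggregate(self, values: np.ndarray, axis: int = -1) -> np.ndarray:
        """Sum a per-unit axis up to the parent-SSMU level."""
        values = np.asarray(values)
        return np.apply_along_axis(lambda v: self.aggregation_matrix @ v, axis, values)

    @classmethod
    def whole(cls, ssmu_ids, areas, subareas: Mapping[int, str] | None = None) -> "Layout":
        """Build an undecomposed layout (one 'whole' unit per SSMU)."""
        ssmu_ids = np.asarray(ssmu_ids, dtype=int)
        if subareas is None:
            try:
                subs = [SUBAREA_OF_SSMU[int(s)] for s in ssmu_ids]
            except KeyError as exc:
                raise ValidationError(
                    f"SSMU {exc.args[0]} has no standard subarea; pass `subareas`"
                ) from None
        else:
            subs = [subareas[int(s)] for s in ssmu_ids]
        order = np.argsort(ssmu_ids)
        return cls(
            ssmu_id=ssmu_ids[order],
            zone=np.array(["whole"] * len(ssmu_ids)),
            subarea=np.array(subs, dtype=object)[order],
            area=np.asarray(areas, dtype=float)[order],
        )


# ---------------------------------------------------------------------------
# Reference parameterization
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentNoise:
    """Multiplicative, mean-1 recruitment deviates.

    ``lognormal`` draws exp(N(−σ²/2, σ²)) with σ = ``dispersion``;
    dispersion 0 yields the deterministic model.
    """

    family: str = "lognormal"
    dispersion: float = 0.0

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.dispersion < 0:
            raise ValidationError("recruitment dispersion must be >= 0")
        if self.dispersion == 0:
            return np.ones(size)
        if self.family == "lognormal":
            s = self.dispersion
            return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)
        raise ValidationError(f"unknown recruitment noise family {self.family!r}")


@dataclass
class ReferenceParameterization:
    """All spatial and biological parameters for one model hypothesis.

    Zone-unit axes have length ``layout.n_units``; breeding axes have length
    ``layout.n_ssmu`` (predators breed in an SSMU, not in a zone).

    Fields
    ------
    movement_mode : 'none' (krill stay put) or 'drift' (passive drifters).
    response_mode : 'hyperstable' or 'linear' breeder response to krill.
    krill_init : (n_units,) initial krill biomass, tonnes.
    max_recruitment : (n_units,) maximum annual krill recruitment, tonnes.
    movement : (2, n_units, n_units) instantaneous rates v[s, i, j] from
        unit i to unit j per season; diagonal zero.
    groups : predator group labels.
    predator_init : (n_groups, n_ssmu) initial abundance by breeding SSMU.
    foraging : (2, n_groups, n_ssmu, n_units) proportions p[s, k, i, j] of
        group k's demand (breeding in SSMU i) drawn from unit j in season s;
        each occupied row sums to 1, unoccupied rows are all zero.
    demand_per_capita : (n_groups, 2) tonnes krill per animal per season.
    krill_mortality : (2,) instantaneous natural mortality per season.
    predator_mortality : (n_groups,) instantaneous annual natural mortality.
    catch_annual : (n_units,) 2009–2017 proportional catch distribution,
        summing to 1 over the arena.
    catch_seasonal : (n_units, 2) per-unit summer/winter split, rows sum 1.
    recruitment_noise : multiplicative deviate spec for krill recruitment.
    hyperstability_shape : h in φ(x) = x(1+h)/(x+h) (hyperstable response).
    """

    movement_mode: str
    response_mode: str
    layout: Layout
    krill_init: np.ndarray
    max_recruitment: np.ndarray
    movement: np.ndarray
    groups: tuple
    predator_init: np.ndarray
    foraging: np.ndarray
    demand_per_capita: np.ndarray
    krill_mortality: np.ndarray
    predator_mortality: np.ndarray
    catch_annual: np.ndarray
    catch_seasonal: np.ndarray
    recruitment_noise: RecruitmentNoise = field(default_factory=RecruitmentNoise)
    hyperstability_shape: float = 0.2

    def __post_init__(self):
        self.groups = tuple(self.groups)
        for name in ("krill_init", "max_recruitment", "movement", "predator_init",
                     "foraging", "demand_per_capita", "krill_mortality",
                     "predator_mortality", "catch_annual", "catch_seasonal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    # -- derived quantities ------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.layout.n_units

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def krill_density_init(self) -> np.ndarray:
        """Initial krill density, g·m⁻²."""
        return self.krill_init * GRAMS_PER_TONNE / self.layout.area

    @property
    def occupancy(self) -> np.ndarray:
        """(n_groups, n_ssmu) bool — where each group breeds."""
        return self.predator_init > 0

    def group_index(self, group: str) -> int:
        try:
            return self.groups.index(group)
        except ValueError:
            raise ValidationError(f"unknown predator group {group!r}") from None

    # -- validation --------------------------------------------------------
    def validate(self, atol: float = 1e-9) -> "ReferenceParameterization":
        lay = self.layout
        n, m, g = lay.n_units, lay.n_ssmu, self.n_groups
        shapes = {
            "krill_init": (n,), "max_recruitment": (n,),
            "movement": (2, n, n), "predator_init": (g, m),
            "foraging": (2, g, m, n), "demand_per_capita": (g, 2),
            "krill_mortality": (2,), "predator_mortality": (g,),
            "catch_annual": (n,), "catch_seasonal": (n, 2),
        }
        for name, want in shapes.items():
            got = getattr(self, name).shape
            if got != want:
                raise ValidationError(f"{name}: expected shape {want}, got {got}")
        if self.movement_mode not in MOVEMENT_MODES:
            raise ValidationError(f"movement_mode must be one of {MOVEMENT_MODES}")
        if self.response_mode not in RESPONSE_MODES:
            raise ValidationError(f"response_mode must be one of {RESPONSE_MODES}")
        for name in ("krill_init", "max_recruitment", "movement", "predator_init",
                     "foraging", "demand_per_capita", "krill_mortality",
                     "predator_mortality", "catch_annual", "catch_seasonal"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"{name}: non-finite entry")
            if np.any(a < 0):
                raise ValidationError(f"{name}: negative entry")
        if self.hyperstability_shape <= 0:
            raise ValidationError("hyperstability_shape must be > 0")
        if np.any(np.diagonal(self.movement, axis1=1, axis2=2) != 0):
            raise ValidationError("movement: diagonal (self-transfer) rates must be 0")
        if self.movement_mode == "none" and np.any(self.movement != 0):
            raise ValidationError("movement_mode 'none' requires all rates to be 0")
        occ = self.occupancy
        for s in (SUMMER, WINTER):
            for k in range(g):
                for i in range(m):
                    row = self.foraging[s, k, i]
                    if occ[k, i]:
                        if abs(row.sum() - 1.0) > atol:
                            raise ValidationError(
                                f"foraging row ({self.groups[k]}, SSMU {lay.ssmus[i]}, "
                                f"{SEASONS[s]}) sums to {row.sum():.6g}, expected 1"
                            )
                    elif row.any():
                        raise ValidationError(
                            f"foraging row present for unoccupied ({self.groups[k]}, "
                            f"SSMU {lay.ssmus[i]}, {SEASONS[s]})"
                        )
        if abs(self.catch_annual.sum() - 1.0) > atol:
            raise ValidationError(
                f"annual catch proportions sum to {self.catch_annual.sum():.6g}, expected 1"
            )
        rows = self.catch_seasonal.sum(axis=1)
        bad = np.flatnonzero(np.abs(rows - 1.0) > atol)
        if bad.size:
            u = bad[0]
            raise ValidationError(
                f"seasonal catch split for unit (SSMU {lay.ssmu_id[u]}, {lay.zone[u]}) "
                f"sums to {rows[u]:.6g}, expected 1"
            )
        return self

    def total_krill_init(self) -> float:
        return float(self.krill_init.sum())

    def copy(self) -> "ReferenceParameterization":
        new = dataclasses.replace(self)
        for name in ("krill_init", "max_recruitment", "movement", "predator_init",
                     "foraging", "demand_per_capita", "krill_mortality",
                     "predator_mortality", "catch_annual", "catch_seasonal"):
            setattr(new, name, getattr(self, name).copy())
        new.recruitment_noise = dataclasses.replace(self.recruitment_noise)
        return new


# ---------------------------------------------------------------------------
# Scenario and run configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioDefinition:
    """An MPA as per-SSMU closed fractions plus foraging-inside percentages.

    ``foraging_inside`` maps (group, ssmu_id, season label) to the
    percentage (0–100) of the group's seasonal krill demand drawn from
    inside the closed areas; ``None`` selects the area-proportional default
    split.  ``closed_catch_fraction`` is the share of the 2009–2017 catch of
    each SSMU taken inside the closure.
    """

    name: str
    closed_area_fraction: dict
    closed_catch_fraction: dict
    foraging_inside: dict | None = None
    redistribution: str = "regional"

    REDISTRIBUTIONS = ("regional", "local", "current")

    def __post_init__(self):
        self.closed_area_fraction = {int(k): float(v) for k, v in self.closed_area_fraction.items()}
        self.closed_catch_fraction = {int(k): float(v) for k, v in self.closed_catch_fraction.items()}
        if self.foraging_inside is not None:
            self.foraging_inside = {
                (str(g), int(s), SEASONS[season_index(se)]): float(v)
                for (g, s, se), v in self.foraging_inside.items()
            }

    def validate(self, par: ReferenceParameterization | None = None) -> "ScenarioDefinition":
        if self.redistribution not in self.REDISTRIBUTIONS:
            raise ValidationError(
                f"redistribution must be one of {self.REDISTRIBUTIONS}, got {self.redistribution!r}"
            )
        for label, d in (("closed_area_fraction", self.closed_area_fraction),
                         ("closed_catch_fraction", self.closed_catch_fraction)):
            for s, v in d.items():
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(f"{label}[{s}] = {v} outside [0, 1]")
        if self.foraging_inside is not None:
            for (g, s, se), v in self.foraging_inside.items():
                if not (0.0 <= v <= 100.0):
                    raise ValidationError(
                        f"foraging_inside[({g}, {s}, {se})] = {v} outside [0, 100]"
                    )
        if par is not None:
            occ = par.occupancy
            ssmus = list(par.layout.ssmus)
            if self.foraging_inside is not None:
                for (g, s, se) in self.foraging_inside:
                    if s not in ssmus:
                        raise ValidationError(f"foraging_inside names unknown SSMU {s}")
                    k = par.group_index(g)
                    if not occ[k, ssmus.index(s)]:
                        raise ValidationError(
                            f"foraging_inside given for ({g}, SSMU {s}) but the group "
                            "does not breed there"
                        )
        return self

    def area_fraction(self, ssmu: int) -> float:
        return self.closed_area_fraction.get(int(ssmu), 0.0)

    def catch_fraction(self, ssmu: int) -> float:
        return self.closed_catch_fraction.get(int(ssmu), 0.0)

    def inside_percent(self, group: str, ssmu: int, season) -> float | None:
        if self.foraging_inside is None:
            return None
        return self.foraging_inside.get((group, int(ssmu), SEASONS[season_index(season)]))

    @property
    def is_no_mpa(self) -> bool:
        return all(v == 0.0 for v in self.closed_catch_fraction.values()) and all(
            v == 0.0 for v in self.closed_area_fraction.values()
        )

    @classmethod
    def no_mpa(cls, ssmu_ids) -> "ScenarioDefinition":
        """The No-MPA reference: nothing closed, nothing displaced."""
        z = {int(s): 0.0 for s in ssmu_ids}
        return cls(name="NoMPA", closed_area_fraction=dict(z),
                   closed_catch_fraction=dict(z), foraging_inside=None)


#: The four reference parameterizations of the study design.
DEFAULT_PARAMETERIZATIONS = (
    ("none", "hyperstable"),
    ("none", "linear"),
    ("drift", "hyperstable"),
    ("drift", "linear"),
)


@dataclass
class RunConfig:
    """Monte Carlo experiment configuration (study-design defaults)."""

    n_trials: int = 1001
    n_years: int = 30
    harvest_rate: float = 0.093
    density_threshold: float = 15.0  # g·m⁻²
    seed: int = 0
    parameterizations: tuple = DEFAULT_PARAMETERIZATIONS

    def validate(self) -> "RunConfig":
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.n_years < 1:
            raise ValidationError("n_years must be >= 1")
        if not (0.0 < self.harvest_rate < 1.0):
            raise ValidationError("harvest_rate must lie in (0, 1)")
        if self.density_threshold <= 0:
            raise ValidationError("density_threshold must be > 0")
        return self


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_FILES = {
    "units": "units.csv",
    "krill": "krill.csv",
    "movement": "movement.csv",
    "predators": "predators.csv",
    "foraging": "foraging.csv",
    "demand": "demand.csv",
    "mortality": "mortality.csv",
    "catch": "catch_history.csv",
    "meta": "meta.yaml",
}


def write_parameterization(par: ReferenceParameterization, directory) -> Path:
    """Write one parameterization as a directory of delimited tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lay = par.layout
    pd.DataFrame({
        "ssmu_id": lay.ssmu_id, "zone": lay.zone,
        "subarea": lay.subarea, "area_m2": lay.area,
    }).to_csv(directory / _FILES["units"], index=False)
    pd.DataFrame({
        "ssmu_id": lay.ssmu_id, "zone": lay.zone,
        "initial_biomass_tonnes": par.krill_init,
        "initial_density_g_m2": par.krill_density_init,
        "max_recruitment_tonnes": par.max_recruitment,
    }).to_csv(directory / _FILES["krill"], index=False)
    rows = []
    for s in (SUMMER, WINTER):
        for i in range(lay.n_units):
            for j in range(lay.n_units):
                if par.movement[s, i, j] != 0:
                    rows.append((SEASONS[s], lay.ssmu_id[i], lay.zone[i],
                                 lay.ssmu_id[j], lay.zone[j], par.movement[s, i, j]))
    pd.DataFrame(rows, columns=["season", "from_ssmu", "from_zone",
                                "to_ssmu", "to_zone", "rate"]
                 ).to_csv(directory / _FILES["movement"], index=False)
    rows = []
    for k, gname in enumerate(par.groups):
        for i, ssmu in enumerate(lay.ssmus):
            if par.predator_init[k, i] > 0:
                rows.append((gname, int(ssmu), par.predator_init[k, i]))
    pd.DataFrame(rows, columns=["group", "breeding_ssmu", "initial_abundance"]
                 ).to_csv(directory / _FILES["predators"], index=False)
    rows = []
    for s in (SUMMER, WINTER):
        for k, gname in enumerate(par.groups):
            for i, ssmu in enumerate(lay.ssmus):
                for j in range(lay.n_units):
                    pv = par.foraging[s, k, i, j]
                    if pv != 0:
                        rows.append((gname, int(ssmu), SEASONS[s],
                                     lay.ssmu_id[j], lay.zone[j], pv))
    pd.DataFrame(rows, columns=["group", "breeding_ssmu", "season",
                                "foraging_ssmu", "foraging_zone", "proportion"]
                 ).to_csv(directory / _FILES["foraging"], index=False)
    rows = [(g, SEASONS[s], par.demand_per_capita[k, s])
            for k, g in enumerate(par.groups) for s in (SUMMER, WINTER)]
    pd.DataFrame(rows, columns=["group", "season", "tonnes_per_capita"]
                 ).to_csv(directory / _FILES["demand"], index=False)
    rows = [("krill", SEASONS[s], par.krill_mortality[s]) for s in (SUMMER, WINTER)]
    rows += [(g, "annual", par.predator_mortality[k]) for k, g in enumerate(par.groups)]
    pd.DataFrame(rows, columns=["component", "season", "rate"]
                 ).to_csv(directory / _FILES["mortality"], index=False)
    pd.DataFrame({
        "ssmu_id": lay.ssmu_id, "zone": lay.zone,
        "annual_proportion": par.catch_annual,
        "summer_fraction": par.catch_seasonal[:, SUMMER],
        "winter_fraction": par.catch_seasonal[:, WINTER],
    }).to_csv(directory / _FILES["catch"], index=False)
    meta = {
        "movement_mode": par.movement_mode,
        "response_mode": par.response_mode,
        "groups": list(par.groups),
        "recruitment_noise": {"family": par.recruitment_noise.family,
                              "dispersion": float(par.recruitment_noise.dispersion)},
        "hyperstability_shape": float(par.hyperstability_shape),
    }
    (directory / _FILES["meta"]).write_text(yaml.safe_dump(meta, sort_keys=False))
    return directory


def _require_columns(df: pd.DataFrame, cols, fname: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{fname}: missing column(s) {missing}")


def read_parameterization(directory, atol: float = 1e-9) -> ReferenceParameterization:
    """Read and validate a parameterization written by
    :func:`write_parameterization`."""
    directory = Path(directory)
    for f in _FILES.values():
        if not (directory / f).exists():
            raise ValidationError(f"missing parameter file {f} in {directory}")

    units = pd.read_csv(directory / _FILES["units"])
    _require_columns(units, ["ssmu_id", "zone", "subarea", "area_m2"], _FILES["units"])
    units = units.sort_values(["ssmu_id", "zone"],
                              key=lambda c: c.map(_ZONE_ORDER) if c.name == "zone" else c)
    layout = Layout(
        ssmu_id=units["ssmu_id"].to_numpy(int),
        zone=units["zone"].to_numpy(object),
        subarea=units["subarea"].astype(str).to_numpy(object),
        area=units["area_m2"].to_numpy(float),
    )
    uidx = {(int(s), str(z)): k for k, (s, z) in enumerate(zip(layout.ssmu_id, layout.zone))}
    sidx = {int(s): k for k, s in enumerate(layout.ssmus)}

    meta = yaml.safe_load((directory / _FILES["meta"]).read_text())
    groups = tuple(meta["groups"])
    gidx = {g: k for k, g in enumerate(groups)}
    n, m, g = layout.n_units, layout.n_ssmu, len(groups)

    krill = pd.read_csv(directory / _FILES["krill"])
    _require_columns(krill, ["ssmu_id", "zone", "initial_biomass_tonnes",
                             "max_recruitment_tonnes"], _FILES["krill"])
    krill_init = np.zeros(n)
    max_rec = np.zeros(n)
    for _, r in krill.iterrows():
        u = uidx[(int(r["ssmu_id"]), str(r["zone"]))]
        krill_init[u] = r["initial_biomass_tonnes"]
        max_rec[u] = r["max_recruitment_tonnes"]
        if "initial_density_g_m2" in krill.columns and np.isfinite(r["initial_density_g_m2"]):
            implied = r["initial_biomass_tonnes"] * GRAMS_PER_TONNE / layout.area[u]
            stated = float(r["initial_density_g_m2"])
            scale = max(abs(stated), 1e-30)
            if abs(implied - stated) / scale > 1e-6:
                raise ValidationError(
                    f"krill.csv row (SSMU {int(r['ssmu_id'])}, {r['zone']}): density "
                    f"{stated} g/m2 inconsistent with biomass/area ({implied:.6g})"
                )

    movement = np.zeros((2, n, n))
    mv = pd.read_csv(directory / _FILES["movement"])
    if len(mv):
        _require_columns(mv, ["season", "from_ssmu", "from_zone",
                              "to_ssmu", "to_zone", "rate"], _FILES["movement"])
        for _, r in mv.iterrows():
            movement[season_index(r["season"]),
                     uidx[(int(r["from_ssmu"]), str(r["from_zone"]))],
                     uidx[(int(r["to_ssmu"]), str(r["to_zone"]))]] = r["rate"]

    predator_init = np.zeros((g, m))
    pr = pd.read_csv(directory / _FILES["predators"])
    if len(pr):
        _require_columns(pr, ["group", "breeding_ssmu", "initial_abundance"], _FILES["predators"])
        for _, r in pr.iterrows():
            predator_init[gidx[r["group"]], sidx[int(r["breeding_ssmu"])]] = r["initial_abundance"]

    foraging = np.zeros((2, g, m, n))
    fo = pd.read_csv(directory / _FILES["foraging"])
    if len(fo):
        _require_columns(fo, ["group", "breeding_ssmu", "season",
                              "foraging_ssmu", "foraging_zone", "proportion"], _FILES["foraging"])
        for _, r in fo.iterrows():
            foraging[season_index(r["season"]), gidx[r["group"]],
                     sidx[int(r["breeding_ssmu"])],
                     uidx[(int(r["foraging_ssmu"]), str(r["foraging_zone"]))]] = r["proportion"]

    demand = np.zeros((g, 2))
    de = pd.read_csv(directory / _FILES["demand"])
    _require_columns(de, ["group", "season", "tonnes_per_capita"], _FILES["demand"])
    for _, r in de.iterrows():
        demand[gidx[r["group"]], season_index(r["season"])] = r["tonnes_per_capita"]

    krill_mort = np.zeros(2)
    pred_mort = np.zeros(g)
    mo = pd.read_csv(directory / _FILES["mortality"])
    _require_columns(mo, ["component", "season", "rate"], _FILES["mortality"])
    for _, r in mo.iterrows():
        if r["component"] == "krill":
            krill_mort[season_index(r["season"])] = r["rate"]
        else:
            pred_mort[gidx[r["component"]]] = r["rate"]

    ca = pd.read_csv(directory / _FILES["catch"])
    _require_columns(ca, ["ssmu_id", "zone", "annual_proportion",
                          "summer_fraction", "winter_fraction"], _FILES["catch"])
    catch_annual = np.zeros(n)
    catch_seasonal = np.zeros((n, 2))
    for _, r in ca.iterrows():
        u = uidx[(int(r["ssmu_id"]), str(r["zone"]))]
        catch_annual[u] = r["annual_proportion"]
        catch_seasonal[u] = (r["summer_fraction"], r["winter_fraction"])

    noise = RecruitmentNoise(**meta.get("recruitment_noise",
                                        {"family": "lognormal", "dispersion": 0.0}))
    par = ReferenceParameterization(
        movement_mode=meta["movement_mode"], response_mode=meta["response_mode"],
        layout=layout, krill_init=krill_init, max_recruitment=max_rec,
        movement=movement, groups=groups, predator_init=predator_init,
        foraging=foraging, demand_per_capita=demand, krill_mortality=krill_mort,
        predator_mortality=pred_mort, catch_annual=catch_annual,
        catch_seasonal=catch_seasonal, recruitment_noise=noise,
        hyperstability_shape=float(meta.get("hyperstability_shape", 0.2)),
    )
    return par.validate(atol=atol)


def write_scenario(scn: ScenarioDefinition, path) -> Path:
    path = Path(path)
    doc = {
        "name": scn.name,
        "redistribution": scn.redistribution,
        "closed_area_fraction": {int(k): float(v) for k, v in scn.closed_area_fraction.items()},
        "closed_catch_fraction": {int(k): float(v) for k, v in scn.closed_catch_fraction.items()},
    }
    if scn.foraging_inside is not None:
        tree: dict = {}
        for (g, s, se), v in scn.foraging_inside.items():
            tree.setdefault(g, {}).setdefault(int(s), {})[se] = float(v)
        doc["foraging_inside"] = tree
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_scenario(path) -> ScenarioDefinition:
    doc = yaml.safe_load(Path(path).read_text())
    fi = None
    if "foraging_inside" in doc and doc["foraging_inside"] is not None:
        fi = {(g, int(s), se): float(v)
              for g, per_ssmu in doc["foraging_inside"].items()
              for s, per_season in per_ssmu.items()
              for se, v in per_season.items()}
    return ScenarioDefinition(
        name=doc["name"],
        closed_area_fraction=doc.get("closed_area_fraction", {}),
        closed_catch_fraction=doc.get("closed_catch_fraction", {}),
        foraging_inside=fi,
        redistribution=doc.get("redistribution", "regional"),
    ).validate()


def write_run_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({
        "n_trials": cfg.n_trials, "n_years": cfg.n_years,
        "harvest_rate": cfg.harvest_rate, "density_threshold": cfg.density_threshold,
        "seed": cfg.seed,
        "parameterizations": [list(p) for p in cfg.parameterizations],
    }, sort_keys=False))
    return path


def read_run_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if "parameterizations" in doc:
        doc["parameterizations"] = tuple(tuple(p) for p in doc["parameterizations"])
    return RunConfig(**doc).validate()


# ---------------------------------------------------------------------------
# Packaged foraging-inside fixture (telemetry-derived percentages)
# ---------------------------------------------------------------------------

def load_table1_fixture() -> dict:
    """Telemetry-derived foraging-inside percentages for the two Scotia Sea
    MPA scenarios (D1MPA and US10).

    Returns a mapping (scenario, group, ssmu_id, season label) → percent of
    the group's seasonal krill demand drawn from inside the closure.  Only
    SSMU/group combinations where the group breeds are present.
    """
    with resources.files("krillmpa.data").joinpath("table1_foraging.csv").open() as fh:
        df = pd.read_csv(fh)
    return {(r["scenario"], r["group"], int(r["ssmu_id"]), r["season"]): float(r["percent"])
            for _, r in df.iterrows()}


def table1_foraging_inside(scenario_name: str) -> dict:
    """Foraging-inside map for one fixture scenario, keyed for
    :class:`ScenarioDefinition`."""
    fix = load_table1_fixture()
    out = {(g, s, se): v for (name, g, s, se), v in fix.items() if name == scenario_name}
    if not out:
        known = sorted({name for (name, *_rest) in fix})
        raise ValidationError(f"unknown fixture scenario {scenario_name!r}; known: {known}")
    return out
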