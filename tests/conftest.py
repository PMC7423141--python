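import dataclasses

import numpy as np
import pytest

import krillmpa as km
from krillmpa.synth import toy_scenarios


@pytest.fixture(scope="session")
def toy_par():
    return km.toy_parameterization()


@pytest.fixture(scope="session")
def toy_mpa():
    return toy_scenarios()["ToyMPA"]


@pytest.fixture()
def noisy_toy(toy_par):
    return dataclasses.replace(
        toy_par, recruitment_noise=km.RecruitmentNoise("lognormal", 0.5))


def random_scenario(par, rng, redistribution="regional", scalar_inside=None):
    """A random partial closure of every SSMU (so any inside-percentage is
    feasible), with catch split matching the area split by default."""
    ssmus = [int(s) for s in par.layout.ssmus]
    caf = {s: float(rng.uniform(0.05, 0.95)) for s in ssmus}
    fi = None
    if scalar_inside is not None:
        fi = {}
        occ = par.occupancy
        for k, g in enumerate(par.groups):
            for i, s in enumerate(ssmus):
                if occ[k, i]:
                    for se in ("summer", "winter"):
                        fi[(g, s, se)] = float(scalar_inside)
    return km.ScenarioDefinition(
        name="rand", closed_area_fraction=caf, closed_catch_fraction=dict(caf),
        foraging_inside=fi, redistribution=redistribution)
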