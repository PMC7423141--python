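"""Open/closed zone decomposition: exact splits, conservation of foraging
rows and inter-SSMU krill flow, and structural pass-through."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import krillmpa as km
from krillmpa.params import SUMMER, WINTER, Layout, RecruitmentNoise, ValidationError
from conftest import random_scenario


class TestSplitScalar:
    @pytest.mark.parametrize("value,frac,expected", [
        (100.0, 0.0, (100.0, 0.0)),
        (100.0, 1.0, (0.0, 100.0)),
        (80.0, 0.25, (60.0, 20.0)),
    ])
    def test_linear_proportioning(self, value, frac, expected):
        assert km.split_scalar(value, frac) == expected

    @given(st.floats(0, 1e9), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_parts_recompose_exactly(self, value, frac):
        op, cl = km.split_scalar(value, frac)
        # exact up to one ulp of the recomposed sum
        assert abs((op + cl) - value) <= np.spacing(max(value, 1.0))
        assert cl == value * frac
        assert op >= 0 and cl >= 0

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValidationError):
            km.split_scalar(10.0, 1.5)
        with pytest.raises(ValidationError):
            km.split_scalar(float("nan"), 0.5)


def _one_ssmu_par(inside_pct=None):
    """Single-SSMU world: one group foraging 100% at home."""
    lay = Layout.whole([1], [1e10], {1: "48.1"})
    foraging = np.zeros((2, 1, 1, 1))
    foraging[:, 0, 0, 0] = 1.0
    return km.ReferenceParameterization(
        movement_mode="none", response_mode="linear", layout=lay,
        krill_init=[1e5], max_recruitment=[1e5], movement=np.zeros((2, 1, 1)),
        groups=("penguins",), predator_init=[[1e4]], foraging=foraging,
        demand_per_capita=[[0.08, 0.04]], krill_mortality=[0.4, 0.4],
        predator_mortality=[0.1], catch_annual=[1.0],
        catch_seasonal=[[0.5, 0.5]]).validate()


class TestForagingDecomposition:
    def test_zero_inside_keeps_rows_in_open_zones(self, toy_par):
        scn = random_scenario(toy_par, np.random.default_rng(0), scalar_inside=0.0)
        dec = km.decompose_parameterization(toy_par, scn)
        closed = dec.layout.zone == "closed"
        assert dec.foraging[..., closed].sum() == 0.0
        # open-zone rows reproduce the original per-SSMU proportions
        P = dec.layout.aggregation_matrix
        np.testing.assert_allclose(dec.foraging @ P.T, toy_par.foraging,
                                   atol=1e-12)

    def test_printed_percentage_splits_single_row(self):
        # one breeder, one foraged SSMU, telemetry-style 86.6% inside
        par = _one_ssmu_par()
        scn = km.ScenarioDefinition(
            "d1", {1: 0.5}, {1: 0.5},
            foraging_inside={("penguins", 1, "summer"): 86.6,
                             ("penguins", 1, "winter"): 86.6})
        dec = km.decompose_parameterization(par, scn)
        closed = dec.layout.zone == "closed"
        assert dec.foraging[SUMMER, 0, 0, closed].sum() == pytest.approx(0.866, abs=1e-12)
        assert dec.foraging[SUMMER, 0, 0, ~closed].sum() == pytest.approx(0.134, abs=1e-12)

    def test_uniform_row_with_half_protection_gives_sixths(self):
        # uniform foraging over 3 SSMUs, 50% inside -> every zone gets 1/6
        par = km.toy_parameterization().copy()
        par.foraging[SUMMER, 0, 0] = (1 / 3, 1 / 3, 1 / 3)
        scn = km.ScenarioDefinition(
            "u", {1: 0.4, 2: 0.4, 3: 0.4}, {1: 0.4, 2: 0.4, 3: 0.4},
            foraging_inside={("penguins", 1, "summer"): 50.0,
                             ("penguins", 1, "winter"): 50.0,
                             ("penguins", 2, "summer"): 50.0,
                             ("penguins", 2, "winter"): 50.0,
                             ("seals", 3, "summer"): 50.0,
                             ("seals", 3, "winter"): 50.0})
        dec = km.decompose_parameterization(par, scn)
        np.testing.assert_allclose(dec.foraging[SUMMER, 0, 0], np.full(6, 1 / 6),
                                   atol=1e-12)

    def test_inside_percentage_infeasible_without_closed_zone(self):
        par = _one_ssmu_par()
        scn = km.ScenarioDefinition(
            "bad", {1: 0.0}, {1: 0.0},
            foraging_inside={("penguins", 1, "summer"): 50.0,
                             ("penguins", 1, "winter"): 0.0})
        with pytest.raises(ValidationError, match="infeasible"):
            km.decompose_parameterization(par, scn)


class TestMovementDecomposition:
    def test_mode_none_stays_zero(self, toy_par, toy_mpa):
        dec = km.decompose_parameterization(toy_par, toy_mpa)
        assert not dec.movement.any()

    def test_flow_conservation_under_drift(self):
        # oracle: parent-to-parent flow = sum over zone pairs of
        # (area share of source zone) x zone rate
        cfg = km.SynthConfig(n_ssmu=4, seed=5, movement_mode="drift")
        par = km.generate_parameterization(cfg)
        scn = random_scenario(par, np.random.default_rng(2))
        dec = km.decompose_parameterization(par, scn)
        lay = dec.layout
        share = lay.area_share
        for s in (SUMMER, WINTER):
            for i_pos, i in enumerate(par.layout.ssmus):
                for j_pos, j in enumerate(par.layout.ssmus):
                    if i == j:
                        continue
                    flow = sum(share[a] * dec.movement[s, a, b]
                               for a in lay.units_of(i) for b in lay.units_of(j))
                    assert flow == pytest.approx(par.movement[s, i_pos, j_pos],
                                                 abs=1e-9)

    def test_zero_rows_stay_zero(self):
        cfg = km.SynthConfig(n_ssmu=4, seed=5, movement_mode="drift")
        par = km.generate_parameterization(cfg)
        par.movement[:, 2, :] = 0.0
        scn = random_scenario(par, np.random.default_rng(3))
        dec = km.decompose_parameterization(par, scn)
        units3 = dec.layout.units_of(3)
        others = np.setdiff1d(np.arange(dec.layout.n_units), units3)
        # no outflow from SSMU 3's zones to other SSMUs
        assert dec.movement[:, units3][:, :, others].sum() == 0.0


class TestFullDecomposition:
    def test_no_mpa_is_structural_passthrough(self, toy_par):
        dec = km.decompose_parameterization(
            toy_par, km.ScenarioDefinition.no_mpa([1, 2, 3]))
        assert list(dec.layout.zone) == ["open"] * 3
        np.testing.assert_array_equal(dec.krill_init, toy_par.krill_init)
        np.testing.assert_array_equal(dec.catch_annual, toy_par.catch_annual)
        np.testing.assert_array_equal(dec.foraging, toy_par.foraging)

    def test_catch_fraction_splits_annual_share(self, toy_par):
        scn = km.ScenarioDefinition("c", {1: 0.5, 2: 0.5, 3: 0.5},
                                    {1: 0.0, 2: 0.0, 3: 2 / 3})
        # SSMU 3 annual share 0.6 with 2/3 inside -> closed 0.4, open 0.2
        dec = km.decompose_parameterization(toy_par, scn)
        lay = dec.layout
        u_open = lay.units_of(3, "open")[0]
        u_closed = lay.units_of(3, "closed")[0]
        assert dec.catch_annual[u_closed] == pytest.approx(0.4, abs=1e-12)
        assert dec.catch_annual[u_open] == pytest.approx(0.2, abs=1e-12)

    def test_conservation_over_randomized_scenarios(self):
        # decomposed areas / biomass / recruitment / catch sum back to the
        # parent values; foraging rows keep their sum and hit the requested
        # inside fraction
        rng = np.random.default_rng(42)
        for case in range(200):
            cfg = km.SynthConfig(n_ssmu=int(rng.integers(2, 6)),
                                 seed=int(rng.integers(2**31)),
                                 movement_mode=("drift", "none")[case % 2])
            par = km.generate_parameterization(cfg)
            inside = float(rng.uniform(0, 100)) if case % 3 else None
            scn = random_scenario(par, rng, scalar_inside=inside)
            dec = km.decompose_parameterization(par, scn)
            P = dec.layout.aggregation_matrix
            np.testing.assert_allclose(P @ dec.layout.area, par.layout.area,
                                       rtol=1e-12)
            np.testing.assert_allclose(P @ dec.krill_init, par.krill_init,
                                       rtol=1e-12)
            np.testing.assert_allclose(P @ dec.max_recruitment,
                                       par.max_recruitment, rtol=1e-12)
            np.testing.assert_allclose(P @ dec.catch_annual, par.catch_annual,
                                       atol=1e-12)
            occ = par.occupancy
            rowsums = dec.foraging.sum(axis=-1)
            for s in (SUMMER, WINTER):
                np.testing.assert_allclose(rowsums[s][occ], 1.0, atol=1e-9)
            if inside is not None:
                closed = dec.layout.zone == "closed"
                closed_share = dec.foraging[..., closed].sum(axis=-1)
                for s in (SUMMER, WINTER):
                    np.testing.assert_allclose(closed_share[s][occ],
                                               inside / 100.0, atol=1e-9)

    def test_fully_closed_ssmu_with_partial_catch_fraction_rejected(self, toy_par):
        scn = km.ScenarioDefinition("bad", {1: 1.0, 2: 0.0, 3: 0.0},
                                    {1: 0.5, 2: 0.0, 3: 0.0})
        with pytest.raises(ValidationError, match="fully closed"):
            km.decompose_parameterization(toy_par, scn)
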