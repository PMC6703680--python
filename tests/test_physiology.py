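"""Carbon physiology: response curve, beta growth, photosynthesis,
relative-sink-strength allocation and the petiole elongation bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from shadegame.architecture import Leaf, PlasticityStrategy
from shadegame.physiology import (GrowthCurveParams, PhysiologyParams,
                                  SinkDemand, allocate,
                                  apply_petiole_plasticity, beta_growth_mass,
                                  beta_growth_rate, dimension_update,
                                  lamina_demand, percent_biomass_in,
                                  photosynthesis, response_factor)


class TestResponseFactor:
    @pytest.mark.parametrize("rfr,alpha,expected", [
        (2.3, 0.5, 1.0),            # control ratio
        (1.7, 0.0, 1.0),            # alpha 0: no response at any R:FR
        (0.575, 0.5, 2.0),          # (0.25)^-0.5 hits the cap exactly
        (1.15, 0.5, math.sqrt(2)),  # (0.5)^-0.5
    ])
    def test_curve_values(self, rfr, alpha, expected):
        assert response_factor(rfr, PlasticityStrategy(alpha)) == \
            pytest.approx(expected)

    def test_nonpositive_rfr_rejected(self):
        with pytest.raises(ValueError):
            response_factor(0.0, PlasticityStrategy(0.5))

    @given(rfr=st.floats(0.05, 2.3), alpha=st.floats(0.0, 0.7))
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_to_cap(self, rfr, alpha):
        f = response_factor(rfr, PlasticityStrategy(alpha))
        assert 1.0 <= f <= 2.0

    @given(alpha=st.floats(0.05, 0.7),
           r1=st.floats(0.1, 2.2), r2=st.floats(0.1, 2.2))
    @settings(max_examples=100, deadline=None)
    def test_nonincreasing_in_rfr(self, alpha, r1, r2):
        lo, hi = sorted((r1, r2))
        s = PlasticityStrategy(alpha)
        assert response_factor(lo, s) >= response_factor(hi, s)


class TestLaminaDemand:
    @pytest.mark.parametrize("n,expected", [
        (0, 10.0), (1, 5.0), (2, 2.5), (4, 0.625),
    ])
    def test_downregulation_by_scenario_exponent(self, n, expected):
        assert lamina_demand(10.0, 2.0, n) == pytest.approx(expected)

    def test_no_signal_no_change(self):
        assert lamina_demand(10.0, 1.0, 2.0) == pytest.approx(10.0)


class TestBetaGrowth:
    def test_terminal_and_initial_values(self, growth):
        assert beta_growth_mass(0.0, growth) == 0.0
        assert beta_growth_mass(growth.t_e, growth) == growth.w_max
        assert beta_growth_mass(growth.t_e + 5, growth) == growth.w_max

    def test_inflection_value_by_substitution(self, growth):
        # W(t_m) = 10 * (1 + 10/10) * 0.5^2 = 5
        assert beta_growth_mass(10.0, growth) == pytest.approx(5.0)

    def test_rate_zero_outside_growth_window(self, growth):
        assert beta_growth_rate(0.0, growth) == 0.0
        assert beta_growth_rate(growth.t_e, growth) == 0.0
        assert beta_growth_rate(25.0, growth) == 0.0

    def test_rate_matches_numeric_differentiation(self, growth):
        h = 1e-6
        for t in np.linspace(0.5, 19.5, 25):
            numeric = (beta_growth_mass(t + h, growth)
                       - beta_growth_mass(t - h, growth)) / (2 * h)
            assert beta_growth_rate(t, growth) == pytest.approx(numeric,
                                                                rel=1e-5)

    def test_rate_maximal_at_inflection(self, growth):
        ts = np.linspace(0.1, 19.9, 397)
        rates = [beta_growth_rate(t, growth) for t in ts]
        assert abs(ts[int(np.argmax(rates))] - growth.t_m) < 0.1

    def test_rate_integrates_to_final_mass(self, growth):
        total, _ = quad(beta_growth_rate, 0, growth.t_e, args=(growth,),
                        limit=200)
        assert total == pytest.approx(growth.w_max, rel=1e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GrowthCurveParams(10.0, 10.0, 10.0)
        with pytest.raises(ValueError):
            GrowthCurveParams(-1.0, 20.0, 10.0)


class TestPhotosynthesis:
    def test_dark_gives_zero(self, phys):
        assert photosynthesis(0.0, 1e-3, phys, 9.0) == 0.0

    def test_saturates_at_pmax(self, phys):
        area, hours = 1e-3, 9.0
        sat = phys.p_max * area * hours * 3600.0
        assert photosynthesis(1e7, area, phys, hours) == pytest.approx(sat,
                                                                       rel=1e-6)

    def test_characteristic_flux_value(self, phys):
        # I = p_max / phi makes the exponent exactly -1
        i = phys.p_max / phys.phi
        area, hours = 1e-3, 9.0
        expect = phys.p_max * (1 - math.exp(-1)) * area * hours * 3600.0
        assert photosynthesis(i, area, phys, hours) == pytest.approx(expect)


class TestAllocation:
    def demands(self, *vals, organ="lamina"):
        return [SinkDemand(organ, i, v, v) for i, v in enumerate(vals)]

    def test_proportional_when_pool_short(self):
        out = allocate(6.0, self.demands(4.0, 8.0))
        assert [d.allocated for d in out] == [pytest.approx(2.0),
                                              pytest.approx(4.0)]

    def test_demands_met_and_surplus_split_when_pool_ample(self):
        ds = self.demands(4.0, 8.0) + [SinkDemand("root", -1, 1.0, 1.0)]
        out = allocate(23.0, ds, surplus_lamina_fraction=0.5)
        # demands met: 4, 8, 1; surplus 10 -> 5 to laminas pro rata, 5 root
        assert out[0].allocated == pytest.approx(4.0 + 5.0 * 4 / 12)
        assert out[1].allocated == pytest.approx(8.0 + 5.0 * 8 / 12)
        assert out[2].allocated == pytest.approx(6.0)
        assert sum(d.allocated for d in out) == pytest.approx(23.0)

    def test_zero_pool_allocates_nothing(self):
        out = allocate(0.0, self.demands(4.0, 8.0))
        assert all(d.allocated == 0.0 for d in out)

    def test_zero_demand_sends_surplus_to_root(self):
        out = allocate(5.0, [SinkDemand("root", -1, 0.0, 0.0)])
        assert out[0].allocated == pytest.approx(5.0)

    @given(pool=st.floats(0.01, 100), scale=st.floats(0.1, 10),
           d1=st.floats(0.01, 50), d2=st.floats(0.01, 50))
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, pool, scale, d1, d2):
        base = allocate(pool, self.demands(d1, d2))
        scaled = allocate(pool * scale,
                          self.demands(d1 * scale, d2 * scale))
        for b, s in zip(base, scaled):
            assert s.allocated == pytest.approx(b.allocated * scale, rel=1e-9)

    @given(pool=st.floats(0, 100),
           vals=st.lists(st.floats(0, 20), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_allocations_sum_to_pool(self, pool, vals):
        ds = self.demands(*vals) + [SinkDemand("root", -1, 1.0, 1.0)]
        out = allocate(pool, ds)
        assert sum(d.allocated for d in out) == pytest.approx(pool, abs=1e-9)


class TestPetiolePlasticity:
    def test_neutral_factor_changes_nothing(self, leaf):
        extra = apply_petiole_plasticity(leaf, 1.0, 200.0)
        assert extra == 0.0
        assert leaf.petiole_length == pytest.approx(0.02)

    def test_elongation_and_queued_debt(self, leaf):
        extra = apply_petiole_plasticity(leaf, 2.0, 200.0)
        assert leaf.petiole_length == pytest.approx(0.04)
        assert extra == pytest.approx(0.02 * 200.0)
        assert leaf.pending_elongation_demand == pytest.approx(4.0)

    def test_inactive_after_growth_phase(self, leaf):
        leaf.petiole_growing = False
        extra = apply_petiole_plasticity(leaf, 2.0, 200.0)
        assert extra == 0.0
        assert leaf.petiole_length == pytest.approx(0.02)


class TestDimensionUpdate:
    def test_zero_allocation_changes_nothing(self, leaf, phys):
        before = (leaf.lamina_area, leaf.petiole_length, leaf.biomass)
        dimension_update(leaf, 0.0, 0.0, 0.0, phys)
        assert (leaf.lamina_area, leaf.petiole_length, leaf.biomass) == before

    def test_linear_conversions(self, leaf, phys):
        area0, len0 = leaf.lamina_area, leaf.petiole_length
        dimension_update(leaf, 1.0, 1.0, 0.0, phys)
        assert leaf.lamina_area == pytest.approx(area0 + phys.sla)
        assert leaf.petiole_length == pytest.approx(
            len0 + 1.0 / phys.petiole_linear_density)

    def test_debt_payment_adds_mass_but_not_length(self, leaf, phys):
        leaf.pending_elongation_demand = 3.0
        len0, mass0 = leaf.petiole_length, leaf.petiole_biomass
        dimension_update(leaf, 0.0, 0.0, 2.0, phys)
        assert leaf.petiole_length == pytest.approx(len0)
        assert leaf.petiole_biomass == pytest.approx(mass0 + 2.0)
        assert leaf.pending_elongation_demand == pytest.approx(1.0)


class TestPercentBiomass:
    def test_partition(self, plant):
        # petioles 3, laminas 9, root 2 -> total 14
        assert percent_biomass_in("petiole", plant) == \
            pytest.approx(100 * 3 / 14)
        shares = sum(percent_biomass_in(c, plant)
                     for c in ("petiole", "lamina", "root"))
        assert shares == pytest.approx(100.0)

    def test_all_root(self):
        from shadegame.architecture import Plant
        p = Plant(position=(0, 0), strategy=PlasticityStrategy(0.0))
        p.root_biomass = 5.0
        assert percent_biomass_in("petiole", p) == pytest.approx(0.0)

    def test_empty_plant_is_missing_value(self):
        from shadegame.architecture import Plant
        p = Plant(position=(0, 0), strategy=PlasticityStrategy(0.0))
        assert math.isnan(percent_biomass_in("petiole", p))
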