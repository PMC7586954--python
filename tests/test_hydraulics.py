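"""Supply-demand network: k_max, Kirchhoff fluxes, E_crit, demand solve,
stomatal demand, canopy energy balance."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from cottonhydro.hydraulics import (GenotypeParams, HydraulicNetwork,
                                    WeibullElement, boundary_layer_conductance,
                                    build_continuum, canopy_temperature,
                                    kmax_saturated, solve_demand,
                                    stomatal_demand, supply_function)
from cottonhydro.hydraulics import _Layer
from cottonhydro.soilphys import SoilHydraulicParams, theta_to_psi
from cottonhydro.vcurves import VulnerabilityCurve

SOIL = SoilHydraulicParams(psi_e=-0.002, lambda_bc=0.3, ks_soil=2e-6,
                           theta_s=0.4, theta_r=0.09, d_gmean_mm=0.12)


def _genotype(shoot_b=1.55, shoot_c=0.75):
    return GenotypeParams(
        gsref=0.63, e_sat=11.4, psi_pd_sat=-0.8, psi_md_sat=-2.4,
        vc_shoot=VulnerabilityCurve(shoot_b, shoot_c),
        vc_root=VulnerabilityCurve(0.29, 0.59, organ="root"),
        root_to_leaf_area=2.5)


def _single_element_network(k, b, c, x_soil=0.0):
    """Network whose only real constriction is the shoot element."""
    shoot = WeibullElement(k, b, c)
    root = WeibullElement(1e8 * k, 100.0, 1.0)
    return HydraulicNetwork(shoot, [_Layer(root=root, g_rhiz=1e15,
                                           x_soil=x_soil, frac=1.0)], k_max=k)


class TestKmax:
    def test_published_parameterization(self):
        # 11.4 / (-0.8 - (-2.4)) = 7.125
        assert kmax_saturated(_genotype()) == pytest.approx(7.125)

    def test_linear_in_e_sat(self):
        g = _genotype()
        doubled = GenotypeParams(**{**g.__dict__, "e_sat": 2 * g.e_sat})
        assert kmax_saturated(doubled) == pytest.approx(2 * kmax_saturated(g))

    def test_equal_potentials_rejected(self):
        with pytest.raises(ValueError):
            GenotypeParams(gsref=0.63, e_sat=11.4, psi_pd_sat=-2.4,
                           psi_md_sat=-2.4,
                           vc_shoot=VulnerabilityCurve(1.55, 0.75),
                           vc_root=VulnerabilityCurve(0.29, 0.59))


class TestKirchhoff:
    def test_transform_matches_quadrature(self):
        el = WeibullElement(5.0, 1.55, 0.75)
        for x in (0.3, 1.0, 3.0, 8.0):
            ref, _ = quad(lambda t: math.exp(-((t / 1.55) ** 0.75)), 0.0, x)
            assert float(el.phi(x)) == pytest.approx(ref, rel=1e-9)

    def test_phi_inverse_round_trip(self):
        el = WeibullElement(5.0, 0.8, 0.6)
        for x in (0.05, 0.5, 2.0, 6.0):
            assert el.phi_inv(float(el.phi(x))) == pytest.approx(x, rel=1e-9)

    def test_flux_never_negative(self):
        el = WeibullElement(5.0, 1.0, 1.0)
        assert el.flux(2.0, 1.0) == 0.0


class TestEcrit:
    def test_single_element_closed_form(self):
        # E_crit = k b Gamma(1 + 1/c) for a lone Weibull element on wet soil
        for b, c, k in [(1.55, 0.75, 10.0), (0.5, 1.3, 4.0), (3.0, 0.6, 2.0)]:
            net = _single_element_network(k, b, c)
            assert net.e_crit() == pytest.approx(
                k * b * math.gamma(1.0 + 1.0 / c), rel=1e-4)

    def test_reference_value_b155_c075(self):
        # b Gamma(1 + 1/c) = 1.846 for the species shoot curve
        net = _single_element_network(1.0, 1.55, 0.75)
        assert net.e_crit() == pytest.approx(1.846, abs=2e-3)

    def test_e_crit_decreases_with_drying_soil(self):
        vals = [
            _single_element_network(5.0, 1.55, 0.75, x_soil=x).e_crit()
            for x in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestNetwork:
    def _layers(self, theta, fracs):
        psi = theta_to_psi(SOIL, theta)
        return [(SOIL, theta)] * len(fracs), fracs

    def test_series_reduction_at_saturation(self):
        # with an ideal rhizosphere the saturated network conductance is k_max
        g = _genotype()
        net = build_continuum(g, [(SOIL, SOIL.theta_s)], lai=3.5,
                              root_profile=[1.0], rhiz_geometry_factor=1e-6)
        state = net.solve(0.0)
        assert state.k_plant == pytest.approx(kmax_saturated(g), rel=1e-6)

    def test_symmetric_layers_split_uptake_equally(self):
        g = _genotype()
        layers, fracs = self._layers(0.25, [0.5, 0.5])
        net = build_continuum(g, layers, lai=3.5, root_profile=fracs)
        state = net.solve(2.0)
        np.testing.assert_allclose(state.layer_uptake, [0.5, 0.5], atol=1e-9)

    def test_uptake_scales_with_root_area(self):
        # conductances scale with root-area fraction -> 4:1 uptake split
        g = _genotype()
        layers, fracs = self._layers(0.25, [0.8, 0.2])
        net = build_continuum(g, layers, lai=3.5, root_profile=fracs,
                              rhiz_geometry_factor=1e-6)
        state = net.solve(2.0)
        assert state.layer_uptake[0] / state.layer_uptake[1] == \
            pytest.approx(4.0, rel=1e-6)

    def test_flux_conservation(self):
        g = _genotype()
        layers, fracs = self._layers(0.2, [0.4, 0.3, 0.2, 0.1])
        net = build_continuum(g, layers, lai=3.5, root_profile=fracs)
        e = 1.5
        state = net.solve(e)
        assert state.layer_uptake.sum() == pytest.approx(1.0, abs=1e-9)
        assert state.e_c == pytest.approx(e)

    def test_zero_demand_equilibrates_with_soil(self):
        g = _genotype()
        layers, fracs = self._layers(0.25, [0.6, 0.4])
        net = build_continuum(g, layers, lai=3.5, root_profile=fracs)
        state = net.solve(0.0)
        assert state.psi_leaf == pytest.approx(theta_to_psi(SOIL, 0.25))

    def test_demand_beyond_capacity_is_capped_and_flagged(self):
        g = _genotype()
        layers, fracs = self._layers(0.25, [1.0])
        net = build_continuum(g, layers, lai=3.5, root_profile=fracs)
        e_crit = net.e_crit()
        state = net.solve(2.0 * e_crit)
        assert state.flagged
        assert state.e_c == pytest.approx(0.9 * e_crit, rel=1e-9)

    def test_all_zero_root_area_rejected(self):
        g = _genotype()
        with pytest.raises(ValueError):
            build_continuum(g, [(SOIL, 0.25)], lai=3.5, root_profile=[0.0])

    def test_supply_curve_nondecreasing_and_anchored(self):
        g = _genotype()
        layers, fracs = self._layers(0.22, [0.7, 0.3])
        net = build_continuum(g, layers, lai=3.5, root_profile=fracs)
        psi_soil = theta_to_psi(SOIL, 0.22)
        psi_grid = psi_soil - np.linspace(0.0, 10.0, 60)
        _, e_vals, e_crit = supply_function(net, psi_grid)
        assert e_vals[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(e_vals) >= -1e-9)
        assert e_vals[-1] <= e_crit + 1e-9

    def test_solve_matches_bisection_on_supply_curve(self):
        g = _genotype()
        layers, fracs = self._layers(0.22, [1.0])
        net = build_continuum(g, layers, lai=3.5, root_profile=fracs)
        e_target = 0.5 * net.e_crit()
        state = net.solve(e_target)
        psi_soil = theta_to_psi(SOIL, 0.22)
        root = brentq(lambda p: net.supply(p) - e_target,
                      psi_soil - 40.0, psi_soil - 1e-12, xtol=1e-10)
        assert state.psi_leaf == pytest.approx(root, abs=1e-6)

    def test_steeper_shoot_vc_transpires_less_on_dry_soil(self):
        # the headline genotype contrast: a steep landrace-like curve limits
        # flux more than a shallow modern-cultivar curve under dry soil
        steep = _genotype(shoot_b=0.6)
        shallow = _genotype(shoot_b=2.0)
        theta = 0.135
        outs = []
        for geno in (steep, shallow):
            net = build_continuum(geno, [(SOIL, theta)], lai=3.5,
                                  root_profile=[1.0])
            outs.append(net.solve(10.0).e_c)
        assert outs[0] < outs[1]


class TestDemand:
    def test_reference_conductance_at_unit_vpd(self):
        g = _genotype()
        e = stomatal_demand(g, vpd=1.0, lai=1.0, par=2000.0)
        assert e == pytest.approx(0.63 * (1.0 / 101.3) * 1e3)

    def test_closure_at_high_vpd(self):
        g = _genotype()
        assert stomatal_demand(g, vpd=math.exp(1.0 / 0.6) + 0.01, lai=3.5) == 0.0

    def test_linear_in_lai(self):
        g = _genotype()
        e1 = stomatal_demand(g, vpd=2.0, lai=2.0)
        e2 = stomatal_demand(g, vpd=2.0, lai=4.0)
        assert e2 == pytest.approx(2.0 * e1)

    def test_nonpositive_vpd_rejected(self):
        with pytest.raises(ValueError):
            stomatal_demand(_genotype(), vpd=0.0, lai=3.5)


class TestCanopyTemperature:
    def test_latent_flux_balancing_radiation_gives_air_temperature(self):
        par = 1000.0
        rn = 0.283 * par
        e_ground = rn / 44.0  # mmol m-2 s-1 such that lambda E = Rn
        t_c = canopy_temperature(30.0, par, 2.0, e_ground, lai=3.0)
        assert t_c == pytest.approx(30.0, abs=1e-9)

    def test_no_transpiration_warms_canopy(self):
        assert canopy_temperature(30.0, 1500.0, 2.0, 0.0, lai=3.0) > 30.0

    def test_hand_arithmetic_balance(self):
        # Rn = 400, lambda E = 200, rho_a c_p g_H = 50 -> delta T = 4 K
        par = 400.0 / 0.283
        lai = 1.0
        g_h_target = 50.0 / 29.3
        wind = 0.1 * (g_h_target / (1.4 * 0.135)) ** 2
        assert boundary_layer_conductance(wind, lai) == \
            pytest.approx(g_h_target, rel=1e-12)
        e_ground = 200.0 / 44.0
        t_c = canopy_temperature(25.0, par, wind, e_ground, lai)
        assert t_c - 25.0 == pytest.approx(4.0, rel=1e-9)
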