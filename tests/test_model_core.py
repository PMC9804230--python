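import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from thermospectra.model_core import (
    InteractionMatrix,
    Model,
    ModelState,
    ResourceParams,
    SpeciesParams,
    WeightGrid,
    available_energy,
    background_mortality,
    beverton_holt,
    encounter_rate,
    feeding_level,
    fishing_mortality,
    lognormal_selectivity,
    maturity_allocation,
    maturity_ogive,
    net_energy,
    predation_mortality,
    search_volume_coefficient,
    somatic_growth,
    starvation_mortality,
)


class TestSpeciesParams:
    def test_valid_construction(self, species_one):
        assert species_one.w0 < species_one.wmat < species_one.Wi

    @pytest.mark.parametrize(
        "field,value",
        [
            ("w0", 50.0),  # w0 > wmat
            ("alpha", 1.5),
            ("alpha", 0.0),
            ("beta", 0.5),
            ("sigma", -1.0),
            ("Rmax", 0.0),
            ("xi", 0.0),
            ("F", -0.1),
        ],
    )
    def test_invalid_rejected(self, field, value):
        kwargs = dict(
            name="x", w0=1e-3, Wi=100.0, wmat=20.0, h=20.0, ks=2.0, mu0=0.6, Rmax=1e8
        )
        kwargs[field] = value
        with pytest.raises(ValueError):
            SpeciesParams(**kwargs)


class TestResourceParams:
    def test_invalid(self):
        with pytest.raises(ValueError):
            ResourceParams(name="r", r0=-1.0, kappa=1e3, lambda_=2.05, w_min=1e-7, w_max=1.0)
        with pytest.raises(ValueError):
            ResourceParams(name="r", r0=1.0, kappa=1e3, lambda_=2.05, w_min=1.0, w_max=0.5)

    def test_lambda_mismatch_warns(self):
        r = ResourceParams(name="r", r0=1.0, kappa=1e3, lambda_=1.9, w_min=1e-7, w_max=1.0)
        with pytest.warns(UserWarning):
            r.validate_lambda(n=0.75, q=0.8)


class TestWeightGrid:
    def test_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            WeightGrid(w=np.array([1.0, 1.0, 2.0]), dw=np.ones(3))

    def test_range_inside_grid_required(self):
        with pytest.raises(ValueError):
            WeightGrid(
                w=np.array([1.0, 2.0]), dw=np.ones(2), species_ranges={"x": (0, 5)}
            )

    def test_build_covers_everything(self, species_one, resource_one):
        g = WeightGrid.build([species_one], [resource_one])
        i0, i1 = g.species_ranges["fish"]
        assert g.w[i0] <= species_one.w0 * 1.0001
        assert g.w[i1 - 1] >= species_one.Wi * 0.9999


class TestModelState:
    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            ModelState(N=np.array([[-1.0]]), NR=np.array([[0.0]]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ModelState(N=np.array([[np.nan]]), NR=np.array([[0.0]]))


class TestInteractionMatrix:
    def test_theta_ij_all_ones(self):
        im = InteractionMatrix(theta_iR=np.array([[0.5], [1.0]]))
        assert np.all(im.theta_ij == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            InteractionMatrix(theta_iR=np.array([[1.5]]))


class TestLognormalSelectivity:
    def test_maximal_at_beta(self):
        assert lognormal_selectivity(1.0, 100.0, beta=100.0, sigma=1.0) == pytest.approx(1.0)

    def test_one_sigma_off(self):
        # wi/wp = beta * e^sigma  ->  exp(-1/2)
        sigma = 0.7
        val = lognormal_selectivity(1.0, 100.0 * math.exp(sigma), beta=100.0, sigma=sigma)
        assert val == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_sigma_to_zero_limit(self):
        assert lognormal_selectivity(1.0, 150.0, beta=100.0, sigma=1e-8) == pytest.approx(0.0, abs=1e-300)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            lognormal_selectivity(0.0, 1.0, beta=100.0, sigma=1.0)

    def test_gaussian_normalisation(self):
        # integral over ln(prey weight) equals sigma * sqrt(2*pi)
        beta, sigma, wi = 100.0, 1.3, 50.0
        val, _ = quad(
            lambda x: lognormal_selectivity(math.exp(x), wi, beta, sigma), -40, 40
        )
        assert val == pytest.approx(sigma * math.sqrt(2 * math.pi), rel=1e-9)


class TestSearchVolumeCoefficient:
    def test_linear_in_h(self):
        a = search_volume_coefficient(0.6, 20.0, 100.0, 1.0, 2.05, 1e3)
        b = search_volume_coefficient(0.6, 40.0, 100.0, 1.0, 2.05, 1e3)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_lambda_two_special_case(self):
        f0, h, kappa, sigma = 0.6, 20.0, 1e3, 1.0
        val = search_volume_coefficient(f0, h, 100.0, sigma, 2.0, kappa)
        expected = f0 * h / ((1 - f0) * math.sqrt(2 * math.pi) * kappa * sigma)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_closed_form_oracle(self):
        # independent evaluation of the printed formula
        f0, h, beta, sigma, lam, kappa = 0.6, 20.0, 100.0, 1.0, 2.05, 1e3
        num = f0 * h * beta ** (2 - lam) * math.exp(-((lam - 2) ** 2) * sigma**2 / 2)
        den = (1 - f0) * math.sqrt(2 * math.pi) * kappa * sigma
        assert search_volume_coefficient(f0, h, beta, sigma, lam, kappa) == pytest.approx(
            num / den, rel=1e-14
        )

    @pytest.mark.parametrize("f0", [0.0, 1.0])
    def test_degenerate_feeding_rejected(self, f0):
        with pytest.raises(ValueError):
            search_volume_coefficient(f0, 20.0, 100.0, 1.0, 2.05, 1e3)


class TestEncounterAndFeeding:
    def test_zero_available(self):
        assert encounter_rate(1e-11, 0.8, 5.0, 0.0) == 0.0

    def test_unit_weight(self):
        assert encounter_rate(2.0, 0.8, 1.0, 3.0) == pytest.approx(6.0)

    def test_gamma_doubling(self):
        assert encounter_rate(4.0, 0.8, 2.0, 3.0) == pytest.approx(
            2 * encounter_rate(2.0, 0.8, 2.0, 3.0)
        )

    def test_half_saturation(self):
        h, w, n = 20.0, 2.0, 0.75
        assert feeding_level(h * w**n, h, w, n) == pytest.approx(0.5)

    def test_zero_encounter(self):
        assert feeding_level(0.0, 20.0, 2.0, 0.75) == 0.0

    def test_satiation_limit(self):
        assert feeding_level(1e30, 20.0, 2.0, 0.75) == pytest.approx(1.0)


class TestNetEnergyGrowthAllocation:
    def test_boundary_zero(self, species_one):
        sp = species_one
        # choose f so intake exactly equals metabolism at w=1
        f = sp.ks / (sp.alpha * sp.h)
        assert net_energy(f, 1.0, sp) == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_case(self):
        sp = SpeciesParams(
            name="x", w0=1e-3, Wi=100.0, wmat=20.0, h=20.0, ks=2.0, mu0=0.6,
            Rmax=1e8, alpha=0.6, n=0.75, p=0.75,
        )
        # alpha*f*h*w^n - ks*w^p = 0.6*0.5*20 - 2 = 4 at w=1
        assert net_energy(0.5, 1.0, sp) == pytest.approx(4.0)

    def test_deficit_clamped(self, species_one):
        assert net_energy(0.0, 1.0, species_one) == 0.0

    def test_allocation_limits(self, species_one):
        sp = species_one
        assert maturity_allocation(sp.w0, sp) < 1e-6
        assert maturity_allocation(sp.Wi, sp) == pytest.approx(1.0, abs=0.05)

    def test_allocation_at_wmat(self, species_one):
        sp = species_one
        expected = 0.5 * (sp.wmat / sp.Wi) ** (1 - sp.n)
        assert maturity_allocation(sp.wmat, sp) == pytest.approx(expected, rel=1e-12)

    def test_growth_shutoff(self):
        assert somatic_growth(5.0, 1.0) == 0.0
        assert somatic_growth(5.0, 0.0) == 5.0

    def test_growth_approaches_asymptote(self, species_one):
        # constant feeding level -> von Bertalanffy-like curve levelling
        # off near the asymptotic weight
        sp = species_one
        f = 0.7

        def rhs(t, w):
            return somatic_growth(net_energy(f, w[0], sp), maturity_allocation(w[0], sp))

        sol = solve_ivp(rhs, (0, 400), [sp.w0], rtol=1e-8, max_step=1.0)
        w_end = sol.y[0, -1]
        assert w_end == pytest.approx(sp.Wi, rel=0.05)
        # decelerating: growth increments shrink over the last stretch
        late = np.diff(sol.y[0, -10:])
        assert np.all(np.diff(late) <= 1e-9)


class TestMortalities:
    def test_background_power_law(self):
        sp16 = SpeciesParams(name="a", w0=1e-3, Wi=16.0, wmat=2.0, h=20, ks=2, mu0=0.6, Rmax=1e8)
        sp1 = SpeciesParams(name="b", w0=1e-3, Wi=1.0, wmat=0.5, h=20, ks=2, mu0=0.6, Rmax=1e8)
        assert background_mortality(sp16) / background_mortality(sp1) == pytest.approx(0.5)

    def test_background_value(self):
        sp = SpeciesParams(name="b", w0=1e-4, Wi=1.0, wmat=0.5, h=20, ks=2, mu0=0.6, Rmax=1e8)
        assert background_mortality(sp) == pytest.approx(0.6)

    def test_starvation_branches(self, species_one):
        sp = species_one
        assert starvation_mortality(1.0, 1.0, sp) == 0.0  # surplus
        # total deficit at f=0: ks*w^p / (xi*w)
        w = 2.0
        expected = sp.ks * w**sp.p / (sp.xi * w)
        assert starvation_mortality(0.0, w, sp) == pytest.approx(expected)
        # continuity at the threshold
        f_crit = sp.ks / (sp.alpha * sp.h)  # at w=1, n=p
        assert starvation_mortality(f_crit, 1.0, sp) == pytest.approx(0.0, abs=1e-12)

    def test_fishing_knife_edge(self, species_one):
        sp = species_one
        assert fishing_mortality(sp.wmat / 2, sp) == 0.0
        assert fishing_mortality(sp.wmat, sp) == sp.F  # closed at wmat
        sp0 = sp.with_(F=0.0)
        assert np.all(fishing_mortality(np.array([1.0, 50.0]), sp0) == 0.0)


class TestBevertonHolt:
    def test_half_saturation(self):
        assert beverton_holt(1e8, 1e8) == pytest.approx(5e7)

    def test_saturation_limit(self):
        assert beverton_holt(1e20, 1e8) == pytest.approx(1e8, rel=1e-10)

    def test_linear_regime(self):
        assert beverton_holt(1.0, 1e8) == pytest.approx(1.0, rel=1e-7)

    def test_monotone_and_bounded(self):
        r = [beverton_holt(x, 1e6) for x in np.logspace(0, 12, 50)]
        assert np.all(np.diff(r) >= 0)
        assert max(r) <= 1e6


class TestQuadratureOracles:
    """Integrals must match naive term-by-term sums on toy grids."""

    def _toy_setup(self, species_one, resource_one, toy_grid):
        im = InteractionMatrix(theta_iR=np.array([[0.8]]))
        N = np.array([[5.0, 3.0, 1.0]])
        NR = np.array([[10.0, 4.0, 2.0]])
        state = ModelState(N=N, NR=NR)
        return state, im

    def test_available_energy_zero_prey(self, species_one, resource_one, toy_grid):
        state = ModelState(N=np.zeros((1, 3)), NR=np.zeros((1, 3)))
        im = InteractionMatrix(theta_iR=np.array([[0.8]]))
        assert available_energy(state, toy_grid, im, 0, 2.0, [species_one]) == 0.0

    def test_available_energy_single_bin(self, species_one, toy_grid):
        state = ModelState(N=np.zeros((1, 3)), NR=np.array([[0.0, 7.0, 0.0]]))
        im = InteractionMatrix(theta_iR=np.array([[0.8]]))
        wi = 150.0
        phi = lognormal_selectivity(2.0, wi, species_one.beta, species_one.sigma)
        expected = 0.8 * 7.0 * 2.0 * phi * 2.0  # theta*d*wp*phi*dw
        got = available_energy(state, toy_grid, im, 0, wi, [species_one])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_available_energy_brute_force(self, species_one, resource_one, toy_grid):
        state, im = self._toy_setup(species_one, resource_one, toy_grid)
        wi = 200.0
        expected = 0.0
        for k in range(3):
            phi = lognormal_selectivity(toy_grid.w[k], wi, species_one.beta, species_one.sigma)
            prey = 0.8 * state.NR[0, k] + state.N[0, k]
            expected += prey * toy_grid.w[k] * phi * toy_grid.dw[k]
        got = available_energy(state, toy_grid, im, 0, wi, [species_one])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_predation_mortality_no_predators(self, species_one, toy_grid):
        state = ModelState(N=np.zeros((1, 3)), NR=np.zeros((1, 3)))
        im = InteractionMatrix(theta_iR=np.array([[0.8]]))
        mu = predation_mortality(
            state, toy_grid, im, "resource", 0, 1.0, [species_one],
            feeding_levels=np.zeros((1, 3)), gammas=np.array([1e-3]),
        )
        assert mu == 0.0

    def test_predation_mortality_satiated(self, species_one, toy_grid):
        state = ModelState(N=np.array([[1.0, 1.0, 1.0]]), NR=np.zeros((1, 3)))
        im = InteractionMatrix(theta_iR=np.array([[0.8]]))
        mu = predation_mortality(
            state, toy_grid, im, "resource", 0, 1.0, [species_one],
            feeding_levels=np.ones((1, 3)), gammas=np.array([1e-3]),
        )
        assert mu == 0.0

    def test_predation_mortality_brute_force(self, species_one, toy_grid):
        state = ModelState(N=np.array([[0.0, 6.0, 0.0]]), NR=np.zeros((1, 3)))
        im = InteractionMatrix(theta_iR=np.array([[0.8]]))
        f = np.full((1, 3), 0.4)
        gam = 2.5e-3
        wp = 0.02
        sp = species_one
        phi = lognormal_selectivity(wp, toy_grid.w[1], sp.beta, sp.sigma)
        expected = 0.8 * phi * (1 - 0.4) * gam * toy_grid.w[1] ** sp.q * 6.0 * toy_grid.dw[1]
        got = predation_mortality(
            state, toy_grid, im, "resource", 0, wp, [sp],
            feeding_levels=f, gammas=np.array([gam]),
        )
        assert got == pytest.approx(expected, rel=1e-12)


class TestModelRatesOracle:
    """The vectorized rate evaluation must agree term-by-term with a naive
    reimplementation from the elementary functions."""

    def test_rates_match_naive(self, tiny_model):
        m = tiny_model
        state = m.initial_state()
        rng = np.random.default_rng(0)
        sl = m.grid.span("fish")
        state.N[0, sl] = rng.uniform(0.1, 2.0, sl.stop - sl.start)
        rates = m.rates(state)
        sp = m.species[0]
        gam = m.gammas[0]
        w, dw = m.grid.w, m.grid.dw
        im = m.interactions
        for j in range(sl.start, sl.stop, 7):
            wi = w[j]
            E_ava = available_energy(state, m.grid, im, 0, wi, m.species)
            E_enc = encounter_rate(gam, sp.q, wi, E_ava)
            f = feeding_level(E_enc, sp.h, wi, sp.n)
            assert rates.f[0, j] == pytest.approx(f, rel=1e-12)
            e_net = net_energy(f, wi, sp)
            assert rates.e_net[0, j] == pytest.approx(e_net, rel=1e-12, abs=1e-15)
            g = somatic_growth(e_net, maturity_allocation(wi, sp))
            assert rates.g[0, j] == pytest.approx(g, rel=1e-12, abs=1e-15)
            mu_expected = (
                background_mortality(sp)
                + starvation_mortality(f, wi, sp)
                + fishing_mortality(wi, sp)
                + predation_mortality(
                    state, m.grid, im, "species", 0, wi, m.species,
                    feeding_levels=rates.f, gammas=m.gammas,
                )
            )
            assert rates.mu[0, j] == pytest.approx(mu_expected, rel=1e-10)

    def test_egg_production_sum_oracle(self, tiny_model):
        m = tiny_model
        sp = m.species[0]
        state = m.initial_state()
        sl = m.grid.span("fish")
        state.N[0, sl] = 1.5
        rates = m.rates(state)
        w, dw = m.grid.w[sl], m.grid.dw[sl]
        expected = 0.0
        for k in range(w.size):
            psi = maturity_allocation(w[k], sp)
            expected += 1.5 * rates.e_net[0, sl][k] * psi * dw[k]
        expected *= sp.erepro / (2 * sp.w0)
        assert rates.R_phy[0] == pytest.approx(expected, rel=1e-12)
        assert rates.R[0] == pytest.approx(beverton_holt(expected, sp.Rmax), rel=1e-12)

    def test_egg_production_free_function_matches_rates(self, tiny_model):
        from thermospectra.model_core import egg_production

        m = tiny_model
        state = m.initial_state()
        sl = m.grid.span("fish")
        state.N[0, sl] = 0.8
        rates = m.rates(state)
        got = egg_production(state, m.grid, m.species[0], 0, rates.e_net[0, sl])
        assert got == pytest.approx(rates.R_phy[0], rel=1e-12)

    def test_egg_production_scales_with_erepro(self, tiny_model):
        m = tiny_model
        state = m.initial_state()
        sl = m.grid.span("fish")
        state.N[0, sl] = 1.0
        r1 = m.rates(state).R_phy[0]
        m.species[0].erepro *= 2
        r2 = m.rates(state).R_phy[0]
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_psi_zero_means_no_eggs(self, species_one, resource_one):
        sp = species_one.with_(wmat=99.0, m=80.0)  # ogive ~0 below 99 g
        m = Model([sp], [resource_one], bins_per_decade=10)
        state = m.initial_state()
        sl = m.grid.span("fish")
        state.N[0, sl] = 0.0
        state.N[0, sl.start] = 1.0  # only tiny fish
        assert m.rates(state).R_phy[0] == pytest.approx(0.0, abs=1e-9)


class TestRateProperties:
    @settings(max_examples=25, deadline=None)
    @given(
        f=st.floats(0, 1),
        w=st.floats(1e-3, 1e4),
        h=st.floats(1.0, 100.0),
        ks=st.floats(0.1, 20.0),
    )
    def test_nonnegative_rates(self, f, w, h, ks):
        sp = SpeciesParams(
            name="x", w0=1e-4, Wi=2e4, wmat=1e3, h=h, ks=ks, mu0=0.6, Rmax=1e8
        )
        assert net_energy(f, w, sp) >= 0
        assert starvation_mortality(f, w, sp) >= 0
        assert 0 <= maturity_allocation(w, sp) <= 1.0000001
        assert background_mortality(sp) >= 0

    @settings(max_examples=25, deadline=None)
    @given(E=st.floats(0, 1e12), h=st.floats(1.0, 100.0), w=st.floats(1e-3, 1e4))
    def test_feeding_level_bounded(self, E, h, w):
        assert 0.0 <= feeding_level(E, h, w, 0.75) <= 1.0

    def test_total_mortality_is_component_sum(self, tiny_model):
        m = tiny_model
        state = m.initial_state()
        sl = m.grid.span("fish")
        state.N[0, sl] = 0.5
        r = m.rates(state)
        sp = m.species[0]
        w = m.grid.w[sl]
        mu_fis = fishing_mortality(w, sp)
        mu_bac = background_mortality(sp)
        total = mu_bac + r.mu_stv[0, sl] + mu_fis + r.mu_pre[0, sl]
        np.testing.assert_allclose(r.mu[0, sl], total, rtol=1e-12)
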