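"""Coupled opinion-epidemic system: incidence, exchange, splitting, moments."""
import numpy as np
import pytest

from sentipol import calibration
from sentipol.coupled import (
    CompartmentFields,
    ContactFunction,
    epidemic_exchange_step,
    incidence_operator,
    moment_ode_oracle,
    solve_coupled,
)
from sentipol.equilibria import BetaMixtureSpec, BetaSpec, count_modes
from sentipol.grids import DensityField2D, Grid2D
from sentipol.meanfield_fp import solve_single_population
from sentipol.params import OpinionParams
from sentipol.seir import CompartmentMasses, EpidemicParams, integrate_seir, seir_derivatives


@pytest.fixture
def calibrated_setup(square20, positive_mixture, negative_mixture, initial_masses):
    shape = DensityField2D(
        square20,
        np.outer(
            positive_mixture.cell_averages(square20.axis_plus),
            negative_mixture.cell_averages(square20.axis_minus),
        ),
    )
    return {
        "init": CompartmentFields.from_shared_shape(shape, initial_masses),
        "opinions": calibration.compartment_opinion_params(),
        "epidemic": calibration.epidemic_params(),
    }


def _random_fields(grid: Grid2D, masses, seed=0) -> CompartmentFields:
    rng = np.random.default_rng(seed)
    fields = []
    for rho in masses:
        v = rng.random((grid.n_plus, grid.n_minus))
        v *= rho / (v.sum() * grid.cell_area)
        fields.append(DensityField2D(grid, v))
    return CompartmentFields(*fields)


class TestIncidence:
    def test_constant_contact_collapses_to_mass_action(self, square20):
        fields = _random_fields(square20, [0.5, 0.1, 0.2, 0.2])
        k = incidence_operator(fields.f_S, fields.f_I, ContactFunction(beta=1.21))
        expected = 1.21 * fields.f_I.mass * fields.f_S.values
        np.testing.assert_allclose(k.values, expected, atol=1e-14)

    def test_no_spreaders_no_incidence(self, square20):
        fields = _random_fields(square20, [0.9, 0.1, 0.0, 0.0])
        k = incidence_operator(fields.f_S, fields.f_I, ContactFunction(beta=1.21))
        np.testing.assert_array_equal(k.values, 0.0)

    def test_separable_contact_matches_brute_force_quadrature(self):
        grid = Grid2D(8, 8)
        fields = _random_fields(grid, [0.6, 0.1, 0.3, 0.0], seed=3)
        contact = ContactFunction(
            beta=0.8, kind="separable", k_plus=lambda w: 1.0 + w, k_minus=lambda w: w**2
        )
        k = incidence_operator(fields.f_S, fields.f_I, contact)
        # O(n^4) oracle: explicit double loop over cell pairs
        cp, cm = grid.axis_plus.centers, grid.axis_minus.centers
        expected = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                acc = 0.0
                for a in range(8):
                    for b in range(8):
                        acc += 0.8 * (1 + cp[a]) * cm[b] ** 2 * fields.f_I.values[a, b]
                expected[i, j] = fields.f_S.values[i, j] * acc * grid.cell_area
        np.testing.assert_allclose(k.values, expected, atol=1e-12)

    def test_grid_mismatch_rejected(self, square20):
        a = _random_fields(square20, [0.5, 0.2, 0.2, 0.1])
        b = _random_fields(Grid2D(10, 10), [0.5, 0.2, 0.2, 0.1])
        with pytest.raises(ValueError):
            incidence_operator(a.f_S, b.f_I, ContactFunction(beta=1.0))


class TestExchange:
    def test_total_mass_conserved_to_round_off(self, square20):
        fields = _random_fields(square20, [0.5, 0.2, 0.2, 0.1])
        params = EpidemicParams(beta=1.21)
        out = epidemic_exchange_step(fields, params, dt=0.05)
        assert out.total_mass == pytest.approx(fields.total_mass, abs=1e-13)

    def test_without_contact_susceptibles_frozen_and_exposed_decay(self, square20):
        fields = _random_fields(square20, [0.5, 0.2, 0.2, 0.1])
        out = epidemic_exchange_step(fields, EpidemicParams(beta=0.0, zeta=1.0), dt=0.01)
        np.testing.assert_array_equal(out.f_S.values, fields.f_S.values)
        np.testing.assert_allclose(
            out.f_E.values, fields.f_E.values * (1 - 0.01), atol=1e-15
        )

    def test_masses_advance_exactly_like_explicit_euler_on_the_ode(self, square20):
        fields = _random_fields(square20, [0.5, 0.2, 0.2, 0.1])
        params = EpidemicParams(beta=1.21, zeta=1.0, gamma=1.0)
        dt = 0.02
        out = epidemic_exchange_step(fields, params, dt)
        rho0 = fields.masses().as_array()
        expected = rho0 + dt * seir_derivatives(rho0, params)
        np.testing.assert_allclose(out.masses().as_array(), expected, atol=1e-13)

    def test_oversized_step_raises(self, square20):
        fields = _random_fields(square20, [0.5, 0.2, 0.2, 0.1])
        with pytest.raises(RuntimeError, match="dt"):
            epidemic_exchange_step(fields, EpidemicParams(beta=1.0, zeta=5.0), dt=0.5)


class TestCoupledSolve:
    def test_reduces_to_single_population_when_epidemic_off(self, square20, product_beta22):
        params = OpinionParams(0.05, 0.05, 0.12, 0.12)
        masses = CompartmentMasses(0.4, 0.3, 0.2, 0.1)
        init = CompartmentFields.from_shared_shape(product_beta22, masses)
        res_c = solve_coupled(
            init,
            {c: params for c in "SEIR"},
            EpidemicParams(beta=0.0, zeta=1.0, gamma=1.0),
            t_final=2.0,
            dt=0.05,
        )
        res_s = solve_single_population(product_beta22, params, t_final=2.0, dt=0.05)
        total = sum(f.values for f in res_c.fields[-1].as_dict().values())
        np.testing.assert_allclose(total, res_s.fields[-1].values, atol=1e-12)

    def test_masses_track_the_compartment_ode(self, calibrated_setup):
        res = solve_coupled(
            calibrated_setup["init"],
            calibrated_setup["opinions"],
            calibrated_setup["epidemic"],
            t_final=1.0,
            dt=1e-3,
        )
        ode = integrate_seir(
            calibrated_setup["epidemic"], calibration.initial_masses(), 1.0, 1e-4,
            store_every=10,
        )
        # compare at shared times
        idx = np.searchsorted(ode.times, res.times)
        idx = np.clip(idx, 0, len(ode.times) - 1)
        assert np.abs(res.moments.masses - ode.masses[idx]).max() < 1e-3

    def test_moments_match_the_closed_ode_oracle(self, calibrated_setup, product_beta22):
        """Whole-system cross-check: kinetic masses and means against the
        closed (rho_J, rho_J m_J) ODE system for constant contact.

        Uses a smooth shared initial shape: moment quadrature on the coarse
        mesh is only faithful for resolved (non-boundary-singular) profiles.
        """
        init = CompartmentFields.from_shared_shape(
            product_beta22, calibration.initial_masses()
        )
        res = solve_coupled(
            init,
            calibrated_setup["opinions"],
            calibrated_setup["epidemic"],
            t_final=20.0,
            dt=0.05,
        )
        mo = res.moments
        m0p = mo.means_plus[0]
        m0m = mo.means_minus[0]
        oracle = moment_ode_oracle(
            calibrated_setup["epidemic"],
            calibrated_setup["opinions"],
            calibration.initial_masses(),
            m0p,
            m0m,
            20.0,
            times=mo.times,
        )
        assert np.abs(mo.masses - oracle.masses).max() < 5e-3
        assert np.nanmax(np.abs(mo.means_plus - oracle.means_plus)) < 1e-6
        assert np.nanmax(np.abs(mo.means_minus - oracle.means_minus)) < 1e-6

    def test_global_means_conserved_for_compartment_independent_rates(
        self, square20, product_beta22
    ):
        params = OpinionParams(0.05, 0.05, 0.15, 0.15)
        init = CompartmentFields.from_shared_shape(product_beta22, calibration.initial_masses())
        res = solve_coupled(
            init, {c: params for c in "SEIR"}, EpidemicParams(beta=1.21), t_final=50.0, dt=0.05
        )
        mo = res.moments
        assert np.abs(mo.m_plus - mo.m_plus[0]).max() < 1e-10
        assert np.abs(mo.m_minus - mo.m_minus[0]).max() < 1e-10

    def test_bimodal_negative_marginal_during_active_spreading(self, calibrated_setup):
        """In the calibrated run the negative marginal keeps its two-peak
        structure (boundary spike + interior bump) through the spreading phase."""
        res = solve_coupled(
            calibrated_setup["init"],
            calibrated_setup["opinions"],
            calibrated_setup["epidemic"],
            t_final=4.0,
            dt=0.05,
        )
        h = res.fields[-1].total_marginal_minus().normalized()
        n_modes, locations = count_modes(h)
        assert n_modes == 2
        assert locations[0] < 0.05
        assert 0.35 < locations[1] < 0.7

    def test_long_time_marginal_is_the_shared_mean_two_beta_mixture(self, calibrated_setup):
        """Terminally the negative marginal is a two-Beta mixture whose
        components share the global mean and whose weights are the final-size
        split (rho_S_inf, 1 - rho_S_inf)."""
        res = solve_coupled(
            calibrated_setup["init"],
            calibrated_setup["opinions"],
            calibrated_setup["epidemic"],
            t_final=191.0,
            dt=0.05,
        )
        mo = res.moments
        h = res.fields[-1].total_marginal_minus().normalized()
        m_inf = mo.m_minus[-1]
        ops = calibrated_setup["opinions"]
        rho_s = mo.masses[-1][0]
        rho_r = mo.masses[-1][3]
        mix = BetaMixtureSpec(
            rho_s / (rho_s + rho_r),
            BetaSpec(m_inf, ops["S"].equilibrium_ratio("minus")),
            BetaSpec(m_inf, ops["R"].equilibrium_ratio("minus")),
        )
        l1 = np.abs(h.values - mix.cell_averages(h.grid)).sum() * h.grid.dw
        assert l1 < 5e-2

    def test_moment_oracle_long_time_identities(self, calibrated_setup):
        """For large times the S and R mean opinions converge to a common value."""
        oracle = moment_ode_oracle(
            calibrated_setup["epidemic"],
            calibrated_setup["opinions"],
            calibration.initial_masses(),
            np.full(4, 0.4),
            np.full(4, 0.3),
            800.0,
            times=np.linspace(0.0, 800.0, 81),
        )
        assert abs(oracle.means_minus[-1][0] - oracle.means_minus[-1][3]) < 1e-3
        assert abs(oracle.means_plus[-1][0] - oracle.means_plus[-1][3]) < 1e-3

    def test_moment_oracle_conserves_global_mean_for_equal_rates(self):
        params = OpinionParams(0.05, 0.05, 0.15, 0.15)
        oracle = moment_ode_oracle(
            EpidemicParams(beta=1.21),
            {c: params for c in "SEIR"},
            CompartmentMasses(0.9, 0.05, 0.025, 0.025),
            np.full(4, 0.4),
            np.full(4, 0.3),
            50.0,
        )
        assert np.abs(oracle.m_plus - 0.4).max() < 1e-9
        assert np.abs(oracle.m_minus - 0.3).max() < 1e-9
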