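import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from solvscreen.sigma import (ContactParams, SigmaProfile, hbond_energy,
                              mean_interaction_energies, misfit_energy,
                              residual_chemical_potential,
                              solve_sigma_potential, vdw_energy, DEFAULT_GRID,
                              R_KCAL)
from solvscreen.synthetic import generate_toy_sigma_profiles

ZERO = ContactParams(a_eff=1.0, alpha_prime=0.0, c_hb=0.0, sigma_hb=0.0)
SMALL = ContactParams(a_eff=1.0, alpha_prime=50.0, c_hb=80.0, sigma_hb=0.008)


class TestPairEnergies:
    def test_misfit_direct_arithmetic(self):
        p = ContactParams(a_eff=1.0, alpha_prime=2.0)
        assert misfit_energy(0.01, 0.01, p) == pytest.approx(4e-4)

    def test_misfit_screened_contact_is_zero(self):
        p = ContactParams(a_eff=3.0, alpha_prime=7.0)
        assert misfit_energy(0.013, -0.013, p) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=60)
    @given(s=st.floats(-0.03, 0.03), sp=st.floats(-0.03, 0.03))
    def test_misfit_symmetric_nonnegative(self, s, sp):
        p = ContactParams(a_eff=2.0, alpha_prime=5.0)
        assert misfit_energy(s, sp, p) >= 0.0
        assert misfit_energy(s, sp, p) == pytest.approx(misfit_energy(sp, s, p))

    def test_hbond_adopted_form(self):
        p = ContactParams(a_eff=1.0, c_hb=1.0, sigma_hb=0.008)
        assert hbond_energy(-0.02, 0.02, p) == pytest.approx(-1.44e-4)

    def test_hbond_zero_cases(self):
        p = ContactParams(a_eff=1.0, c_hb=1.0, sigma_hb=0.008)
        assert hbond_energy(0.0, 0.0, p) == 0.0            # apolar
        assert hbond_energy(-0.008, 0.03, p) == 0.0        # donor at threshold
        assert hbond_energy(-0.03, 0.008, p) == 0.0        # acceptor at threshold

    @settings(derandomize=True, max_examples=60)
    @given(s=st.floats(-0.03, 0.03), sp=st.floats(-0.03, 0.03))
    def test_hbond_attractive_and_symmetric(self, s, sp):
        p = ContactParams(a_eff=1.0, c_hb=2.0, sigma_hb=0.0084)
        assert hbond_energy(s, sp, p) <= 0.0
        assert hbond_energy(s, sp, p) == pytest.approx(hbond_energy(sp, s, p))

    def test_hbond_more_polar_more_negative(self):
        p = ContactParams(a_eff=1.0, c_hb=1.0, sigma_hb=0.008)
        assert hbond_energy(-0.025, 0.025, p) < hbond_energy(-0.015, 0.015, p)

    def test_vdw(self):
        p = ContactParams(a_eff=1.0, tau_vdw={"C": -0.01, "O": -0.02, "H": 0.0})
        assert vdw_energy("C", "O", p) == pytest.approx(-0.03)
        assert vdw_energy("O", "C", p) == pytest.approx(vdw_energy("C", "O", p))
        assert vdw_energy("H", "H", p) == 0.0
        with pytest.raises(KeyError, match="N"):
            vdw_energy("C", "N", p)


class TestSigmaPotential:
    def test_zero_energy_fixed_point_is_zero(self):
        prof = generate_toy_sigma_profiles(3, seed=0)[2]
        for t in (298.15, 596.3):
            pot = solve_sigma_potential(prof, ZERO, t)
            assert pot.converged
            assert np.allclose(pot.mu, 0.0, atol=1e-10)

    def test_misfit_only_symmetric_profile_even_mu(self):
        prof = generate_toy_sigma_profiles(1, seed=0)[0]  # symmetric apolar
        params = ContactParams(a_eff=1.0, alpha_prime=50.0, c_hb=0.0)
        pot = solve_sigma_potential(prof, params, 298.15)
        assert pot.converged
        assert np.allclose(pot.mu, pot.mu[::-1], atol=1e-7)

    def test_idempotent_at_fixed_point(self):
        prof = generate_toy_sigma_profiles(2, seed=1)[1]
        pot = solve_sigma_potential(prof, SMALL, 298.15)
        assert pot.converged
        # one more sweep from the converged mu changes nothing beyond tol
        from solvscreen.sigma import _pair_energy_matrix
        from scipy.special import logsumexp
        rt = R_KCAL * 298.15
        w = prof.weights()
        arg = (SMALL.a_eff * pot.mu[None, :] - _pair_energy_matrix(prof.grid, SMALL)) / rt \
            + np.log(w)[None, :]
        mu_next = -(rt / SMALL.a_eff) * logsumexp(arg, axis=1)
        assert np.max(np.abs(mu_next - pot.mu)) < 1e-6

    def test_nonconvergence_flagged(self):
        prof = generate_toy_sigma_profiles(2, seed=1)[1]
        pot = solve_sigma_potential(prof, SMALL, 298.15, max_iter=2)
        assert not pot.converged


class TestResidualPotential:
    def test_zero_mu_gives_zero_for_any_profile(self):
        profs = generate_toy_sigma_profiles(4, seed=2)
        pot = solve_sigma_potential(profs[0], ZERO, 298.15)
        for p in profs:
            assert residual_chemical_potential(p, pot) == pytest.approx(0.0, abs=1e-9)

    def test_single_bin_solute_collapses_integral(self):
        prof = generate_toy_sigma_profiles(2, seed=3)[1]
        pot = solve_sigma_potential(prof, SMALL, 298.15)
        p = np.zeros_like(DEFAULT_GRID)
        p[30] = 2.5  # 2.5 A^2 in one bin
        solute = SigmaProfile(DEFAULT_GRID, p)
        assert residual_chemical_potential(solute, pot) == pytest.approx(2.5 * pot.mu[30])

    def test_grid_mismatch_rejected(self):
        prof = generate_toy_sigma_profiles(1, seed=0)[0]
        pot = solve_sigma_potential(prof, ZERO, 298.15)
        other = SigmaProfile(np.linspace(-0.02, 0.02, 41), np.ones(41))
        with pytest.raises(ValueError, match="grid"):
            residual_chemical_potential(other, pot)


class TestMeanInteractionEnergies:
    def test_zero_params_zero_energies(self):
        prof = generate_toy_sigma_profiles(2, seed=4)[1]
        pot = solve_sigma_potential(prof, ZERO, 298.15)
        assert mean_interaction_energies(prof, pot, ZERO) == (0.0, 0.0, 0.0)

    def test_misfit_only_has_no_hb_component(self):
        prof = generate_toy_sigma_profiles(2, seed=4)[1]
        params = ContactParams(a_eff=1.0, alpha_prime=50.0, c_hb=0.0)
        pot = solve_sigma_potential(prof, params, 298.15)
        e_mf, e_hb, e_vdw = mean_interaction_energies(prof, pot, params)
        assert e_mf > 0.0 and e_hb == 0.0 and e_vdw == 0.0

    def test_sign_conventions(self):
        prof = generate_toy_sigma_profiles(2, seed=5)[1]
        pot = solve_sigma_potential(prof, SMALL, 298.15)
        e_mf, e_hb, _ = mean_interaction_energies(prof, pot, SMALL)
        assert e_mf >= 0.0 and e_hb <= 0.0

    def test_unconverged_potential_refused(self):
        prof = generate_toy_sigma_profiles(2, seed=5)[1]
        pot = solve_sigma_potential(prof, SMALL, 298.15, max_iter=2)
        with pytest.raises(ValueError, match="not converged"):
            mean_interaction_energies(prof, pot, SMALL)


class TestProfileValidation:
    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            SigmaProfile(np.array([0.0, 0.01, 0.03]), np.ones(3))  # non-uniform
        with pytest.raises(ValueError):
            SigmaProfile(DEFAULT_GRID, -np.ones(61))
        with pytest.raises(ValueError):
            SigmaProfile(DEFAULT_GRID, np.zeros(61))
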