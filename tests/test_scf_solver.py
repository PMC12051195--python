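"""Bulk thermodynamics and the Picard slit solver."""

import numpy as np
import pytest

import padft
from padft.scf_solver import picard_step, solve_bulk, solve_slit

M_TO_A3 = 6.02214076e-4


class TestBulk:
    def test_debye_length_182mM_monovalent(self, bulk_simple_182):
        assert bulk_simple_182.lambda_D == pytest.approx(7.1, rel=1e-2)

    def test_debye_length_uses_all_charged_monomers(self):
        arch = padft.build_linear_alternating(11, +1)
        bulk = solve_bulk(padft.SystemParams(arch, c_salt=0.182))
        n_mono = 22 * 0.182 * M_TO_A3
        expected = 1.0 / np.sqrt(4 * np.pi * 7.161447 * n_mono)
        assert bulk.lambda_D == pytest.approx(expected, rel=1e-4)

    def test_11mer_monomer_concentration_is_2M_per_sign(self):
        arch = padft.build_linear_alternating(11, +1)
        bulk = solve_bulk(padft.SystemParams(arch, c_salt=0.182))
        per_sign_M = bulk.n_monomer / 2 / M_TO_A3
        assert per_sign_M == pytest.approx(11 * 0.182, rel=1e-12)

    def test_pressure_reduces_to_ideal_for_small_monomers(self):
        arch = padft.build_linear_alternating(5, +1, b=4.0, d=1e-3)
        bulk = solve_bulk(padft.SystemParams(arch, c_salt=0.182))
        assert bulk.p_b == pytest.approx(2 * 0.182 * M_TO_A3, rel=1e-6)

    def test_chemical_potentials_equal_by_symmetry(self, bulk_simple_182):
        assert bulk_simple_182.mu_plus == bulk_simple_182.mu_minus

    def test_rejects_zero_concentration(self):
        arch = padft.build_linear_alternating(1, +1)
        with pytest.raises(ValueError):
            solve_bulk(padft.SystemParams(arch, c_salt=0.0))


class TestPicardStep:
    def test_converged_state_is_a_fixed_point(self, state_simple_h30,
                                               bulk_simple_182):
        new, diag = picard_step(state_simple_h30, bulk_simple_182, alpha=0.05)
        assert diag["max_rel_change"] < 1e-6
        np.testing.assert_allclose(new.n_si, state_simple_h30.n_si, rtol=1e-6)

    def test_small_alpha_leaves_state_nearly_unchanged(self, state_simple_h30,
                                                       bulk_simple_182):
        new, _ = picard_step(state_simple_h30, bulk_simple_182, alpha=1e-6)
        np.testing.assert_allclose(new.n_si, state_simple_h30.n_si, rtol=1e-5)

    def test_rejects_bad_alpha(self, state_simple_h30, bulk_simple_182):
        with pytest.raises(ValueError):
            picard_step(state_simple_h30, bulk_simple_182, alpha=0.0)


class TestSolveSlit:
    def test_uncharged_walls_recover_bulk_densities(self):
        arch = padft.build_linear_alternating(1, +1, b=4.0, d=4.0)
        params = padft.SystemParams(arch, c_salt=0.182, sigma=0.0)
        bulk = solve_bulk(params)
        grid = padft.Grid(h=60.0, dz=0.25, d=4.0, b=4.0)
        st = solve_slit(params, grid, bulk)
        mid = grid.n_nodes // 2
        assert st.n_tot[mid] == pytest.approx(bulk.n_monomer, rel=1e-6)
        assert abs(st.psi_D - 0.0) < 1e-12
        assert st.psi[mid] == pytest.approx(0.0, abs=1e-12)

    def test_interacting_chains_recover_bulk_midslit(self):
        # grand-canonical consistency for r=5 at eta_b ~ 0.037
        arch = padft.build_linear_alternating(5, +1, b=4.0, d=4.0)
        params = padft.SystemParams(arch, c_salt=0.182, sigma=0.0)
        bulk = solve_bulk(params)
        grid = padft.Grid(h=120.0, dz=0.25, d=4.0, b=4.0)
        st = solve_slit(params, grid, bulk)
        mid = grid.n_nodes // 2
        assert st.n_tot[mid] == pytest.approx(bulk.n_monomer, rel=1e-7)

    def test_convergence_tolerances_met(self, state_simple_h30):
        assert state_simple_h30.converged
        assert state_simple_h30.max_rel_change < 1e-7
        assert abs(state_simple_h30.residual) < 1e-8

    def test_profiles_mirror_symmetric(self, state_simple_h30):
        n = state_simple_h30.n_tot
        np.testing.assert_allclose(n, n[::-1], rtol=1e-9)

    def test_densities_vanish_in_exclusion_zones(self, state_simple_h30):
        out = ~state_simple_h30.grid.accessible
        assert np.all(state_simple_h30.n_tot[out] == 0.0)

    def test_counterions_enriched_coions_depleted(self, state_simple_h30,
                                                  bulk_simple_182):
        i0 = state_simple_h30.grid.i_contact
        assert state_simple_h30.n_plus[i0] > bulk_simple_182.n_chain
        assert state_simple_h30.n_minus[i0] < bulk_simple_182.n_chain

    def test_repeated_runs_bit_identical(self, params_simple_182,
                                         bulk_simple_182):
        grid = padft.Grid(h=20.0, dz=0.25, d=4.0, b=4.0)
        a = solve_slit(params_simple_182, grid, bulk_simple_182)
        b = solve_slit(params_simple_182, grid, bulk_simple_182)
        assert np.array_equal(a.n_si, b.n_si)
        assert a.psi_D == b.psi_D

    def test_warm_start_reaches_same_fixed_point(self, params_simple_182,
                                                 bulk_simple_182):
        grid = padft.Grid(h=24.0, dz=0.25, d=4.0, b=4.0)
        cold = solve_slit(params_simple_182, grid, bulk_simple_182)
        # warm start from a deliberately perturbed copy of the solution
        from dataclasses import replace
        warm0 = replace(cold, n_si=cold.n_si * 1.3, converged=False)
        warm = solve_slit(params_simple_182, grid, bulk_simple_182,
                          initial=warm0)
        np.testing.assert_allclose(warm.n_si, cold.n_si, rtol=1e-5,
                                   atol=1e-30)
        assert warm.psi_D == pytest.approx(cold.psi_D, abs=1e-5)

    def test_grid_architecture_mismatch_rejected(self, params_simple_182):
        grid = padft.Grid(h=20.0, dz=0.25, d=2.0, b=2.0)
        with pytest.raises(ValueError):
            solve_slit(params_simple_182, grid)

    def test_partition_ratio_grid_converged_at_default_spacing(self):
        # halving dz from the 0.25 Å default leaves the 1 mM slit partition
        # ratio unchanged well beyond the convergence tolerance
        arch = padft.build_linear_alternating(1, +1, b=4.0, d=4.0)
        params = padft.SystemParams(arch, c_salt=1e-3)
        bulk = solve_bulk(params)
        from padft.analysis import chain_partition_ratio
        ratios = []
        for dz in (0.25, 0.125):
            grid = padft.Grid(h=108.0, dz=dz, d=4.0, b=4.0)
            st = solve_slit(params, grid, bulk)
            ratios.append(chain_partition_ratio(st).ratio)
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-3)

    def test_point_ion_limit_matches_gouy_chapman_near_wall(self):
        # analytic single-wall solution over the first 3 lambda_D of a wide slit
        arch = padft.build_linear_alternating(1, +1, b=0.25, d=0.25)
        params = padft.SystemParams(arch, c_salt=0.182)
        bulk = solve_bulk(params)
        grid = padft.Grid(h=80.0, dz=0.125, d=0.25, b=0.25)
        st = solve_slit(params, grid, bulk)

        l_B, sigma = params.l_B, params.sigma
        kappa = 1.0 / bulk.lambda_D
        psi_s = 2.0 * np.arcsinh(2 * np.pi * l_B * sigma / kappa)
        gamma = np.tanh(psi_s / 4.0)
        z0 = grid.d / 2
        sel = (grid.z >= z0) & (grid.z <= z0 + 3 * bulk.lambda_D)
        psi_gc = 4.0 * np.arctanh(gamma * np.exp(-kappa * (grid.z[sel] - z0)))
        dpsi = st.psi[sel] - st.psi[sel][-1] + psi_gc[-1]  # match far offset
        np.testing.assert_allclose(dpsi, psi_gc, rtol=1e-2, atol=5e-3)
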