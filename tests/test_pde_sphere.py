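"""Radial solvers: analytic oracles, conservation, limits and couplings."""

import numpy as np
import pytest

from dropfrap import (
    BoundaryTrace,
    ModelParams,
    RadialField,
    RadialGrid,
    average_recovery,
    sample_boundary,
    solve_full_model,
    solve_inside_dirichlet,
    solve_sharp_interface,
)
from dropfrap.model_core import phi_tot_profile


def constant_bc(value, t0=0.0, t1=1e9):
    return BoundaryTrace(np.array([t0, t1]), np.array([value, value]))


def eigen_series(r, t, D=1.0, R=1.0, n_terms=200):
    """Closed-form recovery in a sphere: c=0 initially, c=1 at the boundary."""
    n = np.arange(1, n_terms + 1)[:, None]
    r = np.atleast_1d(r)[None, :]
    s = ((-1.0) ** n / n) * np.sin(n * np.pi * r / R) * np.exp(
        -(n**2) * np.pi**2 * D * t / R**2
    )
    return 1.0 + (2 * R / (np.pi * r)) * s.sum(axis=0)


class TestInsideDirichlet:
    def test_matches_eigenfunction_series(self):
        grid = RadialGrid.uniform(1.0, 300)
        f = solve_inside_dirichlet(
            1.0, 0.0, constant_bc(1.0), grid, np.array([0.0, 0.01, 0.1, 0.5]),
            n_steps=1000,
        )
        for k, t in enumerate([0.01, 0.1, 0.5], start=1):
            sup = np.max(np.abs(f.values[k] - eigen_series(grid.centers, t)))
            assert sup < 1e-3

    def test_stationary_state_preserved(self):
        grid = RadialGrid.uniform(2.0, 50)
        f = solve_inside_dirichlet(0.5, 0.7, constant_bc(0.7), grid,
                                   np.linspace(0, 10, 5))
        np.testing.assert_allclose(f.values, 0.7, rtol=1e-12)

    def test_zero_everywhere_stays_zero(self):
        grid = RadialGrid.uniform(2.0, 50)
        f = solve_inside_dirichlet(0.5, 0.0, constant_bc(0.0), grid,
                                   np.linspace(0, 10, 5))
        np.testing.assert_allclose(f.values, 0.0, atol=1e-15)

    def test_comparison_principle(self):
        """Pointwise larger boundary data gives a pointwise larger solution."""
        grid = RadialGrid.uniform(1.0, 80)
        times = np.linspace(0, 0.5, 20)
        t_bc = np.linspace(0, 0.5, 10)
        lo = BoundaryTrace(t_bc, 0.5 * (1 - np.exp(-5 * t_bc)))
        hi = BoundaryTrace(t_bc, 0.8 * (1 - np.exp(-4 * t_bc)) + 0.05)
        f_lo = solve_inside_dirichlet(1.0, 0.0, lo, grid, times)
        f_hi = solve_inside_dirichlet(1.0, 0.0, hi, grid, times)
        assert np.all(f_hi.values - f_lo.values >= -1e-9)

    def test_rejects_uncovered_times_and_bad_d(self):
        grid = RadialGrid.uniform(1.0, 20)
        short = BoundaryTrace(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            solve_inside_dirichlet(1.0, 0.0, short, grid, np.array([0.0, 2.0]))
        with pytest.raises(ValueError):
            solve_inside_dirichlet(-1.0, 0.0, short, grid, np.array([0.0, 0.5]))


class TestFullModel:
    def test_equilibrium_is_fixed_point(self, green_params):
        p = green_params
        grid = RadialGrid.refined(p.L, p.R, p.ell)
        times = np.array([0.0, p.R**2 / p.D_in])
        f = solve_full_model(p, lambda r: phi_tot_profile(r, p), grid, times)
        rel = np.abs(f.values[-1] / f.values[0] - 1)
        assert rel.max() < 1e-6

    def test_mass_conserved_after_full_bleach(self, green_params):
        p = green_params
        grid = RadialGrid.refined(p.L, p.R, p.ell)
        times = np.linspace(0.0, 1000.0, 6)
        f = solve_full_model(
            p, lambda r: np.where(r > p.R, p.phi_out, 0.0), grid, times
        )
        m = f.total_mass()
        drift_per_time = np.abs(m / m[0] - 1).max() / times[-1]
        assert drift_per_time < 1e-8
        assert f.values.min() >= -1e-9 * f.values.max()

    def test_homogeneous_case_matches_explicit_euler_oracle(self):
        """P = 1 collapses to plain closed-sphere diffusion; brute-force check."""
        D = 0.5
        p = ModelParams(D_in=D, D_out=D, R=1.0, ell=0.02, L=2.0,
                        phi_in=0.05, phi_out=0.05)
        grid = RadialGrid.uniform(2.0, 60)
        times = np.array([0.0, 0.1, 0.4])
        init = lambda r: 0.05 * (1 + np.cos(np.pi * r / 2.0))
        f = solve_full_model(p, init, grid, times, n_steps=800)

        # explicit-Euler finite volumes on a 10x finer grid
        n = 600
        faces = np.linspace(0, 2.0, n + 1)
        r = 0.5 * (faces[:-1] + faces[1:])
        vol = (faces[1:] ** 3 - faces[:-1] ** 3) / 3
        area = faces[1:-1] ** 2
        c = init(r)
        dt = 0.2 * (faces[1] - faces[0]) ** 2 / D
        t = 0.0
        results = [c.copy()]
        for target in times[1:]:
            while t < target - 1e-12:
                step = min(dt, target - t)
                flux = -D * area * np.diff(c) / np.diff(r)
                dc = np.zeros_like(c)
                dc[:-1] -= flux
                dc[1:] += flux
                c = c + step * dc / vol
                t += step
            results.append(c.copy())
        for k in (1, 2):
            ours = f.interp_r(r)[k]
            rel = np.linalg.norm(ours - results[k]) / np.linalg.norm(results[k])
            assert rel < 1e-3

    def test_full_bleach_relaxes_to_scaled_equilibrium(self):
        """c_u -> alpha * phi_tot uniformly, alpha = unbleached/total mass."""
        p = ModelParams.from_p(D_in=0.1, D_out=1.0, R=2.0, P=5.0, ell=0.04, L=20.0)
        grid = RadialGrid.refined(p.L, p.R, p.ell, dr_coarse=p.L / 250)
        tau = p.P * p.R**2 / (3 * p.D_out)
        times = np.array([0.0, 50 * tau])
        init = lambda r: np.where(r > p.R, p.phi_out, 0.0)
        f = solve_full_model(p, init, grid, times, n_steps=600)
        phi = phi_tot_profile(grid.centers, p)
        alpha = (f.values[0] @ grid.volumes) / (phi @ grid.volumes)
        np.testing.assert_allclose(f.values[-1], alpha * phi, rtol=1e-3)
        assert alpha > 0.9  # L >> R: most material is unbleached

    def test_unresolved_interface_rejected(self, green_params):
        grid = RadialGrid.uniform(green_params.L, 50)  # dr = 1 um >> ell
        with pytest.raises(ValueError, match="resolve"):
            solve_full_model(green_params, 0.0, grid, np.array([0.0, 1.0]))


class TestSharpInterface:
    def test_p_equal_one_is_continuous_single_domain(self):
        D = 0.3
        p = ModelParams(D_in=D, D_out=D, R=1.0, ell=0.01, L=3.0,
                        phi_in=0.05, phi_out=0.05)
        times = np.array([0.0, 0.2, 1.0])
        f = solve_sharp_interface(p, 0.0, 0.05, times=times, n_in=60, n_out=120)
        # homogeneous closed-sphere reference on the same physics
        grid = RadialGrid.uniform(3.0, 240)
        ref = solve_full_model(
            ModelParams(D_in=D, D_out=D, R=1.0, ell=0.05, L=3.0,
                        phi_in=0.05, phi_out=0.05),
            lambda r: np.where(r > 1.0, 0.05, 0.0), grid, times, n_steps=800,
        )
        ours = f.interp_r(np.linspace(0.05, 2.9, 80))
        theirs = ref.interp_r(np.linspace(0.05, 2.9, 80))
        for k in (1, 2):
            assert np.max(np.abs(ours[k] - theirs[k])) < 1e-3
        # continuity across R (both adjacent cells on the same smooth curve)
        c = f.grid.centers
        i = np.searchsorted(c, 1.0)
        jump = abs(f.values[-1, i] - f.values[-1, i - 1])
        assert jump < 2 * abs(f.values[-1, i + 1] - f.values[-1, i]) + 1e-9

    def test_quasi_static_outside_approaches_dirichlet_limit(self):
        """Fast outside diffusion pins the interface at P * c_infinity."""
        c_inf = 0.002
        p = ModelParams(D_in=0.01, D_out=500.0, R=5.0, ell=0.05, L=100.0,
                        phi_in=0.3, phi_out=c_inf)
        times = np.linspace(0.0, 1500.0, 8)
        f = solve_sharp_interface(p, 0.0, c_inf, times=times, n_in=150, n_out=300)
        grid_in = RadialGrid.uniform(p.R, 150)
        ref = solve_inside_dirichlet(
            p.D_in, 0.0, constant_bc(p.P * c_inf), grid_in, times, n_steps=600
        )
        radii = np.linspace(0.1, p.R - 0.1, 50)
        ours = f.interp_r(radii)
        theirs = ref.interp_r(radii)
        rel = np.linalg.norm(ours[-1] - theirs[-1]) / np.linalg.norm(theirs[-1])
        assert rel < 0.02

    def test_interface_flux_continuity(self, green_params):
        """The discrete flux through the face at R is single-valued."""
        p = green_params
        times = np.array([0.0, 500.0, 5000.0])
        f = solve_sharp_interface(p, 0.0, p.phi_out, times=times)
        # with a two-point flux there is one flux per face by construction;
        # verify the jump condition c(R-) = P c(R+) via near-face cells
        c = f.grid.centers
        i = np.searchsorted(c, p.R)
        ratio = f.values[-1, i - 1] / f.values[-1, i]
        assert ratio == pytest.approx(p.P, rel=0.05)

    def test_p_below_one_rejected(self):
        with pytest.raises(ValueError):
            ModelParams.from_p(D_in=0.1, D_out=0.1, R=1.0, P=0.5)


class TestReductions:
    def test_average_recovery_uniform_field(self):
        grid = RadialGrid.uniform(2.0, 40)
        f = RadialField(grid, np.array([0.0]), np.full((1, 40), 0.7))
        assert average_recovery(f, 1.5)[0] == pytest.approx(0.7)

    def test_average_recovery_full_bleach_is_zero(self, green_params):
        p = green_params
        grid = RadialGrid.refined(p.L, p.R, p.ell)
        f = solve_full_model(
            p, lambda r: np.where(r > p.R, p.phi_out, 0.0), grid,
            np.array([0.0, 1.0])
        )
        assert average_recovery(f, p.R - 3 * p.ell)[0] == pytest.approx(0.0, abs=1e-12)

    def test_average_recovery_outside_grid_rejected(self):
        grid = RadialGrid.uniform(2.0, 40)
        f = RadialField(grid, np.array([0.0]), np.zeros((1, 40)))
        with pytest.raises(ValueError):
            average_recovery(f, 3.0)

    def test_sample_boundary_constant_field(self):
        grid = RadialGrid.uniform(5.0, 50)
        f = RadialField(grid, np.array([0.0, 1.0]), np.full((2, 50), 0.4))
        tr = sample_boundary(f, 5.0, margin=1.4)
        np.testing.assert_allclose(tr.values, 0.4)

    def test_sample_boundary_picks_nearest_cell(self):
        grid = RadialGrid.uniform(5.0, 50)
        vals = np.tile(grid.centers, (2, 1))
        f = RadialField(grid, np.array([0.0, 1.0]), vals)
        tr = sample_boundary(f, 5.0, margin=1.4)
        assert abs(tr.values[0] - 3.6) <= 0.05 + 1e-12

    def test_sample_boundary_margin_too_large(self):
        grid = RadialGrid.uniform(5.0, 50)
        f = RadialField(grid, np.array([0.0]), np.zeros((1, 50)))
        with pytest.raises(ValueError):
            sample_boundary(f, 5.0, margin=5.0)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        grid = RadialGrid.uniform(2.0, 20)
        f = RadialField(grid, np.array([0.0, 1.0]),
                        np.arange(40, dtype=float).reshape(2, 20))
        path = tmp_path / "field.csv"
        f.to_csv(path)
        g = RadialField.from_csv(path)
        np.testing.assert_allclose(g.values, f.values)
        np.testing.assert_allclose(g.times, f.times)

    def test_hdf5_round_trip(self, tmp_path):
        grid = RadialGrid.uniform(2.0, 20)
        f = RadialField(grid, np.array([0.0, 1.0]),
                        np.arange(40, dtype=float).reshape(2, 20),
                        phi=np.linspace(0.3, 0.002, 20))
        path = tmp_path / "field.h5"
        f.to_hdf5(path)
        g = RadialField.from_hdf5(path)
        np.testing.assert_allclose(g.values, f.values)
        np.testing.assert_allclose(g.phi, f.phi)
        np.testing.assert_allclose(g.grid.faces, f.grid.faces)
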