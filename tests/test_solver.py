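"""Stochastic Boussinesq integrator: scheme, boundaries, forcing, invariants."""

from dataclasses import replace

import numpy as np
import pytest

from aquasoliton.medium import DimensionlessParameters, dimensionless_velocity
from aquasoliton.soliton import initial_state, soliton_family, stationary_soliton
from aquasoliton.solver import (
    FieldState,
    Grid1D,
    SolverConfig,
    SolverDivergenceError,
    Trajectory,
    apply_boundary,
    flux,
    make_forcing,
    simulate,
    step_maccormack,
)


def model_units_dimless(k1p=0.65, k2p=0.32, alphap=0.215, nuLp=0.0):
    return DimensionlessParameters(
        k1p=k1p, k2p=k2p, alphap=alphap, nuLp=nuLp,
        q_star=1.0, omega_star=1.0, A_star=1.0,
    )


class TestGridConfig:
    def test_default_grid_matches_production_lattice(self):
        g = Grid1D()
        assert g.length == 120.0 and g.dx == 1e-2
        assert g.n_nodes == 12001
        assert g.positions[0] == 0.0 and g.positions[-1] == 120.0

    def test_stability_estimate_admits_production_step(self, case_i):
        cfg = SolverConfig(dimless=case_i.dimless)
        cfl = cfg.check_stability(Grid1D())
        assert cfl < 1.0

    def test_stability_warning_for_oversized_step(self, case_i):
        cfg = SolverConfig(dimless=case_i.dimless, dt=1e-3)
        with pytest.warns(UserWarning, match="unstable"):
            cfg.check_stability(Grid1D())

    def test_noise_std_scalings(self, case_i):
        cfg = SolverConfig(dimless=case_i.dimless, dt=1e-4, noise_enabled=True)
        # literal node-noise reading: nu'/sqrt(dt) at any dx
        assert cfg.noise_std(0.02) == pytest.approx(0.60 / np.sqrt(1e-4))
        pinned = replace(cfg, noise_correlation_length=1e-2)
        assert pinned.noise_std(0.02) == pytest.approx(
            0.60 / np.sqrt(1e-4) * np.sqrt(0.5)
        )


class TestFlux:
    def test_constant_state(self):
        d = model_units_dimless(alphap=0.2)
        grid = Grid1D(length=10.0, dx=0.1)
        c0 = 0.7
        state = FieldState(np.full(grid.n_nodes, c0), np.zeros(grid.n_nodes))
        cfg = SolverConfig(dimless=d, bc="periodic")
        g = flux(state, cfg, grid)
        np.testing.assert_allclose(g, d.k1p * c0 + 0.5 * d.alphap * c0**2, rtol=1e-12)

    def test_zero_state(self, case_i):
        grid = Grid1D(length=10.0, dx=0.1)
        cfg = SolverConfig(dimless=case_i.dimless)
        g = flux(FieldState(np.zeros(grid.n_nodes), np.zeros(grid.n_nodes)), cfg, grid)
        assert np.all(g == 0)

    def test_sinusoid_matches_closed_form(self):
        """For a linear medium, g = (k1 + k2 k^2) sin(kx) to grid accuracy.

        Periodic mode wraps node n-1 to node 0, so the period is
        n*dx and test fields must be built on that period.
        """
        d = model_units_dimless(alphap=1e-300, nuLp=0.0)
        grid = Grid1D(length=8.0, dx=8.0 / 4000)
        period = grid.n_nodes * grid.dx
        k = 2 * np.pi / period
        x = np.arange(grid.n_nodes) * grid.dx
        state = FieldState(np.sin(k * x), np.zeros_like(x))
        cfg = SolverConfig(dimless=d, bc="periodic")
        g = flux(state, cfg, grid)
        expected = (d.k1p + d.k2p * k**2) * np.sin(k * x)
        np.testing.assert_allclose(g, expected, atol=1e-5 * np.max(np.abs(expected)))

    def test_damping_term_uses_continuity(self):
        """The nu' contribution equals -nu' u'_x (central difference)."""
        base = model_units_dimless(nuLp=0.0)
        damped = replace(base, nuLp=0.5)
        grid = Grid1D(length=6.0, dx=0.01)
        period = grid.n_nodes * grid.dx
        x = np.arange(grid.n_nodes) * grid.dx
        u = np.sin(2 * np.pi * x / period)
        state = FieldState(np.zeros_like(x), u)
        g0 = flux(state, SolverConfig(dimless=base, bc="periodic"), grid)
        g1 = flux(state, SolverConfig(dimless=damped, bc="periodic"), grid)
        ux = (np.roll(u, -1) - np.roll(u, 1)) / (2 * grid.dx)
        np.testing.assert_allclose(g1 - g0, -0.5 * ux, atol=1e-12)


class TestForcing:
    def test_disabled_forcing_is_zero(self, case_i):
        cfg = SolverConfig(dimless=case_i.dimless, noise_enabled=False)
        f = make_forcing(cfg, Grid1D(length=1.0, dx=0.1), 10)
        assert np.all(f.h == 0)

    def test_variance_matches_fluctuation_dissipation(self, case_i):
        """Per-node variance -> nu'^2/dt' over 1e6 steps (within 1%)."""
        cfg = SolverConfig(dimless=case_i.dimless, dt=2.5e-5,
                           noise_enabled=True, seed=11)
        grid = Grid1D(length=0.07, dx=0.01)  # 8 nodes
        f = make_forcing(cfg, grid, 1_000_000)
        target = case_i.dimless.nuLp**2 / cfg.dt
        var = f.h.var(axis=0)
        assert np.all(np.abs(var / target - 1) < 0.01)
        assert np.abs(f.h.mean()) < 3 * np.sqrt(target / (1e6 * 8))

    def test_cross_node_independence(self, case_i):
        """Cross-node sample correlation stays below 0.01 over 1e5 steps."""
        cfg = SolverConfig(dimless=case_i.dimless, dt=2.5e-5,
                           noise_enabled=True, seed=5)
        grid = Grid1D(length=0.05, dx=0.01)
        f = make_forcing(cfg, grid, 100_000)
        corr = np.corrcoef(f.h.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.max(np.abs(off)) < 0.01

    def test_simulate_consumes_the_same_stream(self, case_i):
        """The integrator's forcing is the make_forcing stream for its seed."""
        d = replace(case_i.dimless, alphap=1e-12)
        grid = Grid1D(length=2.0, dx=0.1)
        cfg = SolverConfig(dimless=d, dt=1e-4, n_steps=1, save_every=1,
                           noise_enabled=True, seed=123, bc="periodic")
        zero = FieldState(np.zeros(grid.n_nodes), np.zeros(grid.n_nodes))
        traj = simulate(zero, cfg, grid)
        h = make_forcing(cfg, grid, 1, seed=123).h[0]
        stepped = step_maccormack(zero.copy(), cfg, grid, forcing=h)
        np.testing.assert_allclose(traj.u[-1], stepped.u, rtol=0, atol=1e-15)


class TestStepping:
    def test_zero_state_is_fixed_point(self, case_i):
        grid = Grid1D(length=5.0, dx=0.05)
        cfg = SolverConfig(dimless=case_i.dimless, dt=1e-4, n_steps=100, save_every=100)
        traj = simulate(FieldState(np.zeros(grid.n_nodes), np.zeros(grid.n_nodes)), cfg, grid)
        assert np.all(traj.rho[-1] == 0) and np.all(traj.u[-1] == 0)

    def test_kernel_matches_numpy_reference_step(self, case_i):
        """Compiled chunk path and the NumPy step agree to machine precision."""
        grid = Grid1D(length=4.0, dx=0.02)
        x = grid.positions
        rho = -0.5 / np.cosh(x - 2.0) ** 2
        u = 0.3 * rho
        cfg = SolverConfig(dimless=case_i.dimless, dt=1e-4, n_steps=3, save_every=3,
                           noise_enabled=True, seed=99)
        traj = simulate(FieldState(rho.copy(), u.copy()), cfg, grid)
        f = make_forcing(cfg, grid, 3, seed=99)
        s = FieldState(rho.copy(), u.copy())
        for j in range(3):
            s = step_maccormack(s, cfg, grid, forcing=f.h[j], forward_first=(j % 2 == 0))
        np.testing.assert_allclose(traj.rho[-1], s.rho, atol=1e-14)
        np.testing.assert_allclose(traj.u[-1], s.u, atol=1e-14)

    def test_linear_standing_wave_frequency(self):
        """alpha' = nu' = 0: a standing mode oscillates at sqrt(k1 k^2 + k2 k^4)
        within 0.1% over ten periods."""
        d = model_units_dimless(k1p=0.65, k2p=0.32, alphap=1e-300, nuLp=0.0)
        L = 2 * np.pi * 3  # about three wavelengths of k ~ 1
        grid = Grid1D(length=L, dx=L / 384)
        wrap_period = grid.n_nodes * grid.dx  # periodic mode wraps at n*dx
        k = 2 * np.pi * 3 / wrap_period
        omega = np.sqrt(d.k1p * k**2 + d.k2p * k**4)
        period = 2 * np.pi / omega
        dt = 5e-4
        n_steps = int(round(10 * period / dt))
        x = np.arange(grid.n_nodes) * grid.dx
        rho0 = 1e-6 * np.sin(k * x)
        cfg = SolverConfig(dimless=d, dt=dt, n_steps=n_steps,
                           save_every=max(1, n_steps // 400), bc="periodic")
        traj = simulate(FieldState(rho0, np.zeros_like(x)), cfg, grid)
        # project every snapshot on the initial mode and fit the frequency
        amp = traj.rho @ rho0 / (rho0 @ rho0)
        # count zero crossings of the mode amplitude
        sign_change = np.nonzero(np.diff(np.sign(amp)))[0]
        t_cross = []
        for i in sign_change:
            t0, t1 = traj.times[i], traj.times[i + 1]
            a0, a1 = amp[i], amp[i + 1]
            t_cross.append(t0 - a0 * (t1 - t0) / (a1 - a0))
        t_cross = np.array(t_cross)
        half_period = np.polyfit(np.arange(len(t_cross)), t_cross, 1)[0]
        measured = np.pi / half_period
        assert measured == pytest.approx(omega, rel=1e-3)

    def test_divergence_raises_named_error(self, case_i):
        grid = Grid1D(length=4.0, dx=0.02)
        x = grid.positions
        rho = -5.0 / np.cosh((x - 2.0) / 0.2) ** 2
        cfg = SolverConfig(dimless=case_i.dimless, dt=0.5, n_steps=200, save_every=10)
        with pytest.warns(UserWarning), pytest.raises(SolverDivergenceError):
            simulate(FieldState(rho, np.zeros_like(x)), cfg, grid)


class TestBoundaries:
    def test_interior_nodes_unchanged_by_sponge(self, case_i):
        grid = Grid1D(length=20.0, dx=0.05)
        cfg = SolverConfig(dimless=case_i.dimless, sponge_width=40)
        x = grid.positions
        state = FieldState(np.sin(x), np.cos(x))
        out = apply_boundary(state, cfg, grid)
        interior = slice(40, grid.n_nodes - 40)
        np.testing.assert_array_equal(out.rho[interior], state.rho[interior])

    def test_zero_state_fixed_point_of_boundaries(self, case_i):
        grid = Grid1D(length=20.0, dx=0.05)
        for bc in ("sponge", "characteristic"):
            cfg = SolverConfig(dimless=case_i.dimless, bc=bc)
            zero = FieldState(np.zeros(grid.n_nodes), np.zeros(grid.n_nodes))
            out = apply_boundary(zero, cfg, grid)
            assert np.all(out.rho == 0) and np.all(out.u == 0)

    @pytest.mark.parametrize("bc", ["sponge", "characteristic"])
    def test_outgoing_pulse_reflection_below_one_percent(self, bc):
        """A linear rightward pulse leaves the domain; the energy that comes
        back must be < 1% of what went out."""
        d = model_units_dimless(k1p=0.65, k2p=1e-6, alphap=1e-300, nuLp=0.0)
        grid = Grid1D(length=40.0, dx=0.02)
        x = grid.positions
        c = np.sqrt(d.k1p)
        rho0 = np.exp(-((x - 20.0) ** 2) / (2 * 1.5**2))
        u0 = c * rho0  # rightward characteristic only
        dt = 5e-3
        t_out = 25.0 / c  # pulse fully out through the right wall
        cfg = SolverConfig(dimless=d, dt=dt, n_steps=int(t_out / dt),
                           save_every=int(t_out / dt), bc=bc)
        traj = simulate(FieldState(rho0.copy(), u0.copy()), cfg, grid)
        e0 = np.sum(rho0**2)
        e_final = np.sum(traj.rho[-1] ** 2)
        assert e_final / e0 < 0.01

    def test_mass_conserved_with_periodic_boundaries(self, case_i):
        """Flux form: the density integral is conserved to ~roundoff over
        1e4 noiseless steps."""
        grid = Grid1D(length=40.0, dx=0.02)
        st = stationary_soliton(case_i.coefficients, case_i.medium.alpha)
        rho0, u0 = initial_state(st, grid.positions, case_i.dimless, min_clearance_fwhm=5)
        cfg = SolverConfig(dimless=case_i.dimless, dt=2.5e-5, n_steps=10_000,
                           save_every=10_000, bc="periodic")
        traj = simulate(FieldState(rho0.copy(), u0.copy()), cfg, grid)
        m0 = np.sum(rho0) * grid.dx
        m1 = np.sum(traj.rho[-1]) * grid.dx
        assert abs(m1 - m0) / abs(m0) < 1e-8


class TestTrajectory:
    def test_bit_exact_replay(self, case_i):
        grid = Grid1D(length=10.0, dx=0.05)
        st = stationary_soliton(case_i.coefficients, case_i.medium.alpha)
        rho0, u0 = initial_state(st, grid.positions, case_i.dimless,
                                 min_clearance_fwhm=2)
        cfg = SolverConfig(dimless=case_i.dimless, dt=1e-4, n_steps=500,
                           save_every=100, noise_enabled=True, seed=42)
        a = simulate(FieldState(rho0.copy(), u0.copy()), cfg, grid)
        b = simulate(FieldState(rho0.copy(), u0.copy()), cfg, grid)
        np.testing.assert_array_equal(a.rho, b.rho)
        np.testing.assert_array_equal(a.u, b.u)

    def test_hdf5_round_trip(self, case_i, tmp_path):
        grid = Grid1D(length=10.0, dx=0.05)
        cfg = SolverConfig(dimless=case_i.dimless, dt=1e-4, n_steps=10, save_every=5)
        zero = FieldState(np.zeros(grid.n_nodes), np.zeros(grid.n_nodes))
        traj = simulate(zero, cfg, grid)
        path = tmp_path / "traj.h5"
        traj.to_hdf5(path)
        back = Trajectory.from_hdf5(path)
        np.testing.assert_array_equal(back.rho, traj.rho)
        assert back.grid == traj.grid
        assert back.config.dimless.k2p == traj.config.dimless.k2p


class TestAgainstAnalyticSoliton:
    def test_traveling_soliton_richardson_convergence(self, case_i):
        """Error against the exact traveling soliton drops ~4x when dx and dt
        are both halved (second-order scheme)."""
        d = replace(case_i.dimless, nuLp=0.0)
        sol = soliton_family(
            1.5 * 2 * np.sqrt(case_i.coefficients.k2 / case_i.coefficients.k1),
            case_i.coefficients, case_i.medium.alpha,
        )
        vp = dimensionless_velocity(sol.v, d)
        t_end = 2.0

        def error(dx, dt):
            grid = Grid1D(length=40.0, dx=dx)
            rho0, u0 = initial_state(sol, grid.positions, d, min_clearance_fwhm=3)
            n = int(round(t_end / dt))
            cfg = SolverConfig(dimless=d, dt=dt, n_steps=n, save_every=n)
            traj = simulate(FieldState(rho0, u0), cfg, grid)
            x = grid.positions
            ref = (sol.A / d.A_star) / np.cosh(
                (x - 20.0 - vp * t_end) / (d.q_star * sol.delta)
            ) ** 2
            return np.linalg.norm(traj.rho[-1] - ref) / np.linalg.norm(ref)

        e_coarse = error(0.08, 8e-4)
        e_fine = error(0.04, 4e-4)
        order = np.log2(e_coarse / e_fine)
        assert order >= 1.9

    def test_ensemble_mean_approaches_deterministic(self, case_i):
        """Averaging N noisy runs converges to the noiseless run ~1/sqrt(N).

        Checked in the weak-nonlinearity regime, where the ensemble mean
        is unbiased; at full alpha' the nonlinearity rectifies part of
        the noise into a systematic O(noise^2) shift that no amount of
        averaging removes.
        """
        d = replace(case_i.dimless, alphap=1e-6)
        grid = Grid1D(length=30.0, dx=0.05)
        st = stationary_soliton(case_i.coefficients, case_i.medium.alpha)
        rho0, u0 = initial_state(st, grid.positions, d, min_clearance_fwhm=5)
        base = SolverConfig(dimless=d, dt=2e-4, n_steps=1500, save_every=1500)
        det = simulate(FieldState(rho0.copy(), u0.copy()), base, grid)

        def ensemble_err(n_runs, seed0):
            acc = np.zeros_like(rho0)
            for s in range(n_runs):
                cfg = replace(base, noise_enabled=True, seed=seed0 + s)
                acc += simulate(FieldState(rho0.copy(), u0.copy()), cfg, grid).rho[-1]
            mean = acc / n_runs
            return np.linalg.norm(mean - det.rho[-1])

        # 16x more runs should cut the residual ~4x; allow wide slack for
        # the small effective number of independent low-k modes
        e4 = ensemble_err(4, 100)
        e64 = ensemble_err(64, 200)
        assert e64 < 0.6 * e4

    def test_linearized_energy_decays_under_damping(self, case_i):
        """alpha' = 0, noise off, nu' > 0: the quadratic energy functional
        E = sum(u'^2 + k1' rho'^2 + k2' rho'_x^2) never increases."""
        d = replace(case_i.dimless, alphap=1e-300)
        grid = Grid1D(length=30.0, dx=0.05)
        x = grid.positions
        rho0 = 1e-3 * np.exp(-((x - 15.0) ** 2) / 2.0)
        cfg = SolverConfig(dimless=d, dt=2e-4, n_steps=4000, save_every=200,
                           bc="periodic")
        traj = simulate(FieldState(rho0, np.zeros_like(x)), cfg, grid)

        def energy(k):
            rho, u = traj.rho[k], traj.u[k]
            rx = np.gradient(rho, grid.dx)
            return np.sum(u**2 + d.k1p * rho**2 + d.k2p * rx**2)

        e = np.array([energy(k) for k in range(traj.n_snapshots)])
        assert np.all(np.diff(e) <= 1e-12 * e[0])
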