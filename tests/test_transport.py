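"""Transport solver: initial condition, operators, time stepping, limits."""

import numpy as np
import pytest

from wavydrift.channel import ModelParams, make_grid
from wavydrift.transport import (
    CompactDiffusion,
    ICSpec,
    advect_upwind,
    initial_condition,
    low_sigma_solver,
    run_simulation,
    step_rk3,
)

from conftest import measured_order


class TestInitialCondition:
    def test_saturated_core_and_tails(self):
        p = ModelParams(n=3)
        g = make_grid(p, Nx_cell=400, Neta=11)
        c = initial_condition(ICSpec(x0=1.75, delta=0.2), g)
        i0 = np.argmin(np.abs(g.x - 1.75))
        assert c[i0, 0] == pytest.approx(1.0)
        far = np.abs(g.x - 1.75) > 5 * 0.2
        assert np.max(c[far]) < 1e-6
        assert np.all(c[:, 0] == c[:, -1])  # eta-independent

    def test_plateau_edge_location(self):
        # oracle: solve (3/2) exp(-16 s^2) = 1 -> s = sqrt(ln(3/2))/4
        delta = 0.2
        p = ModelParams(n=3)
        g = make_grid(p, Nx_cell=3200, Neta=11)
        c = initial_condition(ICSpec(x0=1.5, delta=delta), g)
        edge = delta * np.sqrt(np.log(1.5)) / 4
        inside = np.abs(g.x - 1.5) <= edge - 2 * g.dx
        outside = np.abs(g.x - 1.5) >= edge + 2 * g.dx
        assert np.all(c[inside, 0] == 1.0)
        assert np.all(c[outside, 0] < 1.0)

    def test_bolus_touching_ends_warns(self):
        p = ModelParams(n=3)
        g = make_grid(p, Nx_cell=50, Neta=11)
        with pytest.warns(UserWarning):
            initial_condition(ICSpec(x0=0.1, delta=0.5), g)

    def test_centre_outside_channel_rejected(self):
        p = ModelParams(n=3)
        g = make_grid(p, Nx_cell=50, Neta=11)
        with pytest.raises(ValueError):
            initial_condition(ICSpec(x0=4.5, delta=0.2), g)


class TestAdvection:
    def test_constant_field_untouched(self):
        p = ModelParams(n=1)
        g = make_grid(p, Nx_cell=32, Neta=17)
        c = np.full((33, 17), 0.3)
        u = np.random.default_rng(0).normal(size=c.shape)
        w = np.random.default_rng(1).normal(size=c.shape)
        assert np.max(np.abs(advect_upwind(c, u, w, g))) < 1e-13

    def test_affine_exactness(self):
        p = ModelParams(n=1)
        g = make_grid(p, Nx_cell=32, Neta=17)
        c = np.tile(g.x[:, None], (1, 17))
        term = advect_upwind(c, np.ones_like(c), np.zeros_like(c), g)
        assert np.allclose(term[1:], 1.0, atol=1e-12)

    def test_second_order_convergence(self):
        # oracle: analytic derivative of a smooth synthetic field
        p = ModelParams(n=1)
        errs = []
        for N in (64, 128, 256):
            g = make_grid(p, Nx_cell=N, Neta=N + 1)
            X = g.x[:, None]
            E = g.eta[None, :]
            c = np.sin(2 * np.pi * X) * (1 + 0.3 * np.cos(np.pi * E))
            u = np.full_like(c, 0.7)
            w = np.full_like(c, -0.4)
            exact = (u * 2 * np.pi * np.cos(2 * np.pi * X) * (1 + 0.3 * np.cos(np.pi * E))
                     - w * np.pi * np.sin(2 * np.pi * X) * 0.3 * np.sin(np.pi * E))
            term = advect_upwind(c, u, w, g)
            errs.append(np.max(np.abs(term - exact)[3:-3, 3:-3]))
        orders = measured_order(errs)
        assert np.all(np.abs(orders - 2.0) <= 0.2)


class TestDiffusion:
    def test_polynomial_exactness(self):
        # cubic with zero slope at both walls is resolved to round-off
        op = CompactDiffusion(33, 1 / 32)
        eta = np.linspace(0, 1, 33)
        c = (2 * eta**3 - 3 * eta**2)[None, :]
        d2 = op.second_derivative(c)
        assert np.max(np.abs(d2 - (12 * eta - 6)[None, :])) < 1e-9

    def test_eta_independent_field_gives_zero(self):
        op = CompactDiffusion(17, 1 / 16)
        c = np.full((5, 17), 0.4)
        assert np.max(np.abs(op.second_derivative(c))) < 1e-12

    def test_fourth_order_convergence(self):
        # oracle: -pi^2 cos(pi eta), a Neumann-compatible mode
        errs = []
        for Neta in (17, 33, 65, 129):
            op = CompactDiffusion(Neta, 1 / (Neta - 1))
            eta = np.linspace(0, 1, Neta)
            c = np.cos(np.pi * eta)[None, :]
            d2 = op.second_derivative(c)
            errs.append(np.max(np.abs(d2 + np.pi**2 * c)))
        orders = measured_order(errs)
        assert np.all(np.abs(orders - 4.0) <= 0.3)

    def test_conservative_variant_has_zero_mean(self):
        op = CompactDiffusion(33, 1 / 32)
        eta = np.linspace(0, 1, 33)
        c = (np.cos(np.pi * eta) + 0.2 * np.cos(3 * np.pi * eta))[None, :]
        d2 = op.second_derivative(c, conserve=True)
        assert abs(np.trapezoid(d2[0], dx=1 / 32)) < 1e-14


class TestRK3:
    def test_third_order_on_linear_ode(self):
        # oracle: exact exponential decay/rotation of a linear system
        lam = -1.0 + 2.0j
        c0 = np.array([1.0 + 0j])
        errs = []
        for steps in (8, 16, 32):
            dt = 1.0 / steps
            c = c0.copy()
            for _ in range(steps):
                c = step_rk3(c, lambda y: lam * y, dt)
            errs.append(abs(c[0] - np.exp(lam)))
        orders = measured_order(errs)
        assert np.all(np.abs(orders - 3.0) <= 0.3)

    def test_third_order_on_frozen_advection(self):
        # frozen uniform velocity, diffusion off: compare against a
        # small-step reference on the same grid to isolate temporal error
        p = ModelParams(alpha=4.0, beta=0.0, Ri=0.0, sigma=1e12, n=1)
        g = make_grid(p, Nx_cell=64, Neta=9)
        c0 = np.tile(np.exp(np.sin(2 * np.pi * g.x))[:, None], (1, 9))
        u = np.full_like(c0, 0.9)
        w = np.zeros_like(c0)

        def rhs(c):
            return -advect_upwind(c, u, w, g)

        T = 0.25

        def advance(steps):
            c = c0.copy()
            for _ in range(steps):
                c = step_rk3(c, rhs, T / steps)
            return c

        ref = advance(2048)
        errs = [np.max(np.abs(advance(s) - ref)) for s in (32, 64, 128)]
        orders = measured_order(errs)
        assert np.all(np.abs(orders - 3.0) <= 0.3)

    def test_uniform_state_is_a_fixed_point(self):
        p = ModelParams(alpha=4.0, beta=0.2, Ri=0.0, sigma=1.0, n=3)
        g = make_grid(p, Nx_cell=32, Neta=17)
        res = run_simulation(p, ICSpec(x0=1.5, delta=0.2), grid=g, tau_end=0.05,
                             snapshot_dt=0.05)
        # replace by checking a uniform field via the RHS machinery
        from wavydrift.meandrift import compute_mean_drift
        from wavydrift.transport import _TransportRHS, drift_on_full_grid

        drift = compute_mean_drift(p, grid=make_grid(
            ModelParams(alpha=4.0, beta=0.2, n=1), 32, 17))
        H = 1 + 0.2 * np.cos(2 * np.pi * g.x)
        rhs = _TransportRHS(p, g, drift_on_full_grid(drift, g), H)
        c = np.full((g.x.size, g.Neta), 0.6)
        assert np.max(np.abs(rhs(c))) < 1e-12
        assert res.final.diagnostics.M > 0  # run completed

    def test_pure_transverse_diffusion_relaxes_to_eta_mean(self):
        # beta = 0, Ri = 0: no drift at all, only transverse diffusion
        p = ModelParams(alpha=4.0, beta=0.0, Ri=0.0, sigma=1.0, n=1)
        g = make_grid(p, Nx_cell=32, Neta=33)
        from wavydrift.meandrift import compute_mean_drift
        from wavydrift.transport import _TransportRHS, drift_on_full_grid, step_rk3

        drift = compute_mean_drift(p, grid=make_grid(p, 32, 33))
        H = np.ones(g.x.size)
        rhs = _TransportRHS(p, g, drift_on_full_grid(drift, g), H)
        c = 0.5 + 0.3 * np.cos(np.pi * g.eta)[None, :] * np.ones((g.x.size, 1))
        mean0 = np.trapezoid(c, dx=g.deta, axis=1)
        dt = 0.4 * 0.5 * p.alpha**2 * p.sigma * g.deta**2
        for _ in range(3200):
            c = step_rk3(c, rhs, dt)
        assert np.max(np.abs(c - mean0[:, None])) < 1e-3


class TestRunSimulation:
    def test_mass_conserved_and_bolus_trapped_without_buoyancy(self):
        p = ModelParams(alpha=4.0, beta=0.2, Ri=0.0, sigma=1.0, n=3)
        res = run_simulation(p, ICSpec(), tau_end=1.0, snapshot_dt=0.5,
                             Nx_cell=64, Neta=33)
        M0 = res.snapshots[0].diagnostics.M
        assert res.final.diagnostics.M == pytest.approx(M0, rel=1e-10)
        cells = res.final.diagnostics.cell_masses
        leak = (abs(cells[0]) + abs(cells[2])) / M0
        assert leak < 0.01

    def test_buoyant_bolus_moves_upward(self):
        p = ModelParams(alpha=4.0, beta=0.2, Ri=1.0, sigma=1.0, n=3)
        res = run_simulation(p, ICSpec(), tau_end=1.0, snapshot_dt=0.25,
                             Nx_cell=64, Neta=33)
        coms = [s.diagnostics.center_of_mass for s in res.snapshots]
        assert all(np.diff(coms) < 0)  # toward x = 0, the upper end
        assert res.final.QB < 0

    def test_invalid_horizon_rejected(self):
        p = ModelParams(n=3)
        with pytest.raises(ValueError):
            run_simulation(p, ICSpec(), tau_end=-1.0)


class TestLowSigmaSolver:
    def test_frozen_without_buoyancy(self):
        p = ModelParams(alpha=4.0, beta=0.2, Ri=0.0, sigma=0.01, n=3)
        res = low_sigma_solver(p, ICSpec(), tau_end=1.0, Nx_cell=100)
        assert np.max(np.abs(res.final.c - res.snapshots[0].c)) < 1e-14

    def test_weighted_mass_exactly_conserved(self):
        p = ModelParams(alpha=4.0, beta=0.2, Ri=1.0, sigma=0.01, n=3)
        res = low_sigma_solver(p, ICSpec(), tau_end=1.0, Nx_cell=200)
        M0 = res.snapshots[0].diagnostics.M
        assert abs(res.final.diagnostics.M - M0) / M0 < 1e-6

    def test_translation_speed_matches_characteristics(self):
        # frozen-coefficient check: on a uniform background c* in a straight
        # channel the chimney speed is |QB|/H = alpha^2 Ri c*/12, so a small
        # superposed bump translates at that speed over short times
        cstar = 0.5
        p = ModelParams(alpha=4.0, beta=0.0, Ri=1.0, sigma=0.01, n=3)
        g = make_grid(p, Nx_cell=400, Neta=9)
        from wavydrift.transport import low_sigma_solver as solver  # noqa: F401

        # build the solver state by hand through a custom IC: a narrow bump
        # on top of the uniform background is emulated by tracking the
        # centre of mass of the perturbation
        res = low_sigma_solver(p, ICSpec(x0=1.5, delta=0.2), grid=g, tau_end=0.2,
                               snapshot_dt=0.2)
        c0 = res.snapshots[0].c[:, 0]
        c1 = res.final.c[:, 0]
        # speed of the bolus centroid; QB from the bolus itself
        qb = res.final.QB
        com0 = np.trapezoid(c0 * g.x, dx=g.dx) / np.trapezoid(c0, dx=g.dx)
        com1 = np.trapezoid(c1 * g.x, dx=g.dx) / np.trapezoid(c1, dx=g.dx)
        speed = (com1 - com0) / 0.2
        assert speed == pytest.approx(qb, rel=0.05)  # H = 1

    def test_matches_full_solver_at_small_sigma(self):
        p = ModelParams(alpha=4.0, beta=0.2, Ri=1.0, sigma=0.05, n=3)
        ic = ICSpec()
        full = run_simulation(p, ic, tau_end=0.5, snapshot_dt=0.5,
                              Nx_cell=64, Neta=21)
        lim = low_sigma_solver(p, ic, tau_end=0.5, Nx_cell=64)
        Ci = full.snapshots[0].diagnostics.C
        num = np.trapezoid(np.abs(full.final.diagnostics.C - lim.final.diagnostics.C),
                           dx=full.grid.dx)
        den = np.trapezoid(Ci, dx=full.grid.dx)
        assert num / den < 0.08
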