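"""Reaction terms, diffusion operator, injection schedules and the time
integrator of the six-field continuum model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gliotan import (DomainGrid, InjectionSchedule, ModelParameters,
                     SolverControls, StateFields, advance, apply_diffusion,
                     build_tissue_map, injection_rate, reaction_rates, simulate)
from gliotan.pde import FIELD_NAMES, Event, mean_injection_rate


def uniform_state(grid, **values):
    st = StateFields.zeros(grid)
    for k, v in values.items():
        getattr(st, k)[:] = v
    return st


class TestReactionRates:
    def test_extinction_fixed_point(self, params):
        zero = {f: 0.0 for f in FIELD_NAMES}
        d = reaction_rates(zero, params)
        assert all(np.allclose(v, 0.0) for v in d.values())

    def test_n1_at_capacity_decays(self, params):
        """With N1 at carrying capacity and no cytokine, only natural decay
        remains: dN1 = -mu1*K1."""
        st = {f: 0.0 for f in FIELD_NAMES}
        st["N1"] = params.K1
        d = reaction_rates(st, params)
        assert float(d["N1"]) == pytest.approx(-params.mu1 * params.K1, rel=1e-12)
        assert float(d["N1"]) == pytest.approx(-2.005e5, rel=1e-3)

    def test_tgf_steady_state(self, params):
        """At tumor capacity the TGF-beta equilibrium is lambda_G*n0/mu_G = 1e-8."""
        g_star = params.lambda_G * params.n0 / params.mu_G
        assert g_star == pytest.approx(1e-8, rel=1e-12)
        st = {f: 0.0 for f in FIELD_NAMES}
        st["n"] = params.n0
        st["G"] = g_star
        d = reaction_rates(st, params)
        assert float(d["G"]) == pytest.approx(0.0, abs=1e-30)

    def test_rejects_negative(self, params):
        st = {f: 0.0 for f in FIELD_NAMES}
        st["N2"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            reaction_rates(st, params)


class TestApplyDiffusion:
    def test_constant_field_zero(self, small_grid):
        D = np.full(small_grid.shape, 1e-3)
        out = apply_diffusion(np.full(small_grid.shape, 7.0), D, small_grid)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_zero_flux_conservation(self, small_grid, rng):
        from gliotan import total_population

        u = rng.random(small_grid.shape)
        D = 1e-3 * (1 + rng.random(small_grid.shape))
        out = apply_diffusion(u, D, small_grid)
        # volume-weighted grid integral vanishes: nothing crosses the boundary
        assert abs(total_population(out, small_grid)) \
            < 1e-12 * total_population(np.abs(out), small_grid)

    def test_cosine_eigenfunction(self):
        """u = cos(pi x) is a Neumann eigenfunction: L u = -D pi^2 u + O(h^2)."""
        errs = []
        for nx in (41, 81):
            g = DomainGrid(nx, nx)
            X, _ = g.meshgrid()
            u = np.cos(np.pi * X)
            D = np.full(g.shape, 2.0e-3)
            out = apply_diffusion(u, D, g)
            errs.append(np.abs(out + 2.0e-3 * np.pi ** 2 * u).max())
        assert errs[0] < 1e-4
        assert errs[1] < errs[0] / 3.0  # ~second-order decay

    def test_shape_mismatch(self, small_grid):
        with pytest.raises(ValueError):
            apply_diffusion(np.zeros((5, 5)), np.ones(small_grid.shape), small_grid)


class TestInjectionRate:
    def test_constant_reference_rate(self, params):
        s = InjectionSchedule(mode="constant", rate=params.lambda_A)
        assert injection_rate(50.0, s) == pytest.approx(2.89e1)

    def test_periodic_off_between_pulses(self):
        s = InjectionSchedule(mode="periodic", rate=28.9, pulse_starts=(10.0, 50.0), tau=1.0)
        assert injection_rate(30.0, s) == 0.0

    def test_periodic_amplified_inside_pulse(self):
        s = InjectionSchedule(mode="periodic", rate=28.9, pulse_starts=(10.0,), tau=1.0)
        assert injection_rate(10.5, s) == pytest.approx(2.89e3)

    def test_mean_rate_preserves_dose(self):
        s = InjectionSchedule(mode="periodic", rate=1.0, pulse_starts=(10.0,), tau=1.0)
        # a step straddling the pulse deposits exactly the pulse mass
        assert mean_injection_rate(9.0, 12.0, s) * 3.0 == pytest.approx(100.0)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            InjectionSchedule(mode="periodic", pulse_starts=(5.0, 5.0))
        with pytest.raises(ValueError):
            InjectionSchedule(mode="wavy")


class TestAdvance:
    def test_zero_state_fixed_point(self, white_tissue, params):
        st = StateFields.zeros(white_tissue.grid)
        out = advance(st, white_tissue, params,
                      InjectionSchedule(ifnb_active=False), 0.0, 0.05)
        for f in FIELD_NAMES:
            assert np.allclose(getattr(out, f), 0.0)

    def test_positivity_preserved(self, white_tissue, params, rng):
        st = StateFields(
            N1=rng.random(white_tissue.grid.shape) * 5e6,
            N2=rng.random(white_tissue.grid.shape) * 4e6,
            A=rng.random(white_tissue.grid.shape) * 1e3,
            n=rng.random(white_tissue.grid.shape) * 1e9,
            S=rng.random(white_tissue.grid.shape) * 1e-7,
            G=rng.random(white_tissue.grid.shape) * 1e-8,
        )
        out = advance(st, white_tissue, params, InjectionSchedule(), 0.0, 0.5)
        for f in FIELD_NAMES:
            assert np.all(getattr(out, f) >= 0.0)
            assert np.all(np.isfinite(getattr(out, f)))

    def test_rejects_bad_dt(self, white_tissue, params):
        st = StateFields.zeros(white_tissue.grid)
        with pytest.raises(ValueError):
            advance(st, white_tissue, params, InjectionSchedule(), 0.0, -0.1)


class TestSimulate:
    def test_empty_horizon(self, white_tissue, params):
        st = uniform_state(white_tissue.grid, n=1e6)
        traj = simulate(st, white_tissue, params, InjectionSchedule(), 0.0)
        assert len(traj.times) == 1 and traj.times[0] == 0.0
        assert np.allclose(traj.final().n, 1e6)

    def test_antibody_plateau(self, params):
        """Whole-domain constant injection with everything else zero follows
        A(t) = (lambda_A/mu_A)(1 - e^{-mu_A t}) with plateau 1000 g/cm^3."""
        grid = DomainGrid(9, 9)
        tissue = build_tissue_map("uniform_white", grid)
        sched = InjectionSchedule(mode="constant", rate=params.lambda_A,
                                  ifnb_active=False)
        traj = simulate(StateFields.zeros(grid), tissue, params, sched, 240.0,
                        SolverControls(dt=0.25, sample_times=(60.0, 240.0)))
        assert params.lambda_A / params.mu_A == pytest.approx(1000.0)
        for t in (60.0, 240.0):
            expected = 1000.0 * (1.0 - np.exp(-params.mu_A * t))
            assert traj.state_at(t).A.mean() == pytest.approx(expected, rel=1e-9)

    def test_tumor_only_logistic(self, params):
        """Uniform tumor with no TANs follows the logistic closed form to 0.1%."""
        grid = DomainGrid(9, 9)
        tissue = build_tissue_map("uniform_white", grid)
        n_init = 1e6
        st = uniform_state(grid, n=n_init)
        traj = simulate(st, tissue, params, InjectionSchedule(ifnb_active=False),
                        240.0, SolverControls(dt=0.05))
        r, n0 = params.r, params.n0
        exact = n0 * n_init * np.exp(r * 240) / (n0 + n_init * (np.exp(r * 240) - 1))
        assert traj.final().n.mean() == pytest.approx(exact, rel=1e-3)

    def test_matches_ode_reduction(self, params):
        """On uniform tissue with uniform data the PDE trajectory equals the
        spatially homogeneous ODE system solved by an independent stiff
        integrator (relative error < 1e-4 over 240 h)."""
        grid = DomainGrid(5, 5)
        tissue = build_tissue_map("uniform_white", grid)
        y0 = {"N1": 1e6, "N2": 2e6, "A": 0.0, "n": 1e7, "S": 0.0, "G": 0.0}
        a_rate = 0.0289
        sched = InjectionSchedule(mode="constant", rate=a_rate, ifnb_active=True)
        st = uniform_state(grid, **y0)
        traj = simulate(st, tissue, params, sched, 240.0, SolverControls(dt=0.01))

        def rhs(t, y):
            d = reaction_rates(dict(zip(FIELD_NAMES, y)), params,
                               a_rate=a_rate, s_rate=params.lambda_S)
            return [float(d[f]) for f in FIELD_NAMES]

        sol = solve_ivp(rhs, (0.0, 240.0), [y0[f] for f in FIELD_NAMES],
                        method="LSODA", rtol=1e-10, atol=1e-25)
        fin = traj.final()
        scale = {f: max(abs(sol.y[i, -1]), 1e-12 * max(y0[f], 1.0))
                 for i, f in enumerate(FIELD_NAMES)}
        for i, f in enumerate(FIELD_NAMES):
            rel = abs(fin.__dict__[f].mean() - sol.y[i, -1]) / scale[f]
            assert rel < 1e-4, f"{f}: rel error {rel}"

    def test_uniformity_preserved(self, params):
        grid = DomainGrid(9, 9)
        tissue = build_tissue_map("uniform_white", grid)
        st = uniform_state(grid, N1=1e6, N2=1e6, n=1e7)
        traj = simulate(st, tissue, params, InjectionSchedule(), 10.0,
                        SolverControls(dt=0.1))
        for f in FIELD_NAMES:
            arr = getattr(traj.final(), f)
            assert np.ptp(arr) <= 1e-9 * max(arr.max(), 1e-30)

    def test_antibody_mass_balance_no_decay(self, params):
        """In the (near) no-decay, no-reaction limit the grid integral of A
        grows by exactly the injected mass."""
        grid = DomainGrid(9, 9)
        tissue = build_tissue_map("uniform_white", grid)
        p = params.with_overrides(mu_A=1e-12)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[3:5, 3:5] = True
        sched = InjectionSchedule(mode="constant", rate=2.0, omega_A=mask,
                                  ifnb_active=False)
        traj = simulate(StateFields.zeros(grid), tissue, p, sched, 5.0,
                        SolverControls(dt=0.5))
        from gliotan import total_population
        injected = 2.0 * 5.0 * total_population(mask.astype(float), grid)
        total = total_population(traj.final().A, grid)
        assert total == pytest.approx(injected, rel=1e-6)

    def test_event_applied_at_nominal_time(self, white_tissue, params):
        def wipe(state, ctx):
            state.n[:] = 0.0

        st = uniform_state(white_tissue.grid, n=1e6)
        traj = simulate(st, white_tissue, params, InjectionSchedule(), 10.0,
                        SolverControls(dt=0.3, sample_times=(4.0, 10.0)),
                        events=[Event(4.0, wipe, label="wipe")])
        assert traj.event_log == [(4.0, "wipe")]
        assert traj.state_at(4.0).n.max() == 0.0

    def test_event_outside_horizon_rejected(self, white_tissue, params):
        st = StateFields.zeros(white_tissue.grid)
        with pytest.raises(ValueError, match="event time"):
            simulate(st, white_tissue, params, InjectionSchedule(), 10.0,
                     events=[Event(11.0, lambda s, c: None)])


class TestHeterogeneousDiffusion:
    def test_gray_matter_blocks_spread(self, params):
        """A bump in white matter barely leaks across the gray interface."""
        grid = DomainGrid(41, 41)
        tissue = build_tissue_map("wrinkle", grid)
        st = StateFields.zeros(grid)
        X, Y = grid.meshgrid()
        st.S[(np.hypot(X - 0.5, Y - 0.45) < 0.1) & tissue.white] = 1.0
        sched = InjectionSchedule(ifnb_active=False)
        p = params.with_overrides(mu_S=1e-6)  # isolate transport
        traj = simulate(st, tissue, p, sched, 24.0, SolverControls(dt=0.5))
        fin = traj.final().S
        # harmonic face averaging keeps the interface leak tiny: after a day
        # the gray side holds < 1/30 of the white-matter peak
        assert fin[tissue.white].max() > 30 * fin[tissue.gray].max()
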