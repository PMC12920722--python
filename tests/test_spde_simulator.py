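"""Stencil, noise and time-stepping checks for the 2-D integrator."""

import numpy as np
import pytest

from sirs_turing import (
    EpidemicParams,
    FieldState,
    SimConfig,
    em_step,
    laplacian_no_flux,
    noise_increments,
    run,
    select_stable_equilibrium,
)
from sirs_turing.spde_simulator import initial_state

PURE_DIFFUSION = EpidemicParams(b=0, d=0, beta0=0, gamma=0, mu=0, D1=0.7, D2=1.0, D3=0.2)


class TestLaplacian:
    def test_constant_field_is_flat(self):
        assert np.all(laplacian_no_flux(np.full((7, 9), 3.4), h=0.5) == 0.0)

    def test_mass_conservation_any_field(self):
        """Mirror ghost nodes make boundary fluxes vanish, so the stencil
        telescopes to zero over the grid for arbitrary data."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            f = rng.normal(size=(rng.integers(3, 40), rng.integers(3, 40)))
            assert abs(laplacian_no_flux(f, h=1.0).sum()) < 1e-10

    def test_cosine_eigenfunction(self):
        """Cell-centred cos(kx*x)cos(ky*y) with k = m*pi/L is an exact
        eigenfunction with eigenvalue -(4/h^2)(sin^2(kx h/2)+sin^2(ky h/2))."""
        n, h = 64, 0.5
        L = n * h
        x = (np.arange(n) + 0.5) * h
        for mx, my in [(3, 0), (5, 2), (0, 7)]:
            kx, ky = mx * np.pi / L, my * np.pi / L
            f = np.outer(np.cos(kx * x), np.cos(ky * x))
            eig = -(4.0 / h**2) * (np.sin(kx * h / 2) ** 2 + np.sin(ky * h / 2) ** 2)
            assert np.allclose(laplacian_no_flux(f, h), eig * f, atol=1e-12)


class TestNoiseIncrements:
    def test_zero_intensity_is_exact_zero(self):
        cfg = SimConfig(nx=8, ny=8)
        assert np.all(noise_increments(cfg, 0.0, np.random.default_rng(0)) == 0.0)

    def test_variance_matches_lattice_correlation(self):
        """Per-cell variance 2*C_I*dt, estimated over 1e6 draws."""
        cfg = SimConfig(nx=1000, ny=1000, dt=0.01)
        C_I = 0.08
        xi = noise_increments(cfg, C_I, np.random.default_rng(42))
        assert xi.var() == pytest.approx(2 * C_I * cfg.dt, rel=0.01)
        assert abs(xi.mean()) < 3 * np.sqrt(2 * C_I * cfg.dt / xi.size)

    def test_seed_determinism(self):
        cfg = SimConfig(nx=16, ny=16)
        a = noise_increments(cfg, 0.05, np.random.default_rng(7))
        b = noise_increments(cfg, 0.05, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestEmStep:
    def test_homogeneous_equilibrium_is_fixed_point(self, base_params):
        ss = select_stable_equilibrium(base_params)
        cfg = SimConfig(nx=16, ny=16, init_amp=0.0)
        state, rng = initial_state(base_params, cfg, ss)
        out = em_step(state, base_params, cfg, rng)
        assert np.allclose(out.S, ss.S0, atol=1e-14)
        assert np.allclose(out.I, ss.I0, atol=1e-14)
        assert np.allclose(out.R, ss.R0, atol=1e-14)

    def test_pure_diffusion_conserves_mass(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(nx=20, ny=20, dt=0.01)
        state = FieldState(
            S=rng.uniform(0.5, 1.5, (20, 20)),
            I=rng.uniform(0.5, 1.5, (20, 20)),
            R=rng.uniform(0.5, 1.5, (20, 20)),
            t=0.0,
        )
        masses = [state.S.sum(), state.I.sum(), state.R.sum()]
        for _ in range(50):
            state = em_step(state, PURE_DIFFUSION, cfg, rng)
        for mass, f in zip(masses, (state.S, state.I, state.R)):
            assert f.sum() == pytest.approx(mass, abs=1e-9)

    def test_single_step_against_brute_force(self, base_params):
        """One deterministic step on a 3x3 grid against a loop-written
        Euler update with explicit ghost mirroring."""
        rng = np.random.default_rng(9)
        S0, I0, R0 = rng.uniform(0.2, 1.0, (3, 3, 3))
        cfg = SimConfig(nx=3, ny=3, dt=0.005)
        p = base_params
        state = em_step(FieldState(S0.copy(), I0.copy(), R0.copy(), 0.0), p, cfg, rng)

        def lap(f, i, j):
            def at(a, b):
                # mirror about the cell face: ghost equals the edge cell
                return f[min(max(a, 0), 2), min(max(b, 0), 2)]

            return at(i + 1, j) + at(i - 1, j) + at(i, j + 1) + at(i, j - 1) - 4 * f[i, j]

        for i in range(3):
            for j in range(3):
                inc = p.beta0 * S0[i, j] * I0[i, j] ** 2 / (1 + p.alpha * I0[i, j] ** 2)
                F = p.b - p.d * S0[i, j] - inc + p.mu * R0[i, j]
                G = inc - (p.gamma + p.d) * I0[i, j]
                H = p.gamma * I0[i, j] - (p.mu + p.d) * R0[i, j]
                assert state.S[i, j] == pytest.approx(
                    S0[i, j] + cfg.dt * (F + p.D1 * lap(S0, i, j)), rel=1e-13
                )
                assert state.I[i, j] == pytest.approx(
                    I0[i, j] + cfg.dt * (G + p.D2 * lap(I0, i, j)), rel=1e-13
                )
                assert state.R[i, j] == pytest.approx(
                    R0[i, j] + cfg.dt * (H + p.D3 * lap(R0, i, j)), rel=1e-13
                )

    def test_nonfinite_field_aborts_with_location(self, base_params):
        cfg = SimConfig(nx=4, ny=4, dt=0.01)
        bad = FieldState(np.ones((4, 4)), np.ones((4, 4)), np.ones((4, 4)), 0.0)
        bad.S[2, 1] = np.inf
        with pytest.raises(FloatingPointError, match=r"non-finite S at t=0.0100, cell \(\d+, \d+\)"):
            em_step(bad, base_params, cfg, np.random.default_rng(0))

    def test_stability_bound_enforced(self, base_params):
        with pytest.raises(ValueError, match="stability bound"):
            SimConfig(nx=8, ny=8, dt=0.05).validate_stability(base_params)


class TestRun:
    def test_unperturbed_run_stays_homogeneous(self, base_params):
        """10^4 deterministic steps from the exact equilibrium show only
        round-off drift."""
        ss = select_stable_equilibrium(base_params)
        cfg = SimConfig(
            nx=16, ny=16, dt=0.01, t_end=100.0, init_amp=0.0, stationarity_tol=0.0
        )
        result = run(base_params, cfg, ss)
        assert result.state.t == pytest.approx(100.0)
        assert np.allclose(result.state.I, ss.I0, atol=1e-10)
        assert np.ptp(result.state.I) < 1e-10

    def test_seeded_runs_bit_reproducible(self, base_params):
        cfg = SimConfig(nx=24, ny=24, dt=0.01, t_end=2.0, seed=123)
        p = base_params.with_(C_I=0.05)
        a = run(p, cfg)
        b = run(p, cfg)
        np.testing.assert_array_equal(a.state.I, b.state.I)
        np.testing.assert_array_equal(a.state.S, b.state.S)
        assert a.state.clip_events == b.state.clip_events

    def test_summary_records_field_statistics(self, base_params):
        cfg = SimConfig(nx=16, ny=16, dt=0.01, t_end=1.0, record_every=50)
        result = run(base_params, cfg)
        assert list(result.summary.columns) == [
            "t",
            "mean_I",
            "min_I",
            "max_I",
            "var_I",
            "clip_events",
        ]
        assert len(result.summary) == 3  # t = 0, 0.5, 1.0
        assert (result.summary.var_I >= 0).all()
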