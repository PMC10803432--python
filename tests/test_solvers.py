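"""Grids, transport terms and the IMEX integrator."""

import numpy as np
import pytest
import scipy.fft as sfft

import turingtransients as tt
from turingtransients import _kernels
from turingtransients.fixtures import (
    PerturbationSpec,
    random_initial_condition,
    single_mode_perturbation,
)
from turingtransients.linear_stability import growth_rate, growth_rate_numeric
from turingtransients.models import MODEL_IDS, focal_equilibrium, reaction_rates
from turingtransients.solvers import (
    DivergenceError,
    FieldState,
    amplitude,
    build_grid,
    chemotaxis_term,
    default_n_points,
    integrate,
    nonlocal_term,
)


class TestGrid:
    def test_spacing_and_shape(self):
        g = build_grid(100.0, 1, 256)
        assert g.dx == 100.0 / 256 == 0.390625
        g2 = build_grid(100.0, 2, 128)
        assert g2.shape == (128, 128)

    @pytest.mark.parametrize("n", [10, 63, 65])
    def test_rejects_bad_resolution(self, n):
        with pytest.raises(ValueError):
            build_grid(100.0, 1, n)

    @pytest.mark.parametrize("N,n", [(1, 128), (2, 64)])
    def test_laplacian_matrix_agrees_with_fourier_symbol(self, N, n, rng):
        g = build_grid(50.0, N, n)
        u = rng.normal(size=g.shape)
        via_matrix = (g.laplacian_matrix() @ u.ravel()).reshape(g.shape)
        axes = tuple(range(N))
        lam = g.laplacian_eigenvalues_rfft()
        via_fft = sfft.irfftn(
            sfft.rfftn(u, axes=axes) * lam, s=g.shape, axes=axes
        )
        assert np.allclose(via_matrix, via_fft, atol=1e-8)


class TestAmplitude:
    def test_uniform_and_sine(self):
        g = build_grid(10.0, 1, 64)
        u = np.zeros((1, 64))
        assert amplitude(FieldState(0.0, u)) == 0.0
        u = np.sin(2 * np.pi * g.coords() / g.L)[None, :]
        assert np.isclose(amplitude(FieldState(0.0, u)), 2.0, atol=1e-3)

    def test_ignores_second_field(self):
        u = np.zeros((2, 64))
        u[1] = np.linspace(-5, 5, 64)
        assert amplitude(FieldState(0.0, u)) == 0.0


class TestKernels:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_fused_kinetics_match_reference(self, model_id, base_specs, rng):
        spec = base_specs[model_id]
        p = spec.params
        y = rng.uniform(-3, 3, size=(spec.n_fields, 50))
        out = np.empty_like(y)
        if model_id == "reaction_diffusion":
            _kernels.kin_reaction_diffusion(y, out, p.a, p.b, p.c, p.d, p.e)
        elif model_id == "keller_segel":
            _kernels.kin_keller_segel(y, out, p.a, p.b, p.d)
        else:
            _kernels.kin_cubic(y, out, p.a, p.b, p.c)
        assert np.allclose(out, reaction_rates(spec, y), rtol=1e-13, atol=1e-13)


class TestNonlocalTerm:
    def test_vanishes_on_constant_field(self):
        g = build_grid(30.0, 1, 128)
        u = np.full(128, 0.37)
        assert np.max(np.abs(nonlocal_term(g, u, 20.0))) < 1e-14

    def test_linearisation_matches_dispersion_contribution(self, base_specs):
        """For u = u0 + eps cos(2 pi k x / L), the linearised term equals the
        transport part of the growth rate times the perturbation."""
        spec = base_specs["nonlocal_advection"]
        p = spec.params
        g = build_grid(p.L, 1, 256)
        u0, eps, k = p.c, 1e-6, 2
        x = g.coords()
        mode = np.cos(2 * np.pi * k * x / p.L)
        term = nonlocal_term(g, u0 + eps * mode, p.d)
        rho = (2 * np.pi * k / p.L) ** 2
        coeff = u0 * (1 - u0) * p.d * rho / (np.pi * (1 + rho))
        expected = coeff * eps * mode
        assert np.max(np.abs(term - expected)) / np.max(np.abs(expected)) < 1e-3

    def test_matches_quadrature_oracle(self):
        """Spectral evaluation vs direct quadrature of the periodised kernel
        against a smooth (trigonometric) density."""
        L, n, d = 30.0, 128, 20.0
        g = build_grid(L, 1, n)
        x = g.coords()
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=3)
        modes = [1, 2, 5]

        def u_func(xx):
            out = 0.4 + np.zeros_like(xx)
            for c, k in zip(coeffs, modes):
                out = out + 0.05 * c * np.cos(2 * np.pi * k * xx / L)
            return out

        u = u_func(x)
        # oracle: w(x) = int sign(s) e^{-|s|}/(2 pi) u(x+s) ds over |s| < 40
        s = np.linspace(1e-9, 40.0, 120_001)
        kern = np.exp(-s) / (2 * np.pi)
        w_oracle = np.empty(n)
        for j in range(n):
            vals = kern * (u_func(x[j] + s) - u_func(x[j] - s))
            w_oracle[j] = np.trapezoid(vals, s)
        phi = u * (1 - u) * w_oracle
        # spectral derivative of the oracle flux (same differentiation step)
        q = g.wavenumbers_rfft()
        term_oracle = -d * sfft.irfft(1j * q * sfft.rfft(phi), n)
        term = nonlocal_term(g, u, d)
        scale = np.max(np.abs(term_oracle))
        assert np.max(np.abs(term - term_oracle)) / scale < 1e-6

    def test_2d_raises(self):
        g = build_grid(30.0, 2, 64)
        with pytest.raises(NotImplementedError):
            nonlocal_term(g, np.zeros((64, 64)), 20.0)


class TestIntegrate:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_equilibrium_is_preserved(self, model_id, base_specs, base_equilibria):
        spec = base_specs[model_id]
        g = build_grid(spec.params.L, 1, default_n_points(spec))
        eq = focal_equilibrium(spec)
        fields = np.tile(
            np.asarray(eq.state)[:, None], (1, g.n_points)
        )
        traj = integrate(
            spec, g, FieldState(0.0, fields), t_final=100.0,
            equilibria=base_equilibria[model_id], n_outputs=20,
        )
        assert np.max(traj.amplitudes) < 1e-10

    @pytest.mark.parametrize(
        "model_id,k",
        [
            ("reaction_diffusion", 7),
            ("keller_segel", 11),
            ("biharmonic", 14),
            ("nonlocal_advection", 2),
        ],
    )
    def test_single_mode_growth_matches_dispersion(
        self, model_id, k, base_specs, base_equilibria
    ):
        """Log-amplitude slope of a seeded eigenmode must match Re lambda_k
        while the dynamics stay linear."""
        spec = base_specs[model_id]
        p = spec.params
        g = build_grid(p.L, 1, default_n_points(spec))
        eq = focal_equilibrium(spec)
        rho = (2 * np.pi * k / p.L) ** 2
        lam = complex(growth_rate(spec, eq, rho)).real
        assert lam > 0, "chosen mode must be unstable"
        t_end = np.log(300.0) / lam
        init = single_mode_perturbation(eq, g, k, 1e-6)
        traj = integrate(
            spec, g, init, t_final=t_end, n_outputs=40,
            equilibria=base_equilibria[model_id], early_stop=False,
        )
        mask = (traj.times > 0.25 * t_end) & (traj.amplitudes < 1e-3)
        slope = np.polyfit(traj.times[mask], np.log(traj.amplitudes[mask]), 1)[0]
        assert abs(slope - lam) / lam < 0.05

    @pytest.mark.parametrize("model_id", ["keller_segel", "biharmonic", "nonlocal_advection"])
    def test_transport_conserves_mass_without_kinetics(
        self, model_id, base_specs, base_equilibria
    ):
        spec = base_specs[model_id]
        g = build_grid(spec.params.L, 1, 128)
        eq = focal_equilibrium(spec)
        init = random_initial_condition(
            eq, g, PerturbationSpec(sd=5e-2, seed=4)
        )
        # without its kinetics the biharmonic instability grows unboundedly,
        # so keep the horizon short enough for the fields to stay O(1-1e4)
        t_final = 20.0 if model_id == "biharmonic" else 100.0
        traj = integrate(
            spec, g, init, t_final=t_final, disable_reactions=True,
            n_outputs=10, early_stop=False,
        )
        mean0 = init.fields[0].mean()
        meanT = traj.final.fields[0].mean()
        scale = max(abs(mean0), np.max(np.abs(traj.final.fields[0])))
        assert abs(meanT - mean0) / scale < 1e-8

    def test_translation_equivariance(self, base_specs, base_equilibria):
        spec = base_specs["keller_segel"]
        g = build_grid(spec.params.L, 1, 128)
        eq = focal_equilibrium(spec)
        init = random_initial_condition(eq, g, PerturbationSpec(sd=1e-2, seed=8))
        shift = 17
        shifted = FieldState(0.0, np.roll(init.fields, shift, axis=-1))
        kw = dict(t_final=10.0, fixed_dt=0.02, n_outputs=5)
        a = integrate(spec, g, init, **kw)
        b = integrate(spec, g, shifted, **kw)
        assert np.max(np.abs(np.roll(a.final.fields, shift, axis=-1) - b.final.fields)) < 1e-6

    def test_divergence_raises_with_last_state(self, base_specs):
        spec = base_specs["biharmonic"]
        g = build_grid(spec.params.L, 1, 128)
        fields = np.full((1, 128), 3.0)  # far outside the kinetic attractors
        with pytest.raises(DivergenceError) as exc:
            integrate(spec, g, FieldState(0.0, fields), t_final=50.0, fixed_dt=5.0)
        assert np.all(np.isfinite(exc.value.state.fields))

    def test_trajectory_sampling_contract(self, base_specs, base_equilibria):
        spec = base_specs["nonlocal_advection"]
        g = build_grid(spec.params.L, 1, default_n_points(spec))
        eq = focal_equilibrium(spec)
        init = random_initial_condition(eq, g, PerturbationSpec(sd=1e-2, seed=2))
        traj = integrate(
            spec, g, init, t_final=50.0, n_outputs=25,
            equilibria=base_equilibria["nonlocal_advection"],
        )
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[0] == 0.0 and traj.times[-1] == 50.0
        assert len(traj.amplitudes) == len(traj.times) == traj.fields.shape[0]

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_classification_robust_to_grid_refinement(
        self, model_id, base_specs, base_equilibria
    ):
        """Doubling the resolution must not change the patterned-vs-not
        verdict at the final time (reduced base-parameter ensemble)."""
        spec = base_specs[model_id]
        eqs = base_equilibria[model_id]
        eq = focal_equilibrium(spec)
        for seed in (101, 202):
            verdicts = []
            for n in (256, 512):
                g = build_grid(spec.params.L, 1, n)
                init = random_initial_condition(
                    eq, g, PerturbationSpec(sd=1e-2, seed=seed)
                )
                traj = integrate(
                    spec, g, init, t_final=1e4, equilibria=eqs,
                    rtol=1e-4, atol=1e-8, n_outputs=20,
                )
                verdicts.append(amplitude(traj.final) > 1e-5)
            assert verdicts[0] == verdicts[1]


class TestChemotaxisTerm:
    def test_zero_for_uniform_attractant(self, rng):
        g = build_grid(80.0, 1, 128)
        u = rng.uniform(0.5, 1.5, 128)
        v = np.full(128, 2.0)
        assert np.max(np.abs(chemotaxis_term(g, u, v, 3.0))) < 1e-14

    def test_discrete_divergence_has_zero_mean(self, rng):
        g = build_grid(80.0, 2, 64)
        u = rng.uniform(0.5, 1.5, (64, 64))
        v = rng.normal(size=(64, 64))
        term = chemotaxis_term(g, u, v, 3.0)
        assert abs(term.mean()) < 1e-13


class TestIntegrate2D:
    def test_single_mode_growth_matches_dispersion_2d(self, base_specs):
        spec = tt.base_model("keller_segel", N=2)
        p = spec.params
        g = build_grid(p.L, 2, 128)
        eq = focal_equilibrium(spec)
        # rho ~ 0.20 keeps q*dx small so the FD Laplacian is well resolved
        m, n = 4, 4
        rho = (2 * np.pi / p.L) ** 2 * (m * m + n * n)
        lam = complex(growth_rate(spec, eq, rho)).real
        assert lam > 0
        t_end = np.log(100.0) / lam
        init = single_mode_perturbation(eq, g, (m, n), 1e-6)
        traj = integrate(spec, g, init, t_final=t_end, n_outputs=30,
                         early_stop=False)
        mask = (traj.times > 0.25 * t_end) & (traj.amplitudes < 1e-3)
        slope = np.polyfit(traj.times[mask], np.log(traj.amplitudes[mask]), 1)[0]
        assert abs(slope - lam) / lam < 0.05

    def test_keller_segel_2d_equilibrium_preserved(self):
        spec = tt.base_model("keller_segel", N=2)
        g = build_grid(spec.params.L, 2, 64)
        eq = focal_equilibrium(spec)
        fields = np.tile(np.asarray(eq.state)[:, None, None], (1, 64, 64))
        traj = integrate(spec, g, FieldState(0.0, fields), t_final=20.0,
                         n_outputs=5, early_stop=False)
        assert traj.amplitudes.max() < 1e-10

    def test_2d_nonlocal_integration_rejected(self):
        spec = tt.base_model("nonlocal_advection", N=2)
        with pytest.raises(NotImplementedError):
            g = build_grid(spec.params.L, 2, 64)
            fields = np.full((1, 64, 64), 0.5)
            integrate(spec, g, FieldState(0.0, fields), t_final=1.0)
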