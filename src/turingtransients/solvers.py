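"""Time integration of the four models on periodic grids.

Spatial discretisation is second-order finite differences for the local
transport terms (the periodic 3/5-point Laplacian, and its composition for
the biharmonic operator), with the chemotaxis flux ``-c div(u grad v)`` in
conservative face-flux form.  The nonlocal attraction term is evaluated
pseudospectrally: the interaction kernel enters through its analytic Fourier
symbol at the discrete wavenumbers, so the simulated linearisation matches
the dispersion relation used for the Turing verdict exactly.

Timestepping is the second-order IMEX Runge-Kutta scheme ARS(2,2,2): the
stiff linear transport operators are diagonal in Fourier space (the FFT
diagonalises circulant finite-difference stencils exactly) and are treated
implicitly with an L-stable two-stage method, while reactions and nonlinear
transport are explicit.  Each step is taken once at ``dt`` and twice at
``dt/2``; the difference drives a standard adaptive step-size controller and
the Richardson-extrapolated combination is propagated.

Long runs support early termination once the solution is demonstrably
settled: either the pattern amplitude has fallen far below the patterning
threshold while the spatial mean sits at a kinetically stable equilibrium
that is not Turing unstable on this domain (further evolution is pure
decay), or the state is patterned and stationary to tolerance.  Both checks
are conservative and can be disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
import scipy.sparse

from . import _kernels
from .models import Equilibrium, ModelSpec, find_equilibria
from .linear_stability import is_turing_unstable

__all__ = [
    "Grid",
    "FieldState",
    "Trajectory",
    "DivergenceError",
    "build_grid",
    "default_n_points",
    "nonlocal_term",
    "chemotaxis_term",
    "amplitude",
    "integrate",
]


class DivergenceError(RuntimeError):
    """Integration blew up; carries the last valid state and time."""

    def __init__(self, message: str, state: "FieldState"):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class Grid:
    """Uniform periodic grid on ``[0, L]^N`` with ``n_points`` per side."""

    L: float
    N: int
    n_points: int

    @property
    def dx(self) -> float:
        return self.L / self.n_points

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.n_points,) * self.N

    def coords(self) -> np.ndarray:
        """Node coordinates ``x_j = j dx`` (half-open, periodic wrap)."""
        return np.arange(self.n_points) * self.dx

    def laplacian_eigenvalues_rfft(self) -> np.ndarray:
        """Eigenvalues of the periodic FD Laplacian in (r)fftn layout.

        The circulant 3-point stencil has eigenvalues
        ``-(4/dx^2) sin^2(pi j / n)``; in 2D the axis contributions add.
        """
        n = self.n_points
        lam_full = -(4.0 / self.dx**2) * np.sin(np.pi * np.arange(n) / n) ** 2
        lam_half = lam_full[: n // 2 + 1]
        if self.N == 1:
            return lam_half
        return lam_full[:, None] + lam_half[None, :]

    def wavenumbers_rfft(self) -> np.ndarray:
        """Spectral wavenumbers ``q = 2 pi j / L`` for the 1D rfft layout."""
        return 2.0 * np.pi * np.fft.rfftfreq(self.n_points, d=self.dx)

    def laplacian_matrix(self) -> scipy.sparse.spmatrix:
        """Sparse periodic FD Laplacian (1D: 3-point; 2D: 5-point)."""
        n = self.n_points
        e = np.ones(n)
        lap1 = scipy.sparse.diags(
            [e, -2.0 * e, e], [-1, 0, 1], shape=(n, n), format="lil"
        )
        lap1[0, -1] = 1.0
        lap1[-1, 0] = 1.0
        lap1 = (lap1 / self.dx**2).tocsr()
        if self.N == 1:
            return lap1
        eye = scipy.sparse.identity(n, format="csr")
        return scipy.sparse.kron(lap1, eye) + scipy.sparse.kron(eye, lap1)


@dataclass(frozen=True)
class FieldState:
    """Spatial fields at one instant: ``fields`` has shape (n_fields, *grid)."""

    t: float
    fields: np.ndarray


@dataclass
class Trajectory:
    """Sampled states of one simulation plus solver statistics."""

    times: np.ndarray
    fields: np.ndarray  # (n_samples, n_fields, *grid_shape)
    amplitudes: np.ndarray
    stats: dict = field(default_factory=dict)
    converged: str | None = None  # "homogeneous", "steady_pattern" or None
    t_converged: float | None = None

    @property
    def final(self) -> FieldState:
        return FieldState(t=float(self.times[-1]), fields=self.fields[-1])

    def kymograph(self) -> np.ndarray:
        """u over (time, space); rows are time samples (1D runs only)."""
        return self.fields[:, 0]


def build_grid(L: float, N: int, n_points: int) -> Grid:
    """A validated periodic grid; ``n_points`` must be even and >= 64."""
    if n_points < 64:
        raise ValueError(f"n_points must be >= 64, got {n_points}")
    if n_points % 2:
        raise ValueError(f"n_points must be even, got {n_points}")
    if N not in (1, 2):
        raise ValueError("N must be 1 or 2")
    if L <= 0:
        raise ValueError("L must be positive")
    return Grid(L=float(L), N=N, n_points=n_points)


def default_n_points(spec: ModelSpec) -> int:
    """Default resolution: 256 per side in 1D, 128 in 2D.

    Chosen so dx resolves both L/128 and a tenth of the fastest-growing
    wavelength for every base model.
    """
    return 256 if spec.params.N == 1 else 128


def amplitude(state: FieldState) -> float:
    """Pattern amplitude max(u) - min(u), measured on the u field only."""
    u = state.fields[0]
    return float(u.max() - u.min())


# ---------------------------------------------------------------------------
# transport terms


def chemotaxis_term(grid: Grid, u: np.ndarray, v: np.ndarray, c: float) -> np.ndarray:
    """Conservative discretisation of ``-c div(u grad v)``.

    Face fluxes ``G_{j+1/2} = c * (u_j + u_{j+1})/2 * (v_{j+1} - v_j)/dx``
    per axis; the returned term is minus their discrete divergence, which
    conserves the discrete mean of u exactly.
    """
    dx = grid.dx
    div = np.zeros_like(u)
    for axis in range(grid.N):
        u_face = 0.5 * (u + np.roll(u, -1, axis=axis))
        dv = (np.roll(v, -1, axis=axis) - v) / dx
        G = c * u_face * dv
        div += (G - np.roll(G, 1, axis=axis)) / dx
    return -div


def nonlocal_term(grid: Grid, u: np.ndarray, d: float) -> np.ndarray:
    """Nonlocal attraction term of the aggregation model (1D only).

    Computes the convolution of u with the odd exponential kernel
    ``sign(s) e^{-|s|} / (2 pi)`` spectrally — multiplying the Fourier
    coefficients of u at wavenumber q by the kernel's analytic symbol
    ``i q / (pi (1 + q^2))`` — and returns
    ``-d * d/dx [ u (1 - u) * (that convolution) ]`` with spectral
    differentiation.
    """
    if grid.N != 1:
        raise NotImplementedError("2D nonlocal advection is not implemented")
    n = grid.n_points
    q = grid.wavenumbers_rfft()
    kernel_hat = 1j * q / (np.pi * (1.0 + q**2))
    w = sfft.irfft(sfft.rfft(u) * kernel_hat, n)
    phi = u * (1.0 - u) * w
    return -d * sfft.irfft(1j * q * sfft.rfft(phi), n)


# ---------------------------------------------------------------------------
# IMEX integration


def _linear_symbol(spec: ModelSpec, grid: Grid) -> np.ndarray:
    """Fourier symbol of the implicitly treated linear transport operator."""
    p = spec.params
    lam = grid.laplacian_eigenvalues_rfft()
    if spec.model_id in ("reaction_diffusion", "keller_segel"):
        return np.stack([lam, p.D * lam])
    if spec.model_id == "biharmonic":
        return np.stack([-p.D * lam - lam**2])
    return np.stack([p.D * lam])  # nonlocal_advection: plain diffusion


def _make_explicit_rhs(spec: ModelSpec, grid: Grid, disable_reactions: bool):
    """Reactions plus nonlinear transport, with preallocated-output support.

    The kinetics go through the fused kernels of :mod:`._kernels`, which are
    asserted (in the test suite) to match :func:`models.reaction_rates`.
    """
    p = spec.params
    model = spec.model_id
    nf = spec.n_fields

    if model == "reaction_diffusion":
        def kinetics(yf, of):
            _kernels.kin_reaction_diffusion(yf, of, p.a, p.b, p.c, p.d, p.e)
    elif model == "keller_segel":
        def kinetics(yf, of):
            _kernels.kin_keller_segel(yf, of, p.a, p.b, p.d)
    else:
        def kinetics(yf, of):
            _kernels.kin_cubic(yf, of, p.a, p.b, p.c)

    def rhs(y: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
        if out is None:
            out = np.empty_like(y)
        if disable_reactions:
            out[:] = 0.0
        else:
            kinetics(y.reshape(nf, -1), out.reshape(nf, -1))
        if model == "keller_segel":
            out[0] += chemotaxis_term(grid, y[0], y[1], p.c)
        elif model == "nonlocal_advection":
            out[0] += nonlocal_term(grid, y[0], p.d)
        return out

    return rhs


def _safe_targets(
    spec: ModelSpec, equilibria: list[Equilibrium] | None
) -> list[np.ndarray]:
    """States a homogenised solution can settle at: kinetically stable
    equilibria that are not Turing unstable on this model's own domain."""
    if equilibria is None:
        equilibria = find_equilibria(spec)
    targets = []
    for eq in equilibria:
        if not eq.kinetically_stable:
            continue
        rep = is_turing_unstable(spec, eq, discrete=True)
        if not rep.turing_unstable:
            targets.append(np.asarray(eq.state, dtype=float))
    return targets


def integrate(
    spec: ModelSpec,
    grid: Grid,
    init: FieldState,
    t_final: float,
    output_times: np.ndarray | None = None,
    n_outputs: int = 200,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    dt_init: float | None = None,
    fixed_dt: float | None = None,
    disable_reactions: bool = False,
    equilibria: list[Equilibrium] | None = None,
    early_stop: bool = True,
    stop_amplitude: float = 1e-7,
    steady_drift_tol: float = 1e-9,
    steady_burn_in: float = 1000.0,
    steady_window: float = 100.0,
    pattern_threshold: float = 1e-5,
    max_steps: int = 10_000_000,
) -> Trajectory:
    """Integrate one model from ``init`` to ``t_final``.

    Returns a :class:`Trajectory` sampled at ``output_times`` (default:
    ``n_outputs`` uniform samples, always including 0 and ``t_final``).
    With ``fixed_dt`` the adaptive controller and early stopping are
    bypassed (useful for step-by-step comparisons).  Non-finite states or
    step-size underflow raise :class:`DivergenceError` carrying the last
    valid state.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    if spec.params.N != grid.N:
        raise ValueError("spec and grid dimension differ")
    if spec.model_id == "nonlocal_advection" and grid.N != 1:
        raise NotImplementedError("2D nonlocal advection is not implemented")
    y = np.ascontiguousarray(init.fields, dtype=float)
    if y.shape != (spec.n_fields, *grid.shape):
        raise ValueError(
            f"init fields shape {y.shape} != {(spec.n_fields, *grid.shape)}"
        )

    if output_times is None:
        output_times = np.linspace(0.0, t_final, n_outputs + 1)
    output_times = np.unique(np.clip(np.asarray(output_times, dtype=float), 0.0, t_final))
    if output_times[-1] < t_final:
        output_times = np.append(output_times, t_final)

    S = _linear_symbol(spec, grid)
    fft_axes = tuple(range(1, 1 + grid.N))
    rhs = _make_explicit_rhs(spec, grid, disable_reactions)
    nf = spec.n_fields

    # ARS(2,2,2) coefficients
    gamma = 1.0 - math.sqrt(2.0) / 2.0
    delta = 1.0 - 1.0 / (2.0 * gamma)

    buf_Ny = np.empty_like(y)
    buf_Ny2 = np.empty_like(y)
    buf_w = np.empty_like(y)

    def substep(state: np.ndarray, dt: float, denom: np.ndarray) -> np.ndarray:
        rhs(state, buf_Ny)
        _kernels.axpy(
            state.reshape(nf, -1), buf_Ny.reshape(nf, -1), gamma * dt,
            buf_w.reshape(nf, -1),
        )
        w2_hat = sfft.rfftn(buf_w, axes=fft_axes) / denom
        y2 = sfft.irfftn(w2_hat, s=grid.shape, axes=fft_axes)
        Ly2 = sfft.irfftn(S * w2_hat, s=grid.shape, axes=fft_axes)
        rhs(y2, buf_Ny2)
        _kernels.stage_combo(
            state.reshape(nf, -1), buf_Ny.reshape(nf, -1),
            buf_Ny2.reshape(nf, -1), Ly2.reshape(nf, -1),
            dt, delta, gamma, buf_w.reshape(nf, -1),
        )
        return sfft.irfftn(
            sfft.rfftn(buf_w, axes=fft_axes) / denom, s=grid.shape, axes=fft_axes
        )

    t = float(init.t)
    samples = [y.copy()]
    sample_times = [t]
    out_idx = int(np.searchsorted(output_times, t, side="right"))

    dt = fixed_dt if fixed_dt is not None else (dt_init or min(1e-3, t_final / 100))
    dt_max = t_final / 2
    denom_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def denoms(dt: float) -> tuple[np.ndarray, np.ndarray]:
        if dt not in denom_cache:
            denom_cache.clear()
            denom_cache[dt] = (1.0 - gamma * dt * S, 1.0 - gamma * 0.5 * dt * S)
        return denom_cache[dt]

    targets: list[np.ndarray] | None = None
    n_steps = n_rejected = 0
    converged: str | None = None
    t_converged: float | None = None
    grew_after_reject = True
    snap_t, snap_y = t, y.copy()  # drift-rate reference for the steady check

    # non-finite values are detected and handled after each trial step,
    # so let them propagate silently through the arithmetic
    with np.errstate(invalid="ignore", over="ignore"):
        while t < t_final - 1e-12 * t_final and converged is None:
            if n_steps + n_rejected > max_steps:
                raise DivergenceError(
                    f"exceeded {max_steps} steps at t={t:.6g}", FieldState(t, y)
                )
            # land exactly on the next output time
            t_target = t_final
            if out_idx < len(output_times):
                t_target = min(t_target, output_times[out_idx])
            clamped = dt >= t_target - t
            dt_step = min(dt, t_target - t)
            dt_step = max(dt_step, 1e-14 * t_final)

            d1, d2 = denoms(dt_step)
            if fixed_dt is not None:
                y_new = substep(y, dt_step, d1)
                if not np.all(np.isfinite(y_new)):
                    raise DivergenceError(
                        f"non-finite state at t={t:.6g}", FieldState(t, y)
                    )
                accepted = True
            else:
                y_big = substep(y, dt_step, d1)
                y_half = substep(y, 0.5 * dt_step, d2)
                y_small = substep(y_half, 0.5 * dt_step, d2)
                if not (np.all(np.isfinite(y_big)) and np.all(np.isfinite(y_small))):
                    err = np.inf
                else:
                    err = _kernels.error_norm(
                        y_big.reshape(nf, -1), y_small.reshape(nf, -1),
                        y.reshape(nf, -1), atol, rtol,
                    )
                accepted = err <= 1.0
                if accepted:
                    y_new = np.empty_like(y)
                    _kernels.richardson2(
                        y_big.reshape(nf, -1), y_small.reshape(nf, -1),
                        y_new.reshape(nf, -1),
                    )
                    fac = 0.9 * (err + 1e-16) ** (-1.0 / 3.0)
                    fac = min(fac, 3.0 if grew_after_reject else 1.0)
                    cand = min(dt_step * max(fac, 0.2), dt_max)
                    # a step clamped to hit an output time should not shrink
                    # the proposal the controller had already earned
                    dt = max(cand, dt) if clamped else cand
                    grew_after_reject = True
                else:
                    n_rejected += 1
                    grew_after_reject = False
                    if not np.isfinite(err):
                        dt = dt_step * 0.1
                    else:
                        dt = dt_step * max(min(0.9 * err ** (-1.0 / 3.0), 0.5), 0.1)
                    if dt < 1e-13 * max(t, 1.0):
                        raise DivergenceError(
                            f"step size underflow at t={t:.6g}", FieldState(t, y)
                        )
                    continue

            t = t_target if clamped else t + dt_step
            y = y_new
            n_steps += 1

            while out_idx < len(output_times) and t >= output_times[out_idx] - 1e-9:
                samples.append(y.copy())
                sample_times.append(output_times[out_idx])
                out_idx += 1

            # settledness checks (adaptive runs only)
            if early_stop and fixed_dt is None and n_steps % 25 == 0:
                amp = float(y[0].max() - y[0].min())
                if amp < stop_amplitude:
                    if targets is None:
                        targets = _safe_targets(spec, equilibria)
                    mean = y.reshape(nf, -1).mean(axis=1)
                    for tgt in targets:
                        if np.max(np.abs(mean - tgt)) < 1e-4 * (1.0 + np.max(np.abs(tgt))):
                            converged = "homogeneous"
                            t_converged = t
                            break
                elif amp > pattern_threshold and t - snap_t >= steady_window:
                    drift = float(np.max(np.abs(y - snap_y))) / (t - snap_t)
                    if drift < steady_drift_tol and t >= steady_burn_in:
                        converged = "steady_pattern"
                        t_converged = t
                    snap_t, snap_y = t, y.copy()
                elif t - snap_t >= steady_window:
                    snap_t, snap_y = t, y.copy()

    # if stopped early, the remaining samples hold the settled state
    while out_idx < len(output_times):
        samples.append(y.copy())
        sample_times.append(output_times[out_idx])
        out_idx += 1

    fields = np.array(samples)
    times = np.array(sample_times)
    amps = fields[:, 0].reshape(len(times), -1)
    amps = amps.max(axis=1) - amps.min(axis=1)
    return Trajectory(
        times=times,
        fields=fields,
        amplitudes=amps,
        stats=dict(n_steps=n_steps, n_rejected=n_rejected),
        converged=converged,
        t_converged=t_converged,
    )
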