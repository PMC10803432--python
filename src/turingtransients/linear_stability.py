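"""Dispersion relations and the Turing-instability verdict.

On a periodic domain the negative Laplacian has eigenvalues
``rho_k = (2 pi k / L)^2`` in 1D and ``(2 pi / L)^2 (m^2 + n^2)`` in 2D, with
sinusoidal eigenfunctions.  Linearising a model about a homogeneous
equilibrium turns each spatial mode into a small linear system whose leading
eigenvalue ``lambda(rho)`` — the dispersion relation — gives the growth rate
of that mode.  The Turing criterion is ``Re lambda(0) < 0`` (stable to
uniform perturbations) together with ``Re lambda(rho_k) > 0`` for some
``k > 0``.

Two routes to ``lambda`` are provided: :func:`growth_rate` evaluates the
closed-form dispersion relation of each model at its focal equilibrium, and
:func:`growth_rate_numeric` assembles the linearisation matrix ``M(rho)``
(kinetics Jacobian plus transport symbol) and takes its leading eigenvalue.
The two agree to rounding error at the focal equilibrium; the numeric route
additionally handles every other equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .models import Equilibrium, ModelSpec, focal_equilibrium, reaction_jacobian

__all__ = [
    "SpectralMode",
    "DispersionCurve",
    "StabilityReport",
    "domain_eigenvalues",
    "growth_rate",
    "growth_rate_numeric",
    "dispersion_curve",
    "is_turing_unstable",
    "default_rho_max",
]


@dataclass(frozen=True)
class SpectralMode:
    """One Laplacian eigenmode of the periodic domain.

    ``index`` is ``k`` in 1D or ``(m, n)`` in 2D; ``rho`` the spatial
    eigenvalue (squared wavenumber).  The eigenfunctions themselves are the
    implied sinusoids and are never materialised.
    """

    index: int | tuple[int, int]
    rho: float


@dataclass(frozen=True)
class DispersionCurve:
    """Growth rate per spatial mode for one model/equilibrium pair."""

    model_id: str
    state: tuple[float, ...]
    modes: tuple[SpectralMode, ...]
    lam: np.ndarray  # complex, one entry per mode

    def to_frame(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(
            dict(
                rho=[m.rho for m in self.modes],
                re_lambda=self.lam.real,
                im_lambda=self.lam.imag,
            )
        )


@dataclass(frozen=True)
class StabilityReport:
    """Verdict of the Turing-instability check for one equilibrium."""

    turing_unstable: bool
    kinetically_unstable: bool
    max_growth_rate: float
    argmax_rho: float
    argmax_index: int | tuple[int, int] | None
    rho_max: float
    discrete: bool


def domain_eigenvalues(L: float, N: int, rho_max: float) -> list[SpectralMode]:
    """All Laplacian eigenmodes of the periodic domain with ``rho <= rho_max``.

    Sorted nondecreasing in ``rho``, starting from the constant mode
    ``rho_0 = 0``.  In 2D every ordered pair ``(m, n)`` of nonnegative
    integers is kept (multiplicity retained).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    base = (2.0 * math.pi / L) ** 2
    if rho_max < 0:
        return []
    if N == 1:
        kmax = int(math.floor(math.sqrt(rho_max / base)))
        return [SpectralMode(k, base * k * k) for k in range(kmax + 1)]
    if N == 2:
        cap = int(math.ceil(math.sqrt(rho_max / base))) + 1
        modes = []
        for m in range(cap + 1):
            for n in range(cap + 1):
                rho = base * (m * m + n * n)
                if rho <= rho_max:
                    modes.append(SpectralMode((m, n), rho))
        modes.sort(key=lambda s: s.rho)
        return modes
    raise ValueError("N must be 1 or 2")


def _require_focal(spec: ModelSpec, equilibrium: Equilibrium) -> None:
    focal = focal_equilibrium(spec)
    if np.max(np.abs(np.asarray(equilibrium.state) - np.asarray(focal.state))) > 1e-9:
        raise ValueError(
            "analytic dispersion relation applies only at the focal "
            f"equilibrium {focal.state}, got {equilibrium.state}; "
            "use growth_rate_numeric for other equilibria"
        )


def _quadratic_branch(T, Q):
    """Max-real-part root of lambda^2 - T lambda + Q = 0 (+imag on ties)."""
    T = np.asarray(T, dtype=complex)
    disc = T**2 - 4.0 * np.asarray(Q, dtype=complex)
    s = np.sqrt(disc)
    lam1 = (T + s) / 2.0
    lam2 = (T - s) / 2.0
    pick1 = (lam1.real > lam2.real) | (
        (lam1.real == lam2.real) & (lam1.imag >= lam2.imag)
    )
    return np.where(pick1, lam1, lam2)


def nonlocal_kernel_symbol(rho, N: int):
    """The factor ``1 / (pi^(2-N) (1 + rho)^((N+1)/2))`` of the attraction kernel.

    This is the Fourier transform of the odd exponential interaction kernel,
    expressed against ``rho = q^2`` and normalised so that the advection
    contribution to the dispersion relation is ``u0 (1 - u0) d rho`` times it.
    """
    rho = np.asarray(rho, dtype=float)
    return 1.0 / (math.pi ** (2 - N) * (1.0 + rho) ** ((N + 1) / 2))


def growth_rate(spec: ModelSpec, equilibrium: Equilibrium, rho):
    """Closed-form dispersion relation at the focal equilibrium.

    Accepts scalar or array ``rho >= 0`` and returns the maximal-real-part
    branch as a complex number/array (the complex root with positive
    imaginary part when the discriminant is negative).
    """
    _require_focal(spec, equilibrium)
    p = spec.params
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    if spec.model_id == "reaction_diffusion":
        acd = p.a * p.c * p.d
        T = 1.0 - acd - rho * (1.0 + p.D)
        Q = rho**2 * p.D - rho * (p.D - acd) - acd + p.b
        return _quadratic_branch(T, Q)
    if spec.model_id == "keller_segel":
        bb = p.b * (p.b - p.d)
        T = -bb - p.a - rho * (1.0 + p.D)
        Q = rho**2 * p.D - rho * (p.c * p.b - p.a - p.D * bb) + bb * p.a
        return _quadratic_branch(T, Q)
    if spec.model_id == "biharmonic":
        lam = p.D * rho - rho**2 + p.a * p.c * (p.b - p.c)
        return lam.astype(complex) if lam.ndim else complex(lam)
    # nonlocal_advection
    lam = (
        -p.a * p.c * (p.c - p.b)
        - p.D * rho
        + p.c * (1.0 - p.c) * p.d * rho * nonlocal_kernel_symbol(rho, p.N)
    )
    return lam.astype(complex) if lam.ndim else complex(lam)


def linearization_matrix(spec: ModelSpec, equilibrium: Equilibrium, rho: float) -> np.ndarray:
    """Kinetics Jacobian plus transport symbol at spatial eigenvalue ``rho``."""
    p = spec.params
    J = reaction_jacobian(spec, np.asarray(equilibrium.state))
    M = J.astype(float).copy()
    if spec.model_id == "reaction_diffusion":
        M[0, 0] -= rho
        M[1, 1] -= p.D * rho
    elif spec.model_id == "keller_segel":
        u0 = equilibrium.state[0]
        M[0, 0] -= rho
        M[0, 1] += p.c * u0 * rho  # from -c div(u grad v)
        M[1, 1] -= p.D * rho
    elif spec.model_id == "biharmonic":
        M[0, 0] += p.D * rho - rho**2
    else:  # nonlocal_advection
        u0 = equilibrium.state[0]
        M[0, 0] += -p.D * rho + u0 * (1.0 - u0) * p.d * rho * nonlocal_kernel_symbol(
            rho, p.N
        )
    return M


def growth_rate_numeric(spec: ModelSpec, equilibrium: Equilibrium, rho) -> complex | np.ndarray:
    """Leading eigenvalue of the linearisation matrix ``M(rho)``.

    Independent of the closed-form route: works at any homogeneous
    equilibrium and returns the eigenvalue with the largest real part (the
    member with positive imaginary part on conjugate ties).
    """
    rhos = np.atleast_1d(np.asarray(rho, dtype=float))
    out = np.empty(rhos.shape, dtype=complex)
    for i, r in enumerate(rhos.ravel()):
        eigs = np.linalg.eigvals(linearization_matrix(spec, equilibrium, float(r)))
        lead = eigs[np.argmax(eigs.real)]
        if lead.imag < 0 and np.any(np.isclose(eigs, lead.conjugate())):
            lead = lead.conjugate()
        out.ravel()[i] = lead
    return out if np.ndim(rho) else complex(out.ravel()[0])


def default_rho_max(spec: ModelSpec, equilibrium: Equilibrium | None = None) -> float:
    """Cutoff for mode scans: 4x the continuous argmax of Re lambda, floor 10."""
    if equilibrium is None:
        equilibrium = focal_equilibrium(spec)
    rho = np.linspace(1e-6, 50.0, 2001)
    try:
        lam = growth_rate(spec, equilibrium, rho)
    except ValueError:
        lam = growth_rate_numeric(spec, equilibrium, rho)
    argmax = float(rho[np.argmax(lam.real)])
    return max(10.0, 4.0 * argmax)


def dispersion_curve(
    spec: ModelSpec,
    equilibrium: Equilibrium | None = None,
    rho_max: float | None = None,
    analytic: bool | None = None,
) -> DispersionCurve:
    """Growth rates on the discrete modes of the model's own domain."""
    if equilibrium is None:
        equilibrium = focal_equilibrium(spec)
    if rho_max is None:
        rho_max = default_rho_max(spec, equilibrium)
    modes = domain_eigenvalues(spec.params.L, spec.params.N, rho_max)
    rhos = np.array([m.rho for m in modes])
    if analytic is None:
        analytic = equilibrium.is_focal
    if analytic:
        lam = np.atleast_1d(growth_rate(spec, equilibrium, rhos))
    else:
        lam = np.atleast_1d(growth_rate_numeric(spec, equilibrium, rhos))
    return DispersionCurve(
        model_id=spec.model_id,
        state=tuple(equilibrium.state),
        modes=tuple(modes),
        lam=lam,
    )


def is_turing_unstable(
    spec: ModelSpec,
    equilibrium: Equilibrium | None = None,
    rho_max: float | None = None,
    discrete: bool = True,
) -> StabilityReport:
    """Turing-instability verdict for one homogeneous equilibrium.

    ``discrete=True`` scans only the Laplacian eigenmodes of the model's own
    finite domain; ``discrete=False`` additionally maximises ``Re lambda``
    over continuous ``rho in (0, rho_max]``.  If ``Re lambda(0) >= 0`` the
    equilibrium is kinetically unstable and the report says so instead of
    claiming a Turing instability.
    """
    if equilibrium is None:
        equilibrium = focal_equilibrium(spec)
    if rho_max is None:
        rho_max = default_rho_max(spec, equilibrium)

    lam0 = np.max(np.linalg.eigvals(reaction_jacobian(spec, np.asarray(equilibrium.state))).real)
    if lam0 >= 0:
        return StabilityReport(
            turing_unstable=False,
            kinetically_unstable=True,
            max_growth_rate=float(lam0),
            argmax_rho=0.0,
            argmax_index=None,
            rho_max=rho_max,
            discrete=discrete,
        )

    analytic = True
    try:
        _require_focal(spec, equilibrium)
    except ValueError:
        analytic = False

    def relam(rhos):
        rhos = np.asarray(rhos, dtype=float)
        if analytic:
            return np.atleast_1d(growth_rate(spec, equilibrium, rhos)).real
        return np.atleast_1d(growth_rate_numeric(spec, equilibrium, rhos)).real

    modes = [m for m in domain_eigenvalues(spec.params.L, spec.params.N, rho_max) if m.rho > 0]
    best_rho, best_lam, best_index = 0.0, -np.inf, None
    if modes:
        rhos = np.array([m.rho for m in modes])
        vals = relam(rhos)
        i = int(np.argmax(vals))
        best_rho, best_lam, best_index = float(rhos[i]), float(vals[i]), modes[i].index

    if not discrete:
        grid = np.linspace(1e-8, rho_max, 801)
        vals = relam(grid)
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = scipy.optimize.minimize_scalar(
            lambda r: -relam([r])[0], bounds=(lo, hi), method="bounded"
        )
        if -res.fun > best_lam:
            best_lam = float(-res.fun)
            best_rho = float(res.x)
            best_index = None

    return StabilityReport(
        turing_unstable=bool(best_lam > 0),
        kinetically_unstable=False,
        max_growth_rate=best_lam,
        argmax_rho=best_rho,
        argmax_index=best_index,
        rho_max=rho_max,
        discrete=discrete,
    )
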