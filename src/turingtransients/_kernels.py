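"""Hot-loop kernels for the IMEX integrator.

The adaptive stepper spends nearly all its time in elementwise arithmetic on
small arrays, where numpy's per-call overhead dominates.  These fused
kernels (numba-jitted when numba is importable, plain numpy otherwise)
remove that overhead; they are numerically identical to the reference
kinetics in :mod:`turingtransients.models`, which a unit test asserts.

All kernels take fields flattened to shape ``(n_fields, n_nodes)``.
"""

from __future__ import annotations

import numpy as np

try:
    import numba

    _njit = numba.njit(cache=False, fastmath=False)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def _njit(f):
        return f


@_njit
def kin_reaction_diffusion(y, out, a, b, c, d, e):
    for i in range(y.shape[1]):
        u = y[0, i]
        v = y[1, i]
        out[0, i] = u - v - e * u * u * u
        out[1, i] = a * v * (v + c) * (v - d) + b * u - e * v * v * v


@_njit
def kin_keller_segel(y, out, a, b, d):
    for i in range(y.shape[1]):
        u = y[0, i]
        v = y[1, i]
        out[0, i] = u * (b - u) * (u - d)
        out[1, i] = u - a * v


@_njit
def kin_cubic(y, out, a, b, c):
    # shared by the biharmonic and nonlocal-advection models
    for i in range(y.shape[1]):
        u = y[0, i]
        out[0, i] = a * u * (c - u) * (u - b)


@_njit
def axpy(y, f, s, out):
    """out = y + s * f"""
    for j in range(y.shape[0]):
        for i in range(y.shape[1]):
            out[j, i] = y[j, i] + s * f[j, i]


@_njit
def stage_combo(y, Ny, Ny2, Ly2, dt, delta, gamma, out):
    """out = y + dt * (delta*Ny + (1-delta)*Ny2 + (1-gamma)*Ly2)"""
    for j in range(y.shape[0]):
        for i in range(y.shape[1]):
            out[j, i] = y[j, i] + dt * (
                delta * Ny[j, i]
                + (1.0 - delta) * Ny2[j, i]
                + (1.0 - gamma) * Ly2[j, i]
            )


@_njit
def error_norm(big, small, yold, atol, rtol):
    """max_i |big - small| / (atol + rtol * max(|yold|, |small|))"""
    worst = 0.0
    for j in range(big.shape[0]):
        for i in range(big.shape[1]):
            sc = atol + rtol * max(abs(yold[j, i]), abs(small[j, i]))
            r = abs(big[j, i] - small[j, i]) / sc
            if r > worst:
                worst = r
    return worst


@_njit
def richardson2(big, small, out):
    """Richardson extrapolation of a second-order pair: (4*small - big)/3."""
    for j in range(big.shape[0]):
        for i in range(big.shape[1]):
            out[j, i] = (4.0 * small[j, i] - big[j, i]) / 3.0


if not HAVE_NUMBA:  # numpy fallbacks, same contracts

    def kin_reaction_diffusion(y, out, a, b, c, d, e):  # noqa: F811
        u, v = y[0], y[1]
        out[0] = u - v - e * u**3
        out[1] = a * v * (v + c) * (v - d) + b * u - e * v**3

    def kin_keller_segel(y, out, a, b, d):  # noqa: F811
        u, v = y[0], y[1]
        out[0] = u * (b - u) * (u - d)
        out[1] = u - a * v

    def kin_cubic(y, out, a, b, c):  # noqa: F811
        u = y[0]
        out[0] = a * u * (c - u) * (u - b)

    def axpy(y, f, s, out):  # noqa: F811
        np.multiply(f, s, out=out)
        out += y

    def stage_combo(y, Ny, Ny2, Ly2, dt, delta, gamma, out):  # noqa: F811
        out[:] = y + dt * (
            delta * Ny + (1.0 - delta) * Ny2 + (1.0 - gamma) * Ly2
        )

    def error_norm(big, small, yold, atol, rtol):  # noqa: F811
        sc = atol + rtol * np.maximum(np.abs(yold), np.abs(small))
        return float(np.max(np.abs(big - small) / sc))

    def richardson2(big, small, out):  # noqa: F811
        out[:] = (4.0 * small - big) / 3.0
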