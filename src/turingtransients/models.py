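"""The four bistable reaction-transport models and their homogeneous equilibria.

Each model lives on a periodic domain ``[0, L]`` (1D) or ``[0, L]^2`` (2D) and
couples mild bistable (cubic) kinetics to a transport mechanism:

``reaction_diffusion``
    Two-species system ``u_t = lap(u) + u - v - e u^3``,
    ``v_t = D lap(v) + a v (v + c)(v - d) + b u - e v^3``.
``keller_segel``
    Chemotaxis with Allee population kinetics:
    ``u_t = lap(u) - c div(u grad v) + u (b - u)(u - d)``,
    ``v_t = D lap(v) + u - a v``.
``biharmonic``
    Scalar fourth-order model ``u_t = -D lap(u) - lap^2(u) + a u (c - u)(u - b)``.
``nonlocal_advection``
    Scalar cell-aggregation model ``u_t = D lap(u) + a u (c - u)(u - b)``
    minus the divergence of a nonlocal attraction flux
    ``d u (1 - u) * (odd exponential kernel convolved with u)``.

All parameters are strictly positive; the Keller-Segel kinetics are bistable
only for ``b > d`` and the scalar models for ``c > b``, which is enforced at
construction.  The ``base:<model_id>`` presets hold the reference parameter
sets used throughout the robustness study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

__all__ = [
    "MODEL_IDS",
    "REQUIRED_PARAMS",
    "N_FIELDS",
    "BASE_PARAMS",
    "ModelParams",
    "ModelSpec",
    "Equilibrium",
    "make_model",
    "base_model",
    "reaction_rates",
    "reaction_jacobian",
    "find_equilibria",
    "focal_equilibrium",
    "equilibria_table",
]

MODEL_IDS = (
    "reaction_diffusion",
    "keller_segel",
    "biharmonic",
    "nonlocal_advection",
)

#: Parameter names each model actually uses (beyond the dimension N).
REQUIRED_PARAMS = {
    "reaction_diffusion": ("L", "D", "a", "b", "c", "d", "e"),
    "keller_segel": ("L", "D", "a", "b", "c", "d"),
    "biharmonic": ("L", "D", "a", "b", "c"),
    "nonlocal_advection": ("L", "D", "a", "b", "c", "d"),
}

#: Number of dependent fields (u, and v where present).
N_FIELDS = {
    "reaction_diffusion": 2,
    "keller_segel": 2,
    "biharmonic": 1,
    "nonlocal_advection": 1,
}

#: Base parameter sets for the four models.
BASE_PARAMS = {
    "reaction_diffusion": dict(L=100.0, D=30.0, a=1.75, b=18.0, c=2.0, d=5.0, e=0.02),
    "keller_segel": dict(L=80.0, D=1.0, a=1.0, b=1.0, c=3.0, d=0.8),
    "biharmonic": dict(L=100.0, D=1.45, a=5.0, b=0.9, c=1.0),
    "nonlocal_advection": dict(L=30.0, D=1.0, a=1.0, b=0.45, c=0.5, d=20.0),
}

#: Tolerance below which a Jacobian eigenvalue's real part counts as marginal;
#: marginal equilibria are conservatively classified as unstable.
_STABILITY_TOL = 1e-10


class ModelValidationError(ValueError):
    """Raised for unknown model ids or invalid parameter sets."""


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of one model.

    ``L`` is the domain side length, ``D`` the diffusion (or destabilising
    second-order, for the biharmonic model) coefficient and ``a``..``e`` the
    kinetic/transport coefficients in the roles defined per model.  Entries a
    model does not use are ``None``.  ``N`` is the spatial dimension.
    """

    L: float
    D: float
    a: float | None = None
    b: float | None = None
    c: float | None = None
    d: float | None = None
    e: float | None = None
    N: int = 1

    def present(self) -> dict[str, float]:
        """The non-``None`` named parameters (excluding N)."""
        out = {}
        for name in ("L", "D", "a", "b", "c", "d", "e"):
            val = getattr(self, name)
            if val is not None:
                out[name] = float(val)
        return out


@dataclass(frozen=True)
class ModelSpec:
    """A validated model: identifier, parameters and number of fields."""

    model_id: str
    params: ModelParams
    n_fields: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n_fields", N_FIELDS[self.model_id])


@dataclass(frozen=True)
class Equilibrium:
    """A spatially homogeneous steady state of the kinetics.

    ``state`` is ``(u0,)`` or ``(u0, v0)``; ``kinetically_stable`` means every
    eigenvalue of the kinetics Jacobian has real part below ``-1e-10``;
    ``is_focal`` marks the equilibrium whose Turing instability the study
    analyses (exactly one per model).
    """

    state: tuple[float, ...]
    kinetically_stable: bool
    is_focal: bool = False

    @property
    def u0(self) -> float:
        return self.state[0]

    @property
    def v0(self) -> float | None:
        return self.state[1] if len(self.state) > 1 else None


def _validate(model_id: str, params: ModelParams) -> None:
    if model_id not in MODEL_IDS:
        raise ModelValidationError(f"unknown model_id {model_id!r}")
    required = REQUIRED_PARAMS[model_id]
    present = params.present()
    missing = [n for n in required if n not in present]
    extra = [n for n in present if n not in required]
    if missing:
        raise ModelValidationError(f"{model_id}: missing parameters {missing}")
    if extra:
        raise ModelValidationError(f"{model_id}: unused parameters {extra}")
    nonpos = [n for n in required if present[n] <= 0]
    if nonpos:
        raise ModelValidationError(f"{model_id}: non-positive parameters {nonpos}")
    if params.N not in (1, 2):
        raise ModelValidationError(f"N must be 1 or 2, got {params.N}")
    if model_id == "keller_segel" and not params.b > params.d:
        raise ModelValidationError(
            f"keller_segel requires b > d (got b={params.b}, d={params.d})"
        )
    if model_id in ("biharmonic", "nonlocal_advection") and not params.c > params.b:
        raise ModelValidationError(
            f"{model_id} requires c > b (got c={params.c}, b={params.b})"
        )


def make_model(model_id: str, params: ModelParams | dict) -> ModelSpec:
    """Validate a parameter set and bind it to a model.

    Raises :class:`ModelValidationError` on an unknown id, missing/extra or
    non-positive parameters, or a violated ordering constraint (``b > d`` for
    Keller-Segel, ``c > b`` for the scalar models).
    """
    if isinstance(params, dict):
        params = ModelParams(**params)
    _validate(model_id, params)
    return ModelSpec(model_id=model_id, params=params)


def base_model(model_id: str, N: int = 1) -> ModelSpec:
    """The ``base:<model_id>`` preset in ``N`` spatial dimensions."""
    if model_id not in BASE_PARAMS:
        raise ModelValidationError(f"unknown model_id {model_id!r}")
    return make_model(model_id, ModelParams(N=N, **BASE_PARAMS[model_id]))


def resolve_preset(name: str) -> ModelSpec:
    """Resolve a ``base:<model_id>`` preset name."""
    kind, _, model_id = name.partition(":")
    if kind != "base" or model_id not in MODEL_IDS:
        raise ModelValidationError(f"unknown preset {name!r}")
    return base_model(model_id)


# ---------------------------------------------------------------------------
# kinetics


def reaction_rates(spec: ModelSpec, state: Sequence) -> np.ndarray:
    """Reaction part of d/dt at a spatially uniform state.

    ``state`` is an array of shape ``(n_fields, ...)``; the kinetics are
    applied elementwise so the same function drives both the equilibrium
    analysis (scalars) and the PDE solvers (full grids).  Transport terms
    vanish on uniform states, so at such states this is the full rate.
    """
    p = spec.params
    state = np.asarray(state, dtype=float)
    if state.shape[0] != spec.n_fields:
        raise ValueError(
            f"state has {state.shape[0]} fields, expected {spec.n_fields}"
        )
    if spec.model_id == "reaction_diffusion":
        u, v = state[0], state[1]
        fu = u - v - p.e * u**3
        fv = p.a * v * (v + p.c) * (v - p.d) + p.b * u - p.e * v**3
        return np.stack([fu, fv])
    if spec.model_id == "keller_segel":
        u, v = state[0], state[1]
        fu = u * (p.b - u) * (u - p.d)
        fv = u - p.a * v
        return np.stack([fu, fv])
    # biharmonic and nonlocal_advection share the same cubic kinetics
    u = state[0]
    return np.stack([p.a * u * (p.c - u) * (u - p.b)])


def reaction_jacobian(spec: ModelSpec, state: Sequence) -> np.ndarray:
    """Exact Jacobian of :func:`reaction_rates` at a uniform state."""
    p = spec.params
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.n_fields,):
        raise ValueError(f"state must have shape ({spec.n_fields},)")
    if spec.model_id == "reaction_diffusion":
        u, v = state
        return np.array(
            [
                [1.0 - 3.0 * p.e * u**2, -1.0],
                [
                    p.b,
                    p.a * ((v + p.c) * (v - p.d) + v * (v - p.d) + v * (v + p.c))
                    - 3.0 * p.e * v**2,
                ],
            ]
        )
    if spec.model_id == "keller_segel":
        u, v = state
        du = (p.b - u) * (u - p.d) + u * (-(u - p.d)) + u * (p.b - u)
        return np.array([[du, 0.0], [1.0, -p.a]])
    (u,) = state
    du = p.a * ((p.c - u) * (u - p.b) - u * (u - p.b) + u * (p.c - u))
    return np.array([[du]])


def _is_stable(spec: ModelSpec, state: Sequence) -> bool:
    eigs = np.linalg.eigvals(reaction_jacobian(spec, state))
    return bool(np.max(eigs.real) < -_STABILITY_TOL)


def _focal_state(spec: ModelSpec) -> tuple[float, ...]:
    p = spec.params
    if spec.model_id == "reaction_diffusion":
        return (0.0, 0.0)
    if spec.model_id == "keller_segel":
        return (p.b, p.b / p.a)
    return (p.c,)


def focal_equilibrium(spec: ModelSpec) -> Equilibrium:
    """The equilibrium whose Turing instability the study analyses.

    ``(0, 0)`` for reaction-diffusion, ``(b, b/a)`` for Keller-Segel and
    ``u0 = c`` for the two scalar models.
    """
    state = _focal_state(spec)
    return Equilibrium(
        state=state, kinetically_stable=_is_stable(spec, state), is_focal=True
    )


class RootFindingError(RuntimeError):
    """Raised when the multi-start search fails to corroborate its root set."""


def _rd_equilibria_states(
    spec: ModelSpec,
    box: float = 30.0,
    n_starts: int = 13,
    dedupe_tol: float = 1e-6,
) -> list[tuple[float, float]]:
    """All real kinetic equilibria of the reaction-diffusion model.

    Multi-start Newton (scipy's hybrid Powell solver with analytic Jacobian)
    over a grid of starts in ``[-box, box]^2``, polished and deduplicated at
    distance ``dedupe_tol``.
    """

    def fun(x):
        return reaction_rates(spec, x)

    def jac(x):
        return reaction_jacobian(spec, x)

    roots: list[np.ndarray] = []
    grid = np.linspace(-box, box, n_starts)
    starts = [np.array([u, v]) for u in grid for v in grid]
    starts.append(np.zeros(2))
    n_converged = 0
    for x0 in starts:
        sol = scipy.optimize.root(fun, x0, jac=jac, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        x = sol.x
        # polish with a couple of plain Newton steps
        for _ in range(3):
            x = x - np.linalg.solve(jac(x), fun(x))
        if np.max(np.abs(fun(x))) > 1e-11:
            continue
        x[np.abs(x) < 1e-12] = 0.0  # snap denormal Newton residue to zero
        n_converged += 1
        if not any(np.max(np.abs(x - r)) < dedupe_tol for r in roots):
            roots.append(x)
    if n_converged < len(starts) // 4:
        raise RootFindingError(
            f"only {n_converged}/{len(starts)} starts converged; "
            "root set may be incomplete"
        )
    roots.sort(key=lambda r: (r[0], r[1]))
    return [tuple(map(float, r)) for r in roots]


def find_equilibria(spec: ModelSpec) -> list[Equilibrium]:
    """All real homogeneous equilibria, with kinetic-stability flags.

    Closed form for Keller-Segel (``u0 in {0, d, b}``, ``v0 = u0/a``) and the
    scalar models (``u0 in {0, b, c}``); multi-start Newton for the
    reaction-diffusion model.  Exactly one returned equilibrium has
    ``is_focal=True``.
    """
    p = spec.params
    if spec.model_id == "reaction_diffusion":
        states: list[tuple[float, ...]] = _rd_equilibria_states(spec)
    elif spec.model_id == "keller_segel":
        states = [(u0, u0 / p.a) for u0 in sorted((0.0, p.d, p.b))]
    else:
        states = [(u0,) for u0 in sorted((0.0, p.b, p.c))]
    focal = _focal_state(spec)
    out = []
    for s in states:
        resid = np.max(np.abs(reaction_rates(spec, np.asarray(s))))
        if resid > 1e-10:
            raise RootFindingError(f"state {s} has kinetic residual {resid:.3e}")
        is_focal = np.max(np.abs(np.asarray(s) - np.asarray(focal))) < 1e-9
        out.append(
            Equilibrium(
                state=tuple(map(float, s)),
                kinetically_stable=_is_stable(spec, s),
                is_focal=is_focal,
            )
        )
    if sum(e.is_focal for e in out) != 1:
        raise RootFindingError("focal equilibrium not found among roots")
    return out


def equilibria_table(spec: ModelSpec) -> "pandas.DataFrame":  # noqa: F821
    """Equilibria as a tidy table (model_id, index, u0, v0, flags)."""
    import pandas as pd

    rows = []
    for i, eq in enumerate(find_equilibria(spec)):
        rows.append(
            dict(
                model_id=spec.model_id,
                index=i,
                u0=eq.u0,
                v0=eq.v0 if eq.v0 is not None else np.nan,
                kinetically_stable=eq.kinetically_stable,
                is_focal=eq.is_focal,
            )
        )
    return pd.DataFrame(rows)
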