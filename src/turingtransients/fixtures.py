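"""Randomised study inputs: initial perturbations and parameter samples.

The robustness study perturbs each model in two ways.  Initial conditions
are the focal homogeneous equilibrium plus independent Gaussian noise of
standard deviation ``1e-2`` at every node of every field.  Parameters are
jittered by multiplying every base parameter — including the domain length
``L`` — by a Latin-Hypercube sample from ``[0.95, 1.05]``.

All randomness descends from one master seed: per-sample substreams are
spawned with :class:`numpy.random.SeedSequence` so a sweep's results do not
depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats.qmc

from .models import (
    Equilibrium,
    ModelSpec,
    REQUIRED_PARAMS,
    make_model,
)
from .solvers import FieldState, Grid

__all__ = [
    "PerturbationSpec",
    "SweepSample",
    "random_initial_condition",
    "single_mode_perturbation",
    "lhs_multipliers",
    "perturbed_models",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """How to perturb the homogeneous equilibrium at t=0.

    ``kind`` is ``"gaussian_noise"`` (iid normal of standard deviation
    ``sd`` at every node) or ``"single_mode"`` (one cosine mode, for
    linear-regime validation).  ``allow_zero_sd`` permits ``sd=0`` in tests
    that need the exact equilibrium.
    """

    kind: str = "gaussian_noise"
    sd: float = 1e-2
    mode: int | tuple[int, int] = 1
    amplitude: float = 1e-6
    seed: int = 0
    perturb_all_fields: bool = True
    allow_zero_sd: bool = False

    def __post_init__(self):
        if self.kind not in ("gaussian_noise", "single_mode"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "gaussian_noise" and self.sd <= 0 and not self.allow_zero_sd:
            raise ValueError("sd must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class SweepSample:
    """One parameter sample of the robustness sweep."""

    index: int
    multipliers: tuple[float, ...]
    spec: ModelSpec
    seed: int


def random_initial_condition(
    equilibrium: Equilibrium, grid: Grid, pspec: PerturbationSpec
) -> FieldState:
    """Equilibrium plus iid Gaussian noise at every node (all fields)."""
    if pspec.kind != "gaussian_noise":
        raise ValueError("random_initial_condition requires gaussian_noise kind")
    rng = np.random.default_rng(pspec.seed)
    n_fields = len(equilibrium.state)
    fields = np.empty((n_fields, *grid.shape))
    for i, val in enumerate(equilibrium.state):
        if i > 0 and not pspec.perturb_all_fields:
            fields[i] = val
        else:
            fields[i] = val + rng.normal(0.0, pspec.sd, size=grid.shape)
    return FieldState(t=0.0, fields=fields)


def single_mode_perturbation(
    equilibrium: Equilibrium,
    grid: Grid,
    mode: int | tuple[int, int],
    amplitude: float,
) -> FieldState:
    """Equilibrium plus one cosine eigenmode on the u field (v untouched).

    1D: ``u = u0 + amplitude * cos(2 pi k x / L)``; 2D the product of the
    axis cosines for the ``(m, n)`` pair.  The constant mode is rejected.
    """
    x = grid.coords()
    if grid.N == 1:
        k = int(mode)
        if k < 1:
            raise ValueError("mode index must be >= 1")
        pert = amplitude * np.cos(2 * np.pi * k * x / grid.L)
    else:
        m, n = mode
        if (m, n) == (0, 0):
            raise ValueError("the constant mode is not a perturbation")
        pert = amplitude * np.outer(
            np.cos(2 * np.pi * m * x / grid.L), np.cos(2 * np.pi * n * x / grid.L)
        )
    n_fields = len(equilibrium.state)
    fields = np.empty((n_fields, *grid.shape))
    for i, val in enumerate(equilibrium.state):
        fields[i] = val
    fields[0] += pert
    return FieldState(t=0.0, fields=fields)


def lhs_multipliers(
    n_samples: int, n_dims: int, seed: int, low: float = 0.95, high: float = 1.05
) -> np.ndarray:
    """Latin-Hypercube multipliers on ``[low, high]``.

    Plain (non-optimised) LHS: per dimension exactly one sample falls in
    each of the ``n_samples`` equal-width bins.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sampler = scipy.stats.qmc.LatinHypercube(d=n_dims, seed=seed, optimization=None)
    unit = sampler.random(n=n_samples)
    return low + (high - low) * unit


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic, collision-checked per-sample seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    seeds = np.array([s.generate_state(1)[0] & 0x7FFFFFFF for s in ss.spawn(n)])
    if len(np.unique(seeds)) != n:
        raise RuntimeError("child seed collision; change the master seed")
    return seeds


def perturbed_models(
    spec: ModelSpec,
    n_samples: int,
    seed: int,
    low: float = 0.95,
    high: float = 1.05,
) -> list[SweepSample]:
    """One multiplicatively perturbed model per LHS row.

    Every parameter the model uses (including ``L``) is multiplied by its
    own column of the LHS matrix; the dimension ``N`` is untouched.  Each
    sample carries its own derived seed for the initial condition.
    """
    names = REQUIRED_PARAMS[spec.model_id]
    mult = lhs_multipliers(n_samples, len(names), seed, low, high)
    seeds = child_seeds(seed, n_samples)
    base = spec.params
    out = []
    for i in range(n_samples):
        updates = {
            name: getattr(base, name) * mult[i, j] for j, name in enumerate(names)
        }
        params = replace(base, **updates)
        out.append(
            SweepSample(
                index=i,
                multipliers=tuple(map(float, mult[i])),
                spec=make_model(spec.model_id, params),
                seed=int(seeds[i]),
            )
        )
    return out
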