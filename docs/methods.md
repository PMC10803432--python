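# Methods

This note documents the models, numerical methods and design choices behind
`turingtransients`, in the spirit of the methods sections of simulation
packages: what is computed, with which approximations, and what the results
do and do not demonstrate.

## The models

Four reaction-transport models on a periodic domain `Ω = [0, L]` (1D) or
`[0, L]²` (2D), all with strictly positive parameters and mildly bistable
(cubic) kinetics:

1. **Reaction-diffusion** (two species):
   `u_t = ∇²u + u − v − e u³`,
   `v_t = D ∇²v + a v (v + c)(v − d) + b u − e v³`.
2. **Keller-Segel chemotaxis with Allee population kinetics**:
   `u_t = ∇²u − c ∇·(u ∇v) + u (b − u)(u − d)`,
   `v_t = D ∇²v + u − a v`, requiring `b > d` for bistability.
3. **Biharmonic** (scalar, fourth order):
   `u_t = −D ∇²u − ∇⁴u + a u (c − u)(u − b)`, requiring `c > b`.
4. **Nonlocal advection** (scalar aggregation):
   `u_t = D ∇²u + a u (c − u)(u − b) − d ∇·(u(1−u) K * u)`,
   where `K * u` is the convolution of `u` with the odd interaction kernel
   `(s/‖s‖) e^{−‖s‖}/(2π)`, requiring `c > b`.

The base parameter sets are exposed as presets (`base:<model_id>`):

| model               | L   | D    | a    | b    | c   | d   | e    |
|---------------------|-----|------|------|------|-----|-----|------|
| reaction_diffusion  | 100 | 30   | 1.75 | 18   | 2   | 5   | 0.02 |
| keller_segel        | 80  | 1    | 1    | 1    | 3   | 0.8 | –    |
| biharmonic          | 100 | 1.45 | 5    | 0.9  | 1   | –   | –    |
| nonlocal_advection  | 30  | 1    | 1    | 0.45 | 0.5 | 20  | –    |

Each model has one *focal* homogeneous equilibrium whose Turing instability
is analysed: `(0, 0)` (reaction-diffusion), `(b, b/a)` (Keller-Segel) and
`u₀ = c` (both scalar models).  Each model also has at least one *other*
kinetically stable homogeneous equilibrium — the essential ingredient for
transient patterning: the pattern that grows from the focal equilibrium can
collapse into the competing equilibrium's basin.

## Linear stability

On the periodic domain the negative Laplacian has eigenvalues
`ρ_k = (2πk/L)²` (1D) and `(2π/L)²(m²+n²)` (2D).  The growth rate
`λ(ρ)` of a perturbation in mode `ρ` is the leading eigenvalue of the
linearisation `M(ρ) = J + T(ρ)`, with `J` the kinetics Jacobian and `T` the
transport symbol (diagonal diffusion; the chemotaxis cross term
`+c u₀ ρ` in the (u, v) entry; `Dρ − ρ²` for the biharmonic model;
`−Dρ + u₀(1−u₀) d ρ / (π^{2−N}(1+ρ)^{(N+1)/2})` for the nonlocal model,
whose last factor is the kernel's Fourier transform expressed in `ρ = q²`).

The criterion for a Turing instability is `Re λ(0) < 0` together with
`Re λ(ρ_k) > 0` for some `k > 0`.  Two implementations are kept
deliberately separate and property-tested against each other to `1e-8`
relative error: the closed-form dispersion relation per model
(`growth_rate`) and the assembled-matrix eigenvalue (`growth_rate_numeric`).
The closed forms apply only at the focal equilibrium and raise otherwise;
the numeric route covers all equilibria.

**Discrete vs continuous modes.**  The sweep's Turing verdict scans the
discrete eigenvalues of the sampled (finite, perturbed-`L`) domain, because
those are the modes that can actually grow in the matching simulation; a
continuous-`ρ` maximisation is available as an option and is used where a
domain-independent statement is wanted (e.g. the 2D nonlocal claim).  The
default scan cutoff is four times the continuous argmax of `Re λ`, with a
floor of 10 — far above the unstable band of every base model.

**Stability flags** use strict `Re λ < −1e-10`; marginal eigenvalues are
conservatively classified unstable.

## Equilibria

Keller-Segel (`u₀ ∈ {0, d, b}`, `v₀ = u₀/a`) and the scalar models
(`u₀ ∈ {0, b, c}`) have closed-form equilibria.  The reaction-diffusion
kinetics are solved by multi-start damped Newton iteration (170 starts on a
grid over `[−30, 30]²`, hybrid-Powell with analytic Jacobian, three plain
Newton polishing steps, deduplication at `1e-6`); the root set is verified
in the test suite against elimination of `v = u − e u³` into a degree-9
polynomial whose real roots are found independently.  With base parameters
there are five real equilibria, two of them stable — the origin and one
other — matching the bistable structure of the other models.

## Simulation

* **Space.** Uniform periodic grids, 256 points per side in 1D and 128 in
  2D by default (≥ 10 points per fastest-growing wavelength and ≥ 128
  points per side for every base model; per-sample grids are rebuilt from
  the sampled `L`).  Local transport uses second-order central differences
  — the circulant 3/5-point Laplacian and its composition for `∇⁴`; the
  chemotaxis flux is discretised conservatively at cell faces with
  arithmetic-mean `u`, which conserves the discrete mean of `u` exactly.
  The nonlocal convolution is pseudospectral: the kernel enters through its
  analytic Fourier symbol `i q / (π(1+q²))` at the discrete wavenumbers, so
  the simulated linearisation agrees with the dispersion relation exactly
  (the periodisation error is negligible since the kernel decay length 1 is
  far below L = 30; an O(n²) quadrature oracle in the tests quantifies it).
* **Time.** IMEX ARS(2,2,2): linear transport implicit (L-stable, solved
  exactly in Fourier space since the FFT diagonalises the circulant
  stencils), reactions and nonlinear transport explicit.  Step doubling
  gives a local error estimate; accepted steps propagate the Richardson
  extrapolant.  Default tolerances are rtol `1e-6` / atol `1e-9` for single
  trajectories and rtol `1e-4` / atol `1e-8` inside sweeps — basin and
  patterned/unpatterned classification was verified to be identical from
  rtol `1e-3` down to `1e-6` on base-parameter runs, and a grid-refinement
  test (256 vs 512 nodes) checks classification stability.
* **Early termination.** A run may stop before `t = 1e4` only when its fate
  is decided: (a) pattern amplitude below `1e-7` (two decades under the
  `1e-5` patterning threshold) with the spatial mean within `1e-4` of a
  kinetically stable equilibrium that is *not* Turing unstable on this
  domain — from there the linearised dynamics are pure decay; or (b) a
  patterned state (amplitude above threshold) whose drift rate
  `max|Δu|/Δt` over a 100-time-unit window is below `1e-9` after a burn-in
  of `t = 1000` — converged patterns sit at drift ~`1e-10` while evolving
  transients sit many orders higher.  Remaining output samples then repeat
  the settled state.  Both checks can be disabled (`early_stop=False`).
* **Divergence.**  Non-finite states or step-size underflow raise an error
  carrying the last valid state; the sweep records such samples and
  excludes them from all denominators (none occur under the study
  protocol).

## The robustness sweep

Per sample: every parameter of the model (including `L`) is multiplied by
its own Latin-Hypercube draw from `[0.95, 1.05]` (plain LHS, no maximin
optimisation); the Turing verdict is computed on the sampled domain; the
model is integrated for `1e4` time units from the focal equilibrium plus
iid Gaussian noise (sd `1e-2`, all fields); and the final state is
classified: *patterned* if `max(u) − min(u) > 1e-5`, otherwise
*homogeneous_same* / *homogeneous_different* according to whether the
spatial-mean state is closer (relative Euclidean distance, margin of ten
thresholds) to the starting equilibrium or to a different one.  An
unpatterned state near no known equilibrium would be labelled different
with a warning; this does not occur in practice.  All randomness descends
from a single master seed through `SeedSequence` substreams, so results are
independent of execution order and bit-reproducible.

**Adaptive precision at the decision boundary.**  Near-marginal samples
(`|max Re λ| ≈ 0`, common for the biharmonic model whose base parameters
sit essentially on the Turing boundary) decay so slowly that the solver's
local-error floor at sweep tolerance can sustain a spurious amplitude of
order `rtol`, right around the `1e-5` patterning threshold.  Any sample
whose final amplitude lands between `0.2×` and `1e3×` the threshold is
therefore re-integrated once at rtol `1e-6` / atol `1e-10` and classified
from the refined run.  Genuine patterns (amplitudes of order 1, or stable
small-amplitude states near onset that persist at tight tolerance) are
unaffected; noise-floor artifacts drop by two or more decades and classify
as unpatterned.  Only a few percent of samples fall in the band, so the
extra cost is small.

The summary reports three percentages, with exact (Clopper-Pearson) 95%
intervals: unpatterned at final time; Turing unstable at the focal
equilibrium; and, conditional on Turing instability, decay to a different
homogeneous equilibrium ("Turing conditions insufficient").  The
conditional is reported as undefined, not zero, when no sample is Turing
unstable.

**Ensemble sizes.**  Dispersion-only sweeps (no simulation) run at
n = 2000 (1D) and n = 1000 (2D).  Full-simulation ensembles in the test
suite and acceptance script run at n = 50–100 per model, so their
percentages carry binomial noise of a few points; the reference study used
n = 10⁴ (1D) / 10³ (2D).

## What the synthetic inputs do and do not emulate

The generator reproduces exactly the stochastic structure of the study
protocol — iid Gaussian initial noise around an equilibrium and ±5%
multiplicative parameter jitter.  It does not model spatially correlated
noise, structural model error, boundary effects (domains are periodic by
construction) or perturbations applied to `v` only.  Passing tests
therefore demonstrate the robustness of *transient* patterning within this
protocol, not robustness to qualitatively different noise or geometry.

## Known limitations and open edges

* The 2D nonlocal-advection simulation is not implemented (the linear
  analysis is); requesting it raises `NotImplementedError`.
* Whether `v` should share the initial perturbation is a protocol choice;
  the default perturbs all fields, and `perturb_all_fields=False` restricts
  noise to `u`.
* Continuation of patterned branches, weakly nonlinear amplitude
  expansions, and classification of patterned attractors into localised vs
  domain-filling are out of scope.
* The biharmonic base parameters sit extremely close to the Turing
  boundary (`D²/4 − ac(c−b) ≈ 0.026`), so under ±5% parameter jitter only
  roughly half of the sampled parameter sets remain Turing unstable; the
  unpatterned-at-final statistic is insensitive to this (Turing-stable
  samples also end unpatterned), but the Turing-unstable percentage is not.
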