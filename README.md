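# turingtransients

A Turing instability — a spatially uniform equilibrium that is stable to
homogeneous perturbations but unstable to some finite-wavelength mode — is
the standard linear-theory diagnosis for self-organised pattern formation,
and it is routinely read as a prediction that a persistent pattern will
form.  This package implements a computational study showing that the
prediction can fail *robustly*: in four canonical reaction-transport models
whose kinetics are only mildly bistable, patterns triggered by a genuine
Turing instability grow, live transiently, and then collapse onto a
*different* stable homogeneous equilibrium.  It is aimed at researchers in
mathematical biology and pattern formation who want to reproduce, stress or
extend that analysis.

The four models, on periodic domains `[0, L]^N` (N = 1, 2):

* **reaction_diffusion** — `u_t = ∇²u + u − v − e u³`,
  `v_t = D∇²v + a v(v+c)(v−d) + b u − e v³`;
* **keller_segel** — chemotaxis `u_t = ∇²u − c∇·(u∇v) + u(b−u)(u−d)`,
  `v_t = D∇²v + u − a v`;
* **biharmonic** — `u_t = −D∇²u − ∇⁴u + a u(c−u)(u−b)`;
* **nonlocal_advection** — `u_t = D∇²u + a u(c−u)(u−b)` minus the
  divergence of a nonlocal attraction flux `d·u(1−u)·(K * u)` with an odd
  exponential kernel `K`.

For each model the package provides: homogeneous equilibria with kinetic
stability flags; the dispersion relation `λ(ρ)` on the discrete spectrum
`ρ_k` of the periodic Laplacian (closed form and an independent
matrix-eigenvalue route); the Turing verdict `Re λ(0) < 0 ∧ Re λ(ρ_k) > 0`;
finite-difference/pseudospectral IMEX solvers able to reach `t = 10⁴` time
units; and a Latin-Hypercube robustness sweep that jitters every parameter
by ±5%, simulates from Gaussian-perturbed equilibria (sd `10⁻²`), and
classifies each run as patterned, returned to the same equilibrium, or
decayed to a different one (threshold `max u − min u > 10⁻⁵` at `t = 10⁴`).

See `docs/methods.md` for the numerical methods and design choices.

## Worked example

Equilibria of the reaction-diffusion kinetics (five real roots, two stable
— the origin, which is the Turing-analysed one, and one competing
attractor):

```text
$ turing-transients equilibria --model reaction_diffusion --out out/eq
          model_id  index        u0        v0  kinetically_stable  is_focal
reaction_diffusion      0 -9.278506  6.697350               False     False
reaction_diffusion      1  0.000000  0.000000                True      True
reaction_diffusion      2  0.099172  0.099152               False     False
reaction_diffusion      3  2.535083  2.209241                True     False
reaction_diffusion      4  8.642757 -4.269046               False     False
```

The Keller-Segel focal equilibrium `(b, b/a) = (1, 1)` is Turing unstable
(positive growth over a band of spatial eigenvalues):

```text
$ turing-transients dispersion --model keller_segel --out out/disp
keller_segel at (1.0, 1.0): turing_unstable=True (max Re lambda = 0.2025 at rho = 0.7464)
```

Yet a seeded robustness sweep finds that every perturbed system abandons its
pattern — all simulations end unpatterned and, conditional on the Turing
instability, all decay to a different homogeneous equilibrium:

```text
$ turing-transients sweep --model keller_segel --n-samples 5 --seed 1 --out out/sweep
       model  N  n_samples  pct_unpatterned  pct_turing_unstable  pct_insufficient  n_diverged  seed
keller_segel  1          5            100.0                100.0             100.0           0     1
```

`pct_unpatterned` is the share of runs with final amplitude below `10⁻⁵`;
`pct_turing_unstable` the share whose sampled parameters still satisfy the
Turing conditions; `pct_insufficient` the share of those that nonetheless
decayed to a different homogeneous state — the headline "Turing conditions
are insufficient" statistic.  A single trajectory can be inspected with
`turing-transients simulate --model keller_segel --seed 1 --out out/run`,
which writes the kymograph CSV and a portable `.npz` trajectory.

The same machinery is available as a library:

```python
import turingtransients as tt

spec = tt.base_model("biharmonic")
report = tt.is_turing_unstable(spec)          # discrete modes of L = 100
print(report.turing_unstable, report.max_growth_rate)  # True 0.0232...

summary, outcomes = tt.run_sweep(tt.SweepConfig(
    model_id="biharmonic", n_samples=20, seed=3))
print(summary.pct_unpatterned)                # 100.0
```

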