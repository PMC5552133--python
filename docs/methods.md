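# Methods

## Model

The EFRBM describes mean-field, unidirectional transport of particles on
an `n`-site lattice. The state `x ∈ C^n = [0,1]^n` holds normalized site
densities. With the flow boundary conventions `x_0 ≡ 1` (saturated
source) and `x_{n+1} ≡ 0` (empty sink), and the interaction padding
`z_j = x_j` for `1 ≤ j ≤ n`, `z_j = 0` otherwise, the inter-site flows are

    g_i(x) = λ_i x_i (1 − x_{i+1}) (1 + (q−1) z_{i+2}) (1 + (r−1) z_{i−1}),
    i = 0..n,

and the dynamics are `dx_i/dt = g_{i−1} − g_i`. The two boundary
conventions are distinct on purpose — the exclusion factors use the
virtual full/empty sites, while a virtual site exerts no interaction
force — and both are implemented as pure index maps, never stored, to
rule out off-by-one corruption. The exit flow `R(t) = g_n(x(t))` carries
no new-neighbor factor because `z_{n+2} = 0`; for `n = 1` the old-neighbor
factor also drops (`z_0 = 0`) and the model is interactionless.

Assumptions inherited from the mean-field ansatz: occupation correlations
between neighboring sites are neglected; densities are continuous in
`[0,1]` (soft exclusion) rather than binary; rates are constant in time.

## Parameters

| parameter | meaning | units | constraints |
|---|---|---|---|
| `λ_0..λ_n` | source, hop and exit rates | 1/time | `λ_i > 0` |
| `q` | attachment force toward new neighbors | — | `q ≥ 0` |
| `r` | detachment force from existing neighbors | — | `r ≥ 0` |
| `E` | pair interaction energy (thermodynamic form) | `K_B T` | finite |

`q = r = 1` recovers the RFM; `q = r = 0` a soft "extended-object"
exclusion. Detailed balance with the energy split evenly between pair
creation and breaking gives `q = e^{E/2}`, `r = e^{−E/2}`, so `q·r = 1`;
all single-parameter analyses (sweeps, asymptotics, the `n = 2` closed
form) assume this coupling. `q·r = 0` is accepted by the flow algebra but
flagged: uniqueness and persistence guarantees need `q, r > 0` (at
`q = 1, r = 0`, `n = 3` the boundary segment `[1, 1, s]` is a continuum of
equilibria).

Homogeneity: scaling all rates by `c > 0` rescales time only, so steady
densities are invariant and the steady flow scales linearly. This is used
as a consistency check (`homogeneity_check`) and, via Euler's relations,
to validate the sensitivity module.

## Steady-state computation

`solve()` runs damped Newton on the vector field with the analytic
Jacobian (band structure: `g_i` touches sites `i−1..i+2`), starting from
`0.5·1_n`, with backtracking line search constrained to the open cube.
If Newton stalls, a homotopy walks `(r, q)` geometrically from the RFM
point `(1, 1)` — where Newton is reliable — to the target, warm-starting
each step; this rescues the extreme-interaction regimes where densities
approach the cube boundary and the Jacobian becomes ill-conditioned
(for the same reason, asymptotic validation grids are capped at
`ε ≥ 1e−5`). The last resort is integrate-to-convergence (LSODA,
`rtol 1e−12`), followed by a Newton polish. Tolerance: `|f(e)|_∞ < 1e−12`
by default; the reported `residual` is `max_i |g_i(e) − R|`, which is
`< 1e−10` for every converged result in the test suite.

For `n = 2` under `q = 1/r` the chain reduces to one quadratic:
with `a_1 = (1 − 1/r)(λ_2 r + λ_1) + λ_1 λ_2/λ_0`,

    e_2 = (λ_1 + λ_2 + a_1 − sqrt((λ_1 + λ_2 + a_1)² − 4 a_1 λ_1)) / (2 a_1),
    e_1 = λ_2 e_2 / (λ_1 + (λ_2 (1 − r) − λ_1) e_2).

`a_1` changes sign for small `r`; the implementation keeps the root as
written, verifies the feasibility condition `e_1, e_2 ∈ (0,1)`, and
raises a diagnostic rather than silently swapping roots if that ever
fails (it does not on the tested grids). `a_1 = 0` degenerates to a
linear equation and is handled explicitly; `r = 1` needs no special
casing (`a_1 = λ_1 λ_2/λ_0`).

### Multistability and the stability check

Contraction-based arguments suggest a unique, globally attracting steady
state for all `q, r > 0`. The package's own experiments falsify this in
the strong-attachment regime: the homogeneous six-site chain at
`r = 0.1, q = 10` has three interior equilibria, two of them locally
stable, with both basins reachable from uniform random starts; a second
stable state also coexists at `r = 0.01, q = 100`. (The gap in the
contraction argument: the equivalent RFM representation with
state-dependent rates `η_i = λ_i (1 + (q−1) z_{i+2})(1 + (r−1) z_{i−1})`
bounds the rates uniformly, but two different trajectories experience
*different* rate signals, so pairwise contraction of the frozen-rate
system does not transfer.)

Consequences for the implementation:

* every root returned by `solve()` is checked for linear stability
  (Hurwitz Jacobian); Newton landing on an unstable equilibrium triggers
  the fallback;
* when distinct stable equilibria are detected, `solve()` returns the
  attractor of the canonical interior start `0.5·1_n` and attaches a
  warning — this convention reproduces all the reference values;
* the global-convergence test suite draws random models from the
  moderate-interaction regime (`r ∈ [0.2, 5]` coupled), where repeated
  multi-start experiments found a single attractor; passing it therefore
  certifies global convergence only in that regime.

## Trajectory integration

LSODA with the analytic Jacobian, default `rtol 1e−10`, `atol 1e−12`:
the interaction factors make the effective rates span
`[min(1,q)min(1,r)λ, max(1,q)max(1,r)λ]`, which is stiff at extreme
`r`. States are never clipped inside the solver loop — clipping happens
only at reporting — so an escape from `[0,1]^n` beyond `100·atol + 1e−9`
is raised as an integrator-accuracy error (the exact flow cannot leave
the cube). The persistence margin `d = min_{t≥τ,i} min(x_i, 1−x_i)` is
reported empirically; no formula for `d(τ)` is available.

## Asymptotic expansions (`q = 1/r`)

Jam regime (`r → 0`): for `n = 2`, `e_1 = 1 + o(r)`,
`e_2 = 1 − (λ_2/λ_1) r + o(r)`, `R = λ_2 r + o(r)`; for `n = 3`,
`e_1 = 1 − λ_2λ_3/(λ_0(λ_2+λ_3)) r² + o(r²)`, `e_2 = 1 − (λ_3/λ_1) r² + o(r²)`,
`e_3 = λ_2/(λ_2+λ_3) + o(r)`, `R = λ_2λ_3/(λ_2+λ_3) r + o(r)`.

Separation regime (`r → ∞`, expansion variable `q = 1/r`): for `n = 2`,
`e_1 → λ_0/(λ_0+λ_1)`, `e_2 = (λ_1/λ_2) q + o(q)`,
`R → λ_0λ_1/(λ_0+λ_1)`; for `n = 3`, `e_2 = (λ_1/λ_2) q + o(q)` and the
leading densities `(a_1, a_3)` solve the limiting balance

    λ_0 (1 − a_1) = λ_1 a_1 (1 − a_3) = λ_3 a_3 (1 + λ_1/λ_2),

which has no closed form; eliminating `a_3` leaves a scalar equation
with a sign change across `(0,1)`, solved by Brent bracketing to 1e−15.
`R(r→∞) = λ_0 (1 − a_1)`. The first-order density coefficients
`b_1, b_3` also lack closed forms and are exposed as numerical values
extracted by Richardson extrapolation of the exact solution
(`large_r_n3_first_order`); the `e_3` first-order coefficient in the jam
regime is likewise not asserted anywhere, only its constant term.

`expansion_error_curve` validates every truncation empirically: the
log-log slope of |exact − truncated| against `ε` must exceed the
truncation order (asserted with a small margin in the tests).

## Contraction fits

`contraction_estimate` fits `log d(t)` by least squares on the trailing
70 % of a measured L1 distance curve (excluding the transient during
which a bounded overshoot is permitted), clips the rate at `ℓ ≥ 0`, and
sets the overshoot `ε` to the smallest prefactor making
`(1+ε) e^{−ℓt} d(0)` dominate the whole curve — so the envelope property
holds by construction and the meaningful outputs are `ℓ`, `ε` and the
fit's `r²`. Distances at numerical zero are dropped before taking logs.
No reference values for `ℓ` or `ε` exist; they are descriptive.

## Sensitivities

Central differences with step `h = 1e−6·max(1, |v|)` on the solved steady
state, justified by the analyticity of `e(·)` in the positive parameter
region; steps changing a parameter by more than 10 % are rejected.
Validation is by Euler's homogeneity relations
(`Σ λ_i ∂R/∂λ_i = R`, `Σ λ_i ∂e_k/∂λ_i = 0`) and, for `n = 2`, by a
complex-step derivative of the closed form.

## Problem sizes and reproducibility

All reference computations are desk-scale: lattices of 2–6 sites,
Newton in < 10 iterations, integrations to `t ≈ 10²–2·10⁴` time units
(longer horizons only in the slowly-relaxing extreme-interaction
regimes). The full test suite runs in well under a minute; the
acceptance script in seconds. Random fixtures (parameter draws, initial
conditions) always use an explicit `numpy` generator seed recorded at
the call site; `scripts/acceptance.py` derives every random start from
its `--seed` argument.

## Known limitations

* Printed four-digit reference values from trajectory simulations carry
  ~1e−4 error; where the exit flow amplifies the last-site density (large
  `r`, factor ≈ `λ_n r e_{n−1}`), a four-digit density determines `R` only
  to ~1e−3. Comparisons in the tests use tolerances consistent with this.
* The uniqueness caveat above: outside the moderate-interaction regime,
  "the" steady state means the canonical-start attractor.
* No stochastic (TASEP) engine, no configuration-space master equation,
  no attachment/detachment at interior sites, and no general-`n`
  asymptotic expansions (closed forms exist only for `n = 2, 3`).
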