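# Methods

## Model

The package integrates the dimensionless drift–diffusion system stated in
the README: an attractant field `C` that diffuses (ratio `N` of attractant
to bacterial diffusivity) and is consumed with Monod kinetics (strength
`H`, half-saturation `K_S`), and a bacterial density `B` transported by
the flux

    J = −V(C)² ∇B + (V_k + V_χ) B,

where the dimensionless swimming speed `V(C) = 1 + η Cⁿ/(Cⁿ+ωⁿ)` enters
the diffusivity as `V²`, the chemokinetic drift as `V_k = −V V'(C) ∇C`,
and the chemotactic drift as `V_χ = V² δ₀K_χ/(C+K_χ)² (∇C + ζ/V ∂C/∂T)`.
Logistic growth `B g(C)(1−B)` can be switched on independently of
consumption: a population may deplete a chemoeffector it does not grow on
(this is exactly the transient-source set-up, which has `H = 3.5` with
growth off), and `H = 0` disables consumption.  Speed adaptation is
instantaneous — `V` is a pure function of the local concentration; no
relaxation timescale is modelled.  Negative chemokinesis is admitted as
`η ∈ (−1, 0)`, keeping `V > 0`.

A `constant_speed` mode pins `V ≡ s` everywhere: diffusivity `s²`,
chemotactic prefactor `δ₀ s²`, chemokinetic drift zero.  It provides the
control populations ("same chemotaxis machinery, uniformly slower/faster
swimmer") used by the agar-plate benchmark.

The temporal term in `V_χ` uses the attractant equation's right-hand side
directly, not a finite difference of stored time levels: it is then
exactly zero for a frozen field and exactly the analytic `∂C/∂T` (up to
consumption) for the evolving pulse, and it introduces no coupling between
the time-discretizations of the two equations.

Dimensional parameters map onto the dimensionless set via `t₀ = 1/k_g`,
`D_b⁰ = v₀²/α`, `x₀ = √(t₀ D_b⁰)`; note `δ₀ = χ₀/D_b⁰` reduces exactly to
the chemotactic response constant `β` because `χ₀ = v₀²β/α`.  The
dimensionless logistic term `(1−B)` presumes densities are rescaled by the
carrying capacity, so `nondimensionalize(growth_on=True)` requires
`b₀ = k_b`.

## Closed forms

* **Dominance condition / threshold.**  For a stationary linear attractant
  profile, comparing `|V_k|` and `|V_χ|` pointwise (the common factor
  `V²|∇C|` divided out) gives `lhs = V'(C)/V` vs `rhs = δ₀K_χ/(C+K_χ)²`;
  evaluating at the steepest point of the speed response, `C = ω`, yields
  `n* = 4δ₀ωK_χ/(ω+K_χ)² (1/η + 1/2)`.  For `η ≤ 0` the drifts do not
  oppose and `hill_threshold` returns a `NEVER` sentinel (not `∞`), so
  parameter scans stay type-stable.
* **Zero-flux steady state.**  With zero-flux boundaries the steady flux
  vanishes identically, integrating to `B/B* = (V*/V) exp{δ₀[f(C) −
  f(C*)]}` with `f = C/(C+K_χ)`.  The `V*/V` prefactor is the `d ln V`
  part of `(1/2D) dD/dX` with `D = V²`.  This expression doubles as the
  main solver oracle.

## Numerical scheme

Finite volumes on a uniform cell-centered mesh, 1D Cartesian or
axisymmetric radial.  In the radial case all operators are assembled in
flux form with face-radius weights, so the on-axis `1/R` singularity is
never evaluated (the `R = 0` face flux is identically zero) and
`∇²R² = 4` holds exactly on interior cells.

**Face flux.**  The combined diffusion–advection flux through each face
uses Scharfetter–Gummel exponential fitting: with face diffusivity
`D_f` (arithmetic mean of the cell `V²` values), face drift `V_f`
(drift formulas evaluated at the face-averaged concentration and the
central difference gradient) and Péclet number `Pe = V_f Δ/D_f`,

    J = (D_f/Δ) [ 𝔅(−Pe) B_left − 𝔅(Pe) B_right ],   𝔅(x) = x/(eˣ−1).

This reduces to central differencing as `|Pe| → 0` and to first-order
upwinding as `|Pe| → ∞`, is discretely conservative (face fluxes
telescope; population conserved to round-off with growth off), is
positivity-preserving under the explicit step bound, and reproduces the
zero-flux steady state `B_{i+1}/B_i = exp(Pe)` exactly up to midpoint
quadrature error.  The last property is what makes the scheme viable
here: chemotactic steady states at `δ₀ = 50` span ~14 orders of magnitude
in density across the domain, and a plain first-order upwind flux (whose
discrete steady state is `1+Pe` per cell) accumulates an O(1) exponent
error at any affordable resolution.  Measured, the fixed-linear-gradient
scenario at 400 cells matches the closed-form steady profile to
L1 ≈ 5·10⁻⁷, and a
mesh-halving study shows the expected second-order behaviour.

The Bernoulli function is evaluated in a branch-stable form (series below
|x| = 10⁻⁵, asymptotics beyond |x| = 700), and the Hill response uses
`Cⁿ/(Cⁿ+ωⁿ) = 1/(1+(ω/C)ⁿ)`, which stays finite at exponents where `Cⁿ`
itself underflows (relevant from `n ≈ 40` upwards).

**Time stepping.**  Adaptive explicit Euler with the combined bound
`dt = s / (2 D_max/Δ² + |V|_max/Δ + r_max)`, safety `s = 0.4` and `r_max`
the fastest pointwise reaction rate; this is also (a factor-2-conservative
version of) the positivity condition of the update matrix.  Steps land on
requested snapshot times exactly.  Negative densities from round-off are
clipped to zero with the clipped mass accumulated; a run whose cumulative
clipped mass exceeds 10⁻⁶ of the population aborts, as does step collapse
below `dt_min`.

The production path is a numba-compiled kernel; the pure-NumPy loop in
`engine.py` is the reference implementation (and handles arbitrary
prescribed attractant fields).  Both paths implement the identical scheme
and a test holds them to near-machine agreement, step for step.  When the
attractant is frozen, all face coefficients are constant in time and are
precomputed once, reducing each step to a linear three-point stencil.

## Scenarios and defaults

Parameter sets of the three benchmarks are stored verbatim as data, not
recomputed.  Geometry, initial-condition shapes and output schedules are
the package's own choices:

* **Linear gradient** (frozen `C`, Cartesian): domain `[0, 10]`, 400
  cells, `C` linear from 0 to 1, inoculum a Gaussian bump at `X = 0.5`
  with width 2% of the domain scaled to a domain-mean density of 0.2.
  Snapshots `T = 0.5, 1, 9, 17`.  Variants: pure chemotaxis (`η = 0`) and
  the Hill sweep `n = 1, 5, 10, 40`.
* **Agar plate** (dynamic `C`, axisymmetric, growth on, `ζ = 0` — the
  self-generated profile is stationary relative to the travelling wave):
  domain `R ∈ [0, 120]`, 1800 cells, `C ≡ 1`, inoculum Gaussian at the
  origin.  At these parameters (`δ₀ = 105`) the wave accelerates to front
  speeds ≈ 5, reaching `R ≈ 90` by `T = 16.4`; the domain is sized so the
  front stays > 25 length units from the boundary at the last snapshot.
  Variants: constant-speed controls at `s = 1` and `s = 1+η`.
* **Transient source** (dynamic `C`, axisymmetric, growth off,
  consumption on): domain `R ∈ [0, 10]`, 600 cells, `B ≡ 0.2`, `C` the 2D
  heat kernel with content `S = 0.5` started at `T₀ = 0.01`,
  `ζ = 8.164·10⁻³`.  `B_S` (the profile maximum) is sampled every 0.02
  time units up to `T = 1`.  By default the attractant is *evolved* (so
  consumption acts on it); a `c_analytic` flag imposes the kernel exactly
  instead.  Variants: {chemokinetic, pure chemotaxis} × {ζ as set, ζ = 0}.

A `boundary_sensitivity` helper reruns a variant on a doubled domain at
fixed spacing and reports the relative change of the peak density and of
the population inside the original domain; for the axisymmetric scenarios
at their defaults this change is far below 0.5%.

## Observables

`peak_density` (the accumulation-at-source observable `B_S`; ties break
towards the axis), `total_population` (`Σ B_i w_i` with `w_i = Δ` or
`2πR_iΔ`), and `front_position` (outermost linear-interpolated crossing of
`threshold_frac · max B`, plus the width between outermost and innermost
crossings).  The front threshold defaults to 0.1 and is config-exposed;
the *wave-broadening* comparison uses the width at half maximum
(`threshold_frac = 0.5`), which isolates the band around the peak from the
plateau the growing population leaves behind.

## Interpretation notes and limitations

* On the plate, both the front-speed and the integrated-population
  orderings (constant speed 1 < chemokinetic < constant speed `1+η`) hold
  strictly at every output time from `T = 1` on; the half-max width of the
  chemokinetic wave exceeds both controls by a factor ~2–4.
* Around the spreading pulse, most of the inflowing population sits at
  radii where the concentration is still *rising* (`R > 2√(NT)`), so
  including the temporal correction (`ζ > 0`) *increases* the predicted
  accumulation for the purely chemotactic population; chemokinesis shrinks
  the `ζ`-induced shift by more than half at every output time, because
  the perturbation enters as `ζ/V`.  The chemokinetic-vs-chemotactic
  advantage in `B_S` peaks at ~11% on the sampled schedule.  During the
  very first rise (`T < 0.02`), while both peaks are still near the
  background 0.2, the *relative* excess is transiently much larger; the
  reported value refers to the accumulated phase that the schedule
  samples.
* The scenarios emulate idealised assay geometries: deterministic,
  axisymmetric or 1D, with smooth initial data and a single chemoeffector
  acting as both attractant and (on the plate) nutrient.  Real assays add
  sensing noise, finite speed-adaptation kinetics, 3D structure and
  heterogeneous media — none of which are modelled, so passing benchmarks
  validates the continuum model's dynamics, not quantitative agreement
  with any particular experiment.
* Chemosensing-precision effects of a concentration-dependent speed are
  out of scope, as are agent-based microscopic simulations, 2D
  non-axisymmetric geometry, and unstructured meshes.
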