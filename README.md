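# kinetax

Finite-volume simulation of bacterial populations that combine
**chemotaxis** (biasing run-and-tumble motility up attractant gradients)
with **chemokinesis** (swimming faster at higher attractant
concentration), in the continuum Keller–Segel framework.  Several soil and
marine bacteria show both responses; because a concentration-dependent
speed drives a drift *down* the gradient (towards low speed), the two
responses compete, and their interplay shapes how populations migrate and
accumulate around nutrient sources.  The package is aimed at modellers of
microbial spatial ecology who want the coupled dynamics, the closed-form
limits, and the standard assay geometries in one place.

## Model

In dimensionless form (time in units of the inverse growth rate, length in
units of the run-and-tumble diffusion length, densities rescaled by their
characteristic values) the model reads

    ∂C/∂T = N ∇²C − H B C/(C+K_S)
    ∂B/∂T = −∇·J + B C/(C+K_S) (1−B)
        J = −V(C)² ∇B + (V_k + V_χ) B

with the Hill-type speed response and the two drifts

     V(C) = 1 + η Cⁿ/(Cⁿ+ωⁿ)
      V_k = −V (dV/dC) ∇C                          (chemokinetic)
      V_χ = V² δ₀K_χ/(C+K_χ)² (∇C + ζ/V ∂C/∂T)      (chemotactic)

Here `η` is the maximal relative speed increase, `ω` its half-saturation,
`n` the Hill exponent, `δ₀` the chemotactic sensitivity ratio, and `ζ`
scales the correction for temporally varying attractant fields (a swimming
cell perceives a different gradient when the field itself changes; the
perturbation shrinks at higher speed).  Closed-form results implemented
alongside the solver: the threshold Hill exponent

    n* = 4 δ₀ ω K_χ/(ω+K_χ)² (1/η + 1/2)

above which the chemokinetic drift beats the chemotactic drift at `C = ω`,
and the zero-flux steady state `B/B* = (V*/V) exp{δ₀[C/(C+K_χ) −
C*/(C*+K_χ)]}` used as a solver oracle.

Three benchmark scenarios are built in: a **fixed linear gradient**
(microfluidic channel), a **self-generated gradient** on an axisymmetric
agar plate (growth + consumption, travelling wave), and a **transient
attractant pulse** (diffusing heat kernel from a point-like release, e.g.
a lysed alga).

## Worked example

```python
import numpy as np
import kinetax as kx

spec = kx.make_linear_gradient()          # fixed-gradient benchmark
print(f"dominance threshold n* = {kx.hill_threshold(spec.params):.2f}")

ck = kx.run_variant(spec)                 # chemotaxis + chemokinesis
chemo = kx.run_variant(spec, "pure_chemotaxis")
for i, T in enumerate([0.5, 1.0]):
    print(f"T = {T}: peak B = {ck.states[i].B.max():.2f} "
          f"(pure chemotaxis: {chemo.states[i].B.max():.2f})")

pulse = kx.make_transient_source()        # diffusing attractant pulse
bs_ck = np.array([s.B.max() for s in kx.run_variant(pulse, "ck_zeta").states])
bs_ch = np.array([s.B.max() for s in kx.run_variant(pulse, "chemo_zeta").states])
print(f"max accumulation advantage = {100 * ((bs_ck - bs_ch)/bs_ch).max():.1f}%")
```

prints

```
dominance threshold n* = 39.78
T = 0.5: peak B = 1.17 (pure chemotaxis: 1.04)
T = 1.0: peak B = 2.46 (pure chemotaxis: 0.78)
max accumulation advantage = 11.1%
```

In the fixed gradient the chemokinetic population accumulates markedly
faster (its peak is already at the steady-state level by `T ≈ 1`, three
times the purely chemotactic peak), although both reach the same
steady-state profile peak (2.48) at long times — speed enhancement cancels
from the chemotactic part of the steady state.  Around the transient pulse
the chemokinetic population out-accumulates the chemotactic one by up to
~11% of the peak density `B_S`.

A thin CLI wraps the same machinery: `kinetax run <config.toml>` runs a
scenario (all variants) and writes time-series/snapshot tables plus run
metadata, and `kinetax analyze threshold <config.toml>` prints `n*` for
the configured parameters.  Config files round-trip `ScenarioSpec` exactly
(`spec.to_toml(path)` / `ScenarioSpec.from_toml(path)`).

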