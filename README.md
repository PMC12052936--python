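# acidfront

Toolkit for analyzing bistable traveling fronts in an acid-mediated model
of tumor invasion, and for predicting when the flat tumor–tissue interface
they describe becomes transversally unstable and starts to deform into
cusps or fingers.

## The model

Normal-cell density `U`, tumor-cell density `V` and acid concentration `W`
evolve on a 2D domain according to a regularized Gatenby–Gawlinski system
with an Allee effect in the tumor growth law (all quantities dimensionless):

    U_t = U(1 - U) - δ₁ U W
    V_t = ρ V(1 - V)(V - a) - δ₂ V W + ∇·((1 + κ - U) ∇V)
    W_t = δ₃ (V - W) + (1/ε²) ΔW

Tumor cells produce lactic acid; the acid kills normal cells at rate `δ₁`
and (more weakly) tumor cells at rate `δ₂`. The Allee threshold `a ∈ (0,1)`
makes the tumor kinetics bistable, so 1D invasion fronts exist at an
*isolated* wave speed `c`, and `κ` regularizes the cross-dependent tumor
diffusion. Acid diffuses much faster than cells (`0 < ε ≪ 1`), which makes
the system singularly perturbed and the front a slow/fast (two-scale)
object.

The toolkit implements four connected analyses:

1. **Singular limit** (`acidfront.singular_limit`) — at ε → 0 the front is
   a fast tanh interface at a frozen acid level `w*` (fixed by a
   Hamiltonian matching condition) concatenated with slow acid orbits.
   Three front types arise: *benign* (`δ₁V⁺ < 1`, normal cells survive
   behind the front), *malignant no-gap*, and *malignant gap*
   (`w* > 1/δ₁`), in which an acellular strip — acid only, no cells —
   opens behind the interface with slow-scale width `ln(δ₁w*)/√δ₃`.
2. **Traveling-wave BVP** (`acidfront.traveling_wave`) — the full
   five-component front at finite ε, solved by collocation with the speed
   `c` as an unknown, projected boundary conditions at the end equilibria
   and the singular concatenation as initial guess; plus natural-parameter
   continuation and gap-width measurement.
3. **Transverse stability** (`acidfront.stability`) — the curvature
   coefficient `λ_c''(0)/2 = λ_{c,2}` of the critical eigenvalue branch
   `λ_c(ℓ)` at transverse wavenumber ℓ, from the Fredholm solvability
   quotient against the adjoint null solution

       λ_{c,2} = − ∫[(1+κ−u_h) v_h' v^A + ε⁻² w_h' w^A] dξ
                 / ∫[u_h' u^A + v_h' v^A + w_h' w^A] dξ ,

   together with its ε → 0 closed-form asymptotics. `λ_{c,2} > 0` means
   long transverse wavelengths grow: the planar interface is unstable. A
   gap front with `δ₂ > 0` is always unstable in this sense.
4. **2D simulation** (`acidfront.simulate2d`) — IMEX evolution of the full
   model in the comoving frame from a noise-seeded planar front, with
   interface tracking and per-mode growth-rate fitting that validates the
   spectral predictions.

## Worked example

The reference parameter set `(a, κ, δ₁, δ₂, δ₃, ρ, ε) =
(0.35, 0.1, 12.5, 0.1, 70.0, 1.0, 0.0063)` describes an aggressive tumor:

```python
from acidfront import ModelParams, solve_front, measure_gap_width, lambda_c2

params = ModelParams(a=0.35, kappa=0.1, delta1=12.5, delta2=0.1,
                     delta3=70.0, rho=1.0, eps=0.0063)
front = solve_front(params)
print(front.singular.regime.kind.value)   # malignant_gap
print(round(front.singular.w_star, 4))    # 0.438   (jump acid level w*)
print(round(front.c, 5))                  # 0.04006 (invasion speed)
print(round(measure_gap_width(front)[0], 1))  # 28.9 (acellular gap, xi units)
print(round(lambda_c2(front), 3))         # 0.648  (> 0: interface unstable)
```

The front invades at speed `c ≈ 0.0401`, leaves a cell-free acid strip of
width ≈ 29 behind the tumor interface, and — because `λ_{c,2} > 0` — a
planar interface at these parameters is unstable to long-wavelength
transverse ripples, which 2D simulation shows growing into fingers at
exactly the spectrally predicted rates.

The same analyses are available from the shell:

```
acidfront singular --preset fig1
acidfront tw-solve --preset fig1 --out profile.csv
acidfront lambda2 --preset fig1
acidfront presets          # list the bundled parameter sets
```

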