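# Methods

This note records the mathematical procedures implemented in `acidfront`,
the numerical choices behind them, and their known limits. Symbols follow
the README: fields (U, V, W), parameters (a, κ, δ₁, δ₂, δ₃, ρ, ε), comoving
coordinate ξ = x + cτ, slow coordinate ζ = εξ.

## Model, equilibria and regimes

The kinetics admit the homogeneous states P₁ = (0,0,0), P₂ = (1,0,0),
P₃± = (1−δ₁V±, V±, V±) and P₄± = (0, V±, V±), where V± are the roots of
ρ(1−V)(V−a) = δ₂V; they exist when (ρ(1+a)−δ₂)² ≥ 4ρ²a. Stability is
evaluated from the 3×3 kinetics Jacobian: P₂ is stable, P₁/P₃⁻/P₄⁻
unstable, P₃⁺ stable iff δ₁V⁺ < 1 (the *benign* regime: normal cells
coexist with the tumor) and P₄⁺ stable iff δ₁V⁺ > 1 (*malignant*). The
toolkit treats δ₂ < δ₁ as a model assumption enforced by a warning rather
than an error so that parameter-plane sweeps crossing it remain runnable.

In the traveling-wave phase space (u, v, q, w, p) with
q = (1+κ−u)v′ − cv and p = w′/ε, the rest states carry q = −cV± (the
v-equation forces q = −cv at any equilibrium).

## Singular-limit front construction

At ε = 0 the five-dimensional traveling-wave ODE splits into

* the **layer problem** for (v, q) with (w, p) frozen, posed either in the
  invaded subspace u = 1−δ₁w (effective diffusion D = κ+δ₁w) or in the
  acid-only subspace u = 0 (D = 1+κ). Its heteroclinic is the explicit
  bistable front v(ξ) = (v⁺/2)(1 + tanh β ξ), β = (v⁺/2)√(ρ/2D), between
  the fast rest states v±(w) = (1+a ± √((1−a)² − 4δ₂w/ρ))/2, traveling at
  the isolated speed **c = √(2ρD)(v⁺/2 − v⁻)**. (Note the ρ-scaling: with
  the printed tanh profile, rescaling ξ by √ρ fixes the prefactor at
  √(2ρD), which collapses to the classical (1−2a)/√2 for ρ = D = 1,
  δ₂w = 0, and matches an independent shooting solver to 1e−12 over random
  parameter draws, including ρ ≠ 1.)
* the **reduced problem** w_ζζ = δ₃(w − v) on the critical manifolds, with
  v = 0 ahead of the front and v = v⁺(w) behind it. Both reduced flows are
  Hamiltonian: E₀ = p²/2 − δ₃w²/2 and E₊ = E₀ + δ₃(V⁺)²/2 +
  ∫_{V⁺}^w δ₃ v⁺(s) ds are conserved.

The fast jump occurs at the acid level w\* where the unstable manifold of
the tumor-free saddle (the line p = √δ₃ w) meets the stable manifold of
(V⁺, 0), i.e. the unique root in (0, V⁺) of
(V⁺)² + ∫_{V⁺}^{w\*} 2v⁺(z) dz = 0, located by Brent's method at xtol
1e−14 with the integral by adaptive Gauss–Kronrod quadrature (abs. tol.
1e−12); the δ₂ = 0 closed form w\* = 1/2 is kept as a test cross-check
only. Because w\* does not involve δ₁, the gap onset is simply δ₁ = 1/w\*.

Three concatenations follow. Benign: slow segment on the invaded branch,
jump at w\* in u = 1−δ₁w, slow segment to P₃⁺. Malignant no-gap: the same
jump, with the rear slow orbit crossing the transcritical curve w = 1/δ₁
(where u drops to 0). Malignant gap (w\* > 1/δ₁): the *front* slow orbit
crosses the transcritical curve first, producing a region with u = v = 0 —
the acellular gap — before the jump occurs in u = 0. The gap's slow-scale
width is the time of flight of w_ζζ = δ₃w from 1/δ₁ to w\*, which is
ln(δ₁w\*)/√δ₃ in closed form. Gap widths are reported in ζ units because
only those have a finite ε → 0 limit; the finite-ε measurement (below) is
converted by width_ζ = ε·width_ξ for comparison. When |δ₁w\* − 1| < 1e−8
the jump sits on the transcritical curve itself; the front is returned
with a degeneracy flag (persistence through the non-hyperbolic point is
not guaranteed) and the stability asymptotics decline to evaluate.

Fronts with negative layer speed (strong Allee effect and/or strong acid
toxicity to tumor cells, roughly a ≳ 0.38 at the reference sets) describe
tumor regression; the BVP solver rejects them explicitly — only invading
fronts (c > 0) are in scope.

## Finite-ε traveling waves

The five-component first-order system with unknown speed c is solved by
`scipy.integrate.solve_bvp` in a two-half formulation: the halves
[−L₋, 0] and [0, L₊] are each mapped to t ∈ [0, 1] and stacked into a
ten-component system, which turns the interior phase condition
v(0) = v⁺(w\*)/2 (pinning the translation gauge, paired with the unknown
c) and the five continuity conditions at ξ = 0 into ordinary boundary
conditions. Far-field closure projects the deviation from the end
equilibria onto their stable (left end, 3 conditions) and unstable (right
end, 2 conditions) eigenspaces, recomputed from the 5×5 Jacobian at each
iterate of c; this avoids the O(e^{−rate·L}) speed bias of hard Dirichlet
data. Counting: 3 + 2 + 5 + 1 = 11 conditions for 10 components plus one
parameter.

Numerics: truncation L = 16/(ε√δ₃) — 16 e-foldings of the slow decay rate,
which keeps the end-state mismatch (dominated by p = √δ₃w on the slow
tail) below 1e−6; initial mesh of ~1400 points per half, graded
geometrically into the layer at ξ = 0 and around the u-transition at the
transcritical crossing, with `solve_bvp`'s own residual-driven refinement
on top (typical converged meshes: 4–11k nodes); collocation tolerance
1e−8; analytic ODE Jacobians. The initial guess is the singular
concatenation itself, with the normal-cell profile obtained by integrating
its stiff scalar ODE along the guessed acid profile (LSODA) — at the
reference parameters the solve then converges in ~5 Newton/refinement
rounds and a few seconds. At the reference set the converged speed is
c = 0.04006 against the singular value c\* = 0.0526; the difference shrinks
linearly in ε, as expected of the first-order correction.

Continuation in a model parameter is natural-parameter with adaptive step
halving and the previous solution as the next guess. Each step rebuilds a
fresh graded mesh and interpolates the previous solution onto it: the
collocation solver only ever adds nodes, so inheriting refined meshes
would grow without bound along a branch. Pseudo-arclength continuation was
not needed — no folds arise in the sweeps covered here.

The acellular gap of a computed front is measured as the widest ξ-interval
on which both u and v stay below 10ε. The edge offsets of this threshold
rule are O(1) in ξ (tanh tail) plus O(√ε/ε) (the transcritical passage of
u), so the ζ-width converges to the singular value like √ε; at ε = 1e−4 it
agrees to a few percent.

## Transverse stability

Linearizing the comoving 2D system about a front with perturbations
∝ e^{iℓy + λτ} gives 𝕃φ = λφ + ℓ²Mφ with M = diag(0, 1+κ−u_h, 1/ε²) and 𝕃
the 1D linearization (including the nonlinear-diffusion couplings
−v_h″u − v_h′u_ξ − u_h′v_ξ). Translation invariance gives λ_c(0) = 0;
evenness in ℓ gives λ_c(ℓ) = λ_{c,2}ℓ² + O(ℓ⁴), and eliminating the ℓ²
corrector by Fredholm solvability against the bounded adjoint null
solution ψ = (u^A, v^A, w^A) yields the quotient quoted in the README.

Discretization: second-order finite differences on the front's own
(nonuniform) grid, node-interleaved for small bandwidth, Dirichlet at the
truncated ends, with an optional global mesh-bisection level (`refine`)
that pushes the O(h²) eigenvalue error down (the translational eigenvalue
sits at ~1e−6, ~3e−6 after one refinement at the sharpest preset, and
λ_{c,2} moves by ~4e−6 relative under refinement). The u-row advection is
upwinded: that equation has no diffusion and its coefficient F_u vanishes
on the transcritical curve, so central differences admit spurious
near-null sawtooth modes there which otherwise pollute the adjoint null
vector.

The adjoint is the transpose of the discrete operator
(discretize-then-transpose), so the discrete solvability identity holds
exactly; the discrete left null vector equals the continuous adjoint times
the trapezoid quadrature weights, and is computed by inverse iteration
about zero (a handful of sparse LU solves — shift-invert ARPACK is
unreliable when the shift coincides with an eigenvalue). It is normalized
so the quotient's denominator is one; the quotient itself is invariant to
this choice. The printed analytic adjoint operator serves as a
cross-check: pointwise on the (mollified) tumor row, and through
integrated identities on the normal-cell and acid rows, whose pointwise
forms are themselves singularly perturbed (derivative scales c/|F_u| and
ε).

The eigenvalue branch λ_c(ℓ) is tracked by shift-invert eigensolves seeded
with the previous eigenpair, and the numerically measured λ_c(0) (the
O(h²) bias of the translational eigenvalue) is subtracted from the whole
branch. The curvature is recovered by a least-squares fit of
aℓ² + bℓ⁴ over ℓ ≤ ℓ_ref/4, where ℓ_ref = (ε/2)√(|λ_{c,2}|δ₃) marks the
scale on which the transverse acid term starts to compete; across the four
reference presets the fit agrees with the solvability quotient to ≤ 1.5%.

The ε → 0 asymptotics evaluate λ_{c,2} ~ (1/εδ₃v⁺\*) · I_slow/I_vv ·
I_sign with I_slow = √δ₃w\*²/2 + ∫_{w\*}^{V⁺} p₊(w) dw (exponential branch
ahead, invaded-branch stable manifold behind, p₊ from E₊ = 0), I_vv =
∫ v\*_ξ² e^{−c\*ξ/D} dξ on the closed-form layer, and the sign integral
I_sign = ∫ (δ₁u\*ū\* + δ₂v\*v̄\*) dξ, where v̄\* = v\*_ξ e^{−c\*ξ/D} and
ū\* solves c\*ū′ + F_u ū = −v\*_ξ v̄\*_ξ (computed by an exact
exponential-kernel recursion, since F_u/c\* can reach O(100)). In the gap
case u\* = 0, so I_sign = δ₂∫v\*v̄\* > 0 whenever δ₂ > 0: gap fronts are
transversally unstable for small ε. The numeric and asymptotic values
agree in sign everywhere tested and converge toward each other as ε
decreases (ratio 0.39 → 0.86 over ε = 0.0063 → 0.0015 at the reference
set — the correction is O(√ε) relative, so pointwise agreement at
ε ≈ 0.006 is not expected; the asymptotics are a sign criterion there).
Since λ_{c,2} itself grows like 1/ε, reports carry both λ_{c,2} and
ε·λ_{c,2}.

The stability boundary in the (δ₁, δ₂) plane is located per δ₁ by scanning
the sign of the numeric λ_{c,2} along δ₂ (warm-started front solves) and
bisecting the first sign change. At the mapped parameters (a, κ, δ₃, ρ) =
(0.1, 0.1, 70, 1.0), ε = 0.0063, the unstable region lies at larger δ₂,
the boundary does not coincide with the benign/malignant curve δ₁V⁺ = 1
(both regimes contain both verdicts), and — at this finite ε — a gap front
with very small δ₂ can still be transversally *stable*, consistent with
the leading-order positivity being O(δ₂)/ε against an O(1) correction.

## 2D simulation and its validation contract

The full model is evolved in the frame moving at the 1D front's speed c_h,
so deformation of the interface is directly observable. Scheme (first
order in time, IMEX):

* acid: reaction and advection explicit; the stiff (1/ε²)Δ implicit via
  FFT in the periodic y-direction and tridiagonal solves in ξ;
* tumor: reaction, advection and the y-part of ∇·((1+κ−U)∇V) explicit; the
  ξ-part implicit with the coefficient lagged one step (tridiagonal solve
  per y-row);
* normal cells: explicit reaction with first-order upwind advection
  (no diffusion; inflow pinned at the healthy state);
* ξ-boundaries no-flux with a quadratic sponge relaxing the outer 5% of
  the domain to the end states; y periodic.

Initial data replicate a converged 1D front across y plus uniform noise of
amplitude 1e−3 on V (seeded, bit-reproducible). The interface h(y) is the
leftmost crossing of V through v⁺(w\*)/2 per row; transverse structure is
quantified by |ĥ(ℓ_k)|, ℓ_k = 2πk/L_y, and growth rates by least-squares
slopes of log|ĥ| over a stated window.

Default benchmark (chosen at the reference preset with ε = 0.05, whose
λ_c(ℓ) peaks near ℓ ≈ 0.11): grid ξ ∈ [−150, 80] at h_ξ = 0.1, N_y = 64
rows with L_y = 116 (modes 1–3 at ℓ = 0.054, 0.108, 0.163 — all unstable),
dt = 0.02, horizon T = 130 with the fit window τ ∈ [40, 130] (≈ e² growth
of the slowest mode, well inside the linear regime). Full-scale
long-horizon runs are not the contract; growth-rate agreement with the
spectral module is: on this benchmark the fitted σ(ℓ_k) match λ_c(ℓ_k) to
2–3% for the first three unstable modes. A noise-free run stays y-invariant
to round-off and drifts by < 1e−3 per unit time, bounding the
discretization bias of the comoving frame.

What the simulation does *not* model: lab-frame re-acceleration far behind
the interface over very long horizons (absorbed by the sponge), morphology
taxonomy of the nonlinear regime (cusps vs fingers is observed
qualitatively, asserted only as growth/saturation of the deformation), and
any spatial heterogeneity or phenotypic structure of real tumors — the
instability here is an emergent property of the homogeneous model.

## Parameter presets

`acidfront.workbench.PRESETS` bundles the reference parameter sets used
throughout these analyses (the 2D fingering run, the four 1D-stable gap
fronts, the δ₁ and a continuations, the (δ₁, δ₂) stability map); sweeps
carry their range and a default value. All randomness in the toolkit flows through seeds
recorded in `RunRecord`s, and replaying a record reproduces stochastic
outputs bit-identically.

## Known limitations

* Only slow invading fronts (frame exponent ν = 0, c > 0) are implemented;
  fast fronts and retreating fronts are rejected with explicit errors.
* Longitudinal stability is established numerically (point spectrum near 0
  plus end-state dispersion relations), not proven; the transverse theory
  assumes it.
* The degenerate crossover w\* = 1/δ₁ is flagged, not analyzed; persistence
  there would require blow-up desingularization.
* The asymptotic λ_{c,2} is a leading-order (sign-reliable) approximation;
  at ε ≈ 0.006 its magnitude differs from the numeric quotient by an O(√ε)
  relative correction.
* The stability-boundary scan brackets the first sign change along δ₂ and
  assumes monotonicity of the sign within the scanned window (verified on
  the mapped grid).
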