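# Methods

## Model

The simulator couples two modes of biological growth of the molluskan
mantle/shell system, treated as a single thin elastic body:

* **Surface growth (accretion).** The shell margin is a *generating curve*
  Γ with arclength coordinate ξ2 and local orthonormal frame {s1, s2, s3}
  (s1 = growth direction, s2 = margin tangent, s3 = surface normal,
  s3 = s1 × s2). Each increment lays down a strip of mantle of width δs
  along s1 and constant thickness h along s3. The strip is created in a
  *new* reference configuration attached to the **deformed** edge of the
  previously calcified shell: frames are recomputed on the deformed margin,
  so accretion follows whatever shape the previous increments produced.
* **Volume growth (morphoelasticity).** Within an increment the mantle
  grows along the margin direction only. The growth tensor follows from the
  exponential map, Fg = exp(ε2 Δt s2⊗s2) = I + (e^{ε2Δt} − 1) s2⊗s2, with
  s2 frozen at the strip's own reference frame at deposition; each new
  strip starts from Fg = I. The deformation gradient splits
  multiplicatively, F = Fe·Fg, and only Fe stores energy.
* **Elasticity.** Compressible neo-Hookean:
  ψ(Fe) = μ/2 (tr FeᵀFe − 3) − μ ln Je + λ/2 (ln Je)², P = ∂ψ/∂Fe.
  The equilibrium problem minimizes Π(u) = ∫ ψ(F Fg⁻¹) det Fg dV over the
  strip reference, with u = 0 on the trailing surface (attachment to the
  rigid, calcified shell) and the configured mix of fixed/traction-free
  lateral conditions.
* **Secretion and calcification.** Secretion is bookkeeping: the deformed
  active surface becomes the attachment surface of the next strip.
  Calcification freezes a strip at its deformed coordinates, bitwise,
  forever; it happens when the *next* strip is laid down, so a δs = 0
  increment keeps growing the still-elastic newest strip while the
  calcification front is exactly stationary (this is how hierarchical
  ornamentation protocols are expressed). A `remark2_elastic_tail(n)` mode
  keeps the last n secreted strips elastic instead.

The reduced model is a growing rod on an elastic foundation,
y'''' + (γ−1) y'' + kγ y = 0, whose dispersion relation
γ(q) = (q⁴+q²)/(q²−k) yields the critical growth
γ* = 1 + 2k + 2√(k+k²) at q*² = k + √(k²+k), i.e. a buckling mode number
n* = √(γ*−1)/(2√2 π) = q*/2π, scaling as √k for stiff foundations. The
bridge to the 3D model inverts n*(k)·L = n_FE per strip width and fits
k ~ δs^α. A linearized Kirchhoff–Love strip clamped along one long edge
(free elsewhere, compressed along the margin by a growth prestrain) serves
as a trend oracle for the width dependence of the critical strain and mode.

## Discretization and solver

* Structured hexahedral grids; trilinear geometry map; tensor-product
  Lagrange displacement basis of order 1 or 2 (order 2 default — one
  quadratic element through the thickness resolves bending without the
  shear locking of trilinear bricks). Full Gauss quadrature (p+1)³.
* Newton iteration in energy-minimization form: the residual is the exact
  gradient of Π, the tangent its Hessian; indefinite tangents are
  regularized Levenberg-style (K + τI with adaptive τ) and steps accepted
  by Armijo backtracking on the energy. This keeps iterates off unstable
  (saddle) equilibria such as the flat compressed state above the buckling
  threshold, which plain Newton happily converges to.
* Growth is ramped over `load_steps` (default 20; the sweep presets use 10)
  with the exponent interpolated through the exponential map, warm-started
  continuation for δs = 0 increments, and adaptive substep halving plus an
  L-BFGS energy-descent rescue when Newton stalls.
* After each load step the lowest eigenvalue of the reduced tangent is
  probed (shift-inverted eigensolves at two shifts near zero); a converged
  state with a negative eigenvalue is kicked along that eigenmode (sign by
  energy descent, amplitude `kick_fraction`·h) and re-equilibrated. This
  stability guard — rather than path-following continuation — is what turns
  imperfection seeding into a reliable bifurcation mechanism here.
* Symmetry breaking: a transverse geometric imperfection (smooth
  pseudo-random field along the margin, amplitude 1e-3·h, tapered to zero
  at each strip's trailing ring) is folded into every strip's reference
  coordinates at creation, deterministically in (seed, strip id). Amplitude
  0 recovers the perfect structure; doubling or halving it does not change
  the counted mode numbers in the shipped configurations.
* Convergence: relative residual 1e-8 where attainable. Deep post-buckling
  landscapes contain near-zero-stiffness pattern-phase modes (wrinkles
  sliding along a free-ended margin) along which the residual drains only
  asymptotically while the energy decreases monotonically by O(1e-7) per
  iteration; a stagnated state whose residual is below `loose_tol` (1e-3)
  of the full-increment growth-imbalance norm is accepted as an
  equilibrium. Mode counts and amplitudes are insensitive to this at the
  digit level reported.

## Morphology metrics

* Leading-edge deflection w = u·s3 against each node's reference frame;
  the mode number n counts local extrema of |w| above 10% of the maximum,
  following the more numerous sign family; `n_all` counts every crest.
* Curvature bias: a deflection bump of sign s has curvature −s at its
  extremum, so a crest is *compatible* with the local reference curvature κ
  when sign(w) = −sign(κ). The up/down ratio compares the largest
  compatible and incompatible deflections; the sign-agreement statistic
  considers prominent crests (≥50% of the peak) because the suppressed
  opposite family of an alternating wave disagrees by construction.
* Gaussian curvature by angle deficit with mixed (one-third) area weights
  on the triangulated mid-surface quads. "Crest region" statistics sample
  50–80% of the strip width at crest columns — outside the clamped zone and
  clear of the anticlastic (Poisson) boundary layer at the free edge.
* Edge curvature is measured on geometry (corner) nodes only: higher-order
  displacement nodes sit on trilinear chords and carry no curvature.

## Calibrated study conditions

The source results are dimensionless with the length scale set by the
radius of curvature r = 100 against δs = 1; neither the strip thickness nor
the arc extents are stated there, so they are calibrated once and shipped
in the presets:

* Mantle thickness h: 0.35 for the volume-growth cascade preset (critical
  increment δg* ≈ 0.12, so the 4× multiple stays inside the printed sweep
  range [0, 0.56]); 0.2–0.3 elsewhere (thinner strips lower all strains and
  speed the solves without changing the counted phenomenology).
* Arc extents: 19 for the cascade arc (≈6 buckling wavelengths at δs = 1;
  the doubled increment then develops seven crests), 20 for the
  width-sweep arc, 8 for the hierarchical protocol domain.
* Material: μ = 1, λ = 2 (Poisson ratio ≈ 1/3). μ only sets the stress
  scale; λ variations in [0.5, 9] were checked not to change mode counts.
* "First discernible bifurcation" in the upward growth sweep: the first
  increment whose leading-edge amplitude exceeds 2% of h — an order of
  magnitude above the imperfection response, an order below developed
  post-buckling amplitudes.
* Mesh densities are chosen per preset so that the shortest expected
  wavelength carries ≥6 quadratic elements; the width-family driver scales
  the margin resolution with the strip width.

## What the checks do and do not show

The synthetic protocols reproduce the mechanism-level phenomenology:
mode number falling inversely with the active mantle width (measured
exponent ≈ −0.8, rod-bridge stiffness exponent ≈ −1.6), the volume-growth
cascade from a localized onset to a filled seven-crest pattern with
amplitude-dominated growth beyond, hierarchical mode increase under
narrowing strips and a stationary front, crest-direction bias by
out-of-surface reference curvature, and saddle-shaped backward-arching
ornamentation under growth graded across the strip width.

Two quantitative discrepancies are documented rather than tuned away:
(1) at the first discernible bifurcation of the cascade the ±2-wavelength
crests of the localized pattern carry 11–50% of the peak amplitude, so the
10%-threshold count is 5 rather than 3 — in-plane curvature of magnitude
0.01 shifts the critical strain by less than 5e-5 here (measured by
linearized buckling analysis), which is too weak to confine the onset
pattern to the three central crests; and (2) the symmetric hierarchical
configurations lock the stage-3 parity (counts step 3 → 5), so the shipped
preset uses the shorter domain whose stages run 1 → 2 → 4. Deep growth at
3–4× the first-bifurcation increment adds one crest per multiple instead
of leaving the count fixed.

None of the fixtures emulate real shell data: geometry is ideal, material
homogeneous, contact is only detected (never prevented), and growth laws
are prescribed rather than coupled to stress or chemistry. Passing tests
validate the mechanics and bookkeeping of the implementation, not the
biology of any particular species.

## Known limitations

* No contact mechanics: self-intersecting states are reported, not
  prevented.
* No arc-length continuation; snap-throughs are crossed by substepping,
  stability kicks, and quasi-Newton rescue, which selects one of the
  coexisting stable branches (deterministically for a fixed seed).
* Quantities reported in deep post-buckling (≥3× critical) carry the
  loose-tolerance equilibrium caveat above.
* The plate stand-in is a reconstruction used only for trends; its absolute
  prefactor depends on the plate reduction chosen.
* Closed (circular) generating curves are supported by the geometry and
  solver layers but none of the shipped acceptance experiments exercise
  them beyond smoke level.
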