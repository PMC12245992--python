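# Methods

## Constitutive models

The pelvic floor muscle (PFM) is modeled with the Martins transversely
isotropic strain-energy function: an exponential isotropic matrix term
`U_m = c(e^{b(Ī₁−3)} − 1)`, an exponential passive fiber term
`U_fPE = A(e^{a(λ̄_f−1)²} − 1)`, an active fiber term
`U_fSE = θ T₀ᴹ[(λ̄_f−1) − (4/3)(λ̄_f−1)³]` (the closed form of the
activation integral), and a quadratic volumetric penalty
`U_J = (1/D)(J−1)²`. The invariants are isochoric (`Ī₁ = J^{−2/3} tr C`,
`λ̄_f = J^{−1/3}|FN|`), so the volumetric response is carried entirely by
`U_J`. Activation is off by default (`θ = 0`, passive muscle under
anesthesia-like relaxation); the active branch is implemented and tested
but inert.

Parameters (MPa where dimensional): `c = 0.0185`, `b = 1.1730`,
`A = 0.0280`, `a = 0.6215`. Two constants have no published value and are
package choices:

* `D = 0.1 MPa⁻¹`, i.e. volumetric stiffness `1/D = 10 MPa` — more than
  200× the matrix shear modulus `2cb ≈ 0.0434 MPa`, making the
  compressible evaluation near-incompressible. Configurable.
* `T₀ᴹ = 0.682 MPa` — a placeholder that only enters when `θ > 0`.

Cauchy ("true") stress is the stress measure throughout; principal-stress
outputs are eigenvalues of these tensors. Stresses are derived
analytically by push-forward of `∂U/∂F` and cross-checked in the test
suite against a central-difference first Piola–Kirchhoff oracle
(`O(h²)`, `h = 10⁻⁶`), with agreement to relative 1e−5 on seeded random
isochoric states.

For the 1D ring kinematics, incompressibility is imposed analytically: the
stress state is incompressible uniaxial along the hoop direction with the
hydrostatic pressure fixed by the traction-free lateral condition. No
mixed formulation is needed because no mesh exists in this package.

The perineal body and bulbospongiosus are linear elastic (E = 23.8 kPa,
ν = 0.49). A linear law has no canonical finite-strain extension, so the
ring model uses the engineering-strain convention `σ = E(λ − 1)` even at
large stretch, mirroring the constitutive simplicity of the original
choice. The anal sphincter is Neo-Hookean (`c₁₀ = 0.1 MPa`); it is part of
the material library but not one of the two evaluation rings. The fetal
head is linear elastic (E = 1.1 MPa, ν = 0.25).

## Viscoelasticity

A generalized Maxwell (quasi-linear) model with stress-like internal
variables. Each branch carries a stiffness ratio `B` relative to the
*equilibrium* (long-term) hyperelastic stress and a relaxation time `τ`;
the reduced relaxation function is `g(t) = 1 + Σ B_α e^{−t/τ_α}`. The
normalization in which the branches add to the equilibrium response (so the
instantaneous stiffness is `(1+ΣB)×` equilibrium) is the only one
consistent with branch ratios exceeding 1, as in the matrix set
(B = 1.5, 0.7, 0.5 at τ = 20, 400, 5000 s; fiber set B = 1.2, 0.5, 0.3 at
τ = 0.9, 250, 3500 s).

The update is the standard exponential integrator on overstresses,

    H_α ← e^{−Δt/τ_α} H_α + B_α e^{−Δt/(2τ_α)} ΔS,

exact for piecewise-constant stress increments; total stress = equilibrium
stress + Σ H_α. Matrix and fiber branch sets act on their respective
isochoric stress contributions independently (switching one set off leaves
the other's relaxation bit-identical). Time steps: 1 s during pulls and
rests, 60 s during the 3 h engagement ramp. A step coarser than
`min(τ)/10` is accepted (the integrator remains stable) but recorded as a
warning in relaxation-test metadata; with the default 1 s step the
shortest fiber branch (0.9 s) is under-resolved during transients, which
affects neither the instantaneous jump (applied exactly at Δt = 0) nor the
decay (exact exponential), and halving the step changes sweep stress
traces by well under 0.5%.

## Loading protocol

Engagement: 3 h at zero cup displacement, during which each ring's stretch
ramps linearly from 1 to an engagement pre-stretch `λ_eng = 1.3`
(configurable). This represents the head settling into the pelvic floor
during prolonged labor and gives the viscoelastic rings a loading history
before the first pull; the published record gives no per-path engagement
stretch, so 1.3 is a package default of plausible magnitude. Maneuver:
`n` pulls, each a linear ramp of `100/n` mm over one contraction,
separated by rests; no rest after the final pull. Equal descent per pull
and the linear in-pull ramp are the simplest readings of a protocol
specified only by totals. Scenario grid: contractions {60, 90} s, rests
{60, 180} s, pulls {2, 3, 4} — twelve scenarios.

## Reduced canal model

Two material rings stand in for the stress-evaluation paths: the levator
hiatus (PFM ring, Martins + viscoelasticity, fibers circumferential — hoop
loading is the dominant hiatal mode) and the urogenital hiatus (perineal
ring, linear elastic). An axisymmetric quasi-rigid head profile descends
along the canal axis; ring stretch is purely kinematic,
`λ = max(1, 2πρ(u)/C₀)` with `u` the head coordinate at the ring plane
(during the maneuver the kinematic value is floored at `λ_eng`). Treating
the head as rigid for ring kinematics is justified by its modulus being
~50× the PFM matrix stiffness; head compliance is exercised separately in
the compression-calibration module.

The cup traction force is a membrane projection
`F_y = Σ σ₁ A sin α`, where `α` is the local profile slope angle and `A`
an effective ring cross-section (defaults 300 mm² levator, 150 mm²
urogenital — order-of-magnitude choices). Absolute newtons from this
projection are not comparable to a 3D contact resultant; only
cross-scenario orderings are meaningful, and see Limitations for one
ordering this projection does not preserve.

## Synthetic anatomy (what it emulates, what it does not)

The default anatomy is *calibrated*, not predicted: a spherical head of
radius 47.5 mm (order of a term head; the sphere is the neutral choice for
an axisymmetric profile), ring circumferences `C₀ = 2πR/λ_peak`, and ring
stations placed so the head equator crosses each ring plane at the target
descent. This makes the kinematic anchors exact by construction: peak
levator stretch 2.09 at 69.91 mm of descent, peak urogenital stretch 3.01
at 79.51 mm (the urogenital ring sits 9.6 mm caudal). The generator
emulates the kinematic envelope of hiatal distension; it does not emulate
3D muscle geometry, fiber fields, contact pressure distributions, or
tissue damage, so passing tests demonstrate protocol- and
constitutive-level behavior, not patient-level prediction.

Perturbed cohorts multiply the head scale and each ring circumference by
independent mean-one lognormal factors with a given coefficient of
variation (peak stretch, a ratio of two such factors, then has CV ≈
√2 × cv). Compression curves for the head-modulus loop are the forward
Hertz model times independent multiplicative noise `1 + cv·z`. All
generators are pure functions of (parameters, seed).

## Head-compression calibration

Forward model: two-sided Hertzian contact on an elastic sphere between
rigid plates, `F = (4/3) E* √R (δ/2)^{3/2}`, `E* = E/(1−ν²)`, effective
radius 45 mm, ν fixed at 0.25 (only E is optimized, as in the workflow it
reproduces). In mm·MPa units the force is in newtons; at E = 1.1 MPa and
δ = 5 mm, F = 41.5 N. Recovery is a bounded least-squares fit (linear in
E, so convergence is immediate); diagnostics report the residual norm and
the Gauss–Newton relative standard error. Round-trip recovery is exact to
<0.1% on noiseless curves and within 2% at 2% multiplicative noise.

## Numerical choices

* Phase boundaries are exact samples; the final displacement is pinned to
  the prescribed total, and pull-boundary displacements are computed from
  the global formula so halving the step leaves boundaries bit-identical.
* Rest-phase relaxation percent is `100(σ_start − σ_end)/σ_start` over the
  rest window, with `σ_start` at the boundary sample where the rest
  begins; a rest starting at zero stress reports an undefined marker, not
  a division error.
* The head profile is sampled on 1001 nodes with the equator on-grid, so
  the peak-stretch anchors are attained exactly; off-node radii are linear
  interpolants.
* Degenerate inputs: a ring the head can never distend yields a valid run
  with λ ≡ 1 and zero stress plus a warning; non-positive `det F`,
  non-unit fibers, negative times/steps, and malformed curves raise typed
  errors.
* Everything is deterministic: repeated runs (and pipeline reruns with the
  same config and seed) are bit-identical, which the suite checks at the
  byte level on the CSV outputs.

## Known limitations

* Absolute stress magnitudes on the PFM ring (~7 MPa peak) are far above
  what a 3D model distributing load over a muscle body reports; the
  uniaxial hoop reduction concentrates the entire distension in one
  material direction. Orderings, relaxation percentages and timings are
  the claims, not magnitudes.
* The membrane force projection localizes the cup force at the two ring
  planes. Because `sin α` of a convex profile vanishes at the equator, the
  force window sits ~12 mm *before* the stress peak. One consequence: the
  two-pull scenario's single rest (at 50 mm) lands inside that window, so
  its peak force is capped below the three-pull scenario's — the model
  preserves the 2 > 4 and 3 > 4 peak-force orderings but *inverts* 2 vs 3,
  whereas a full 3D contact resultant peaks near maximum distension and
  preserves the monotone ordering. The peak-stress orderings are
  unaffected.
* At 60 s contraction / 180 s rest timing the two- and three-pull peak
  stresses are within 0.6% and the three-pull value is marginally higher
  (the long rest at 50 mm depresses the two-pull run-up); the monotone
  pull-count ordering is a robust property of the short-rest (60 s)
  timing.
* No contact mechanics, cup suction, head rotation/flexion, fiber fields,
  damage, or mesh-based geometry; the linear "elastic at large stretch"
  perineal law is a deliberate simplification.
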