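# vadsim

Reduced-order biomechanics of vacuum-assisted delivery (VAD).

Vacuum extraction is the most common operative vaginal delivery technique,
and it is associated with elevated rates of levator ani injury and perineal
tears. How the controllable factors of the maneuver — contraction duration,
rest interval between pulls, and the number of pulls — load the maternal
pelvic floor is a biomechanical question: the pelvic floor muscles (PFM)
are nonlinear, fiber-reinforced, and strongly viscoelastic, so the *timing*
of traction matters as much as its magnitude. `vadsim` is a desk-scale,
fully testable pipeline for exploring exactly that: it combines the
finite-strain constitutive models used in childbirth simulation with a
pull/rest loading protocol and a reduced two-ring model of the levator and
urogenital hiatuses distended by a descending fetal head.

It is aimed at biomechanics researchers and students who want a
transparent, scriptable sandbox for the tissue-level mechanics of assisted
delivery, without a finite-element contact model.

## The model

**Pelvic floor muscle** — transversely isotropic hyperelasticity (Martins
model) with strain energy

```
U = U_m + U_f + U_J
U_m   = c ( e^{b (Ī₁ − 3)} − 1 )
U_f   = A ( e^{a (λ̄_f − 1)²} − 1 )  +  θ T₀ᴹ [ (λ̄_f − 1) − (4/3)(λ̄_f − 1)³ ]
U_J   = (1/D) (J − 1)²
```

where `Ī₁` is the first isochoric invariant of the right Cauchy–Green
tensor, `λ̄_f` the isochoric fiber stretch, `J = det F`, and
`c = 0.0185 MPa, b = 1.1730, A = 0.0280 MPa, a = 0.6215` (activation
`θ = 0`: passive muscle). Cauchy stresses are derived analytically and
verified against central-difference differentiation of the energy.

**Viscoelasticity** — a generalized Maxwell model with separate matrix and
fiber branch sets (`B, τ`): matrix (1.5, 20 s), (0.7, 400 s), (0.5, 5000 s);
fiber (1.2, 0.9 s), (0.5, 250 s), (0.3, 3500 s). The reduced relaxation
function is `g(t) = 1 + Σ B_α e^{−t/τ_α}`, so the instantaneous stiffness
is 3.7× (matrix) and 3.0× (fiber) the equilibrium one. Integration uses the
standard exponential internal-variable recurrence
`H ← e^{−Δt/τ} H + B e^{−Δt/2τ} ΔS`.

**Other tissues** — perineal body / bulbospongiosus: linear elastic
(E = 23.8 kPa, ν = 0.49); external anal sphincter: Neo-Hookean
(c₁₀ = 0.1 MPa); fetal head: linear elastic (E = 1.1 MPa, ν = 0.25),
calibrated by a two-plate Hertzian compression to 5 mm deflection.

**Delivery protocol** — 3 h engagement, then `n` pulls, each a linear ramp
of `100/n` mm of cup descent over one contraction, separated by rests.
The clinical grid {60, 90} s × {60, 180} s × {2, 3, 4} pulls gives twelve
scenarios. The levator and urogenital hiatuses are material rings
kinematically distended by an axisymmetric head profile; their hoop stress
(Martins + viscoelastic for the PFM ring, linear elastic for the perineal
ring) and a membrane-projected cup traction force are recorded over time.

## Worked example

```
$ vadsim simulate --contraction 90 --rest 180 --pulls 3 --out out/
wrote out/scenario_c90_r180_p3.csv
peak PFM stress 6.4865 MPa at 66.67 mm; peak cup force 402.07 N
  rest_1: relaxation 15.79%
  rest_2: relaxation 23.86%
```

The peak pelvic-floor stress occurs at 66.67 mm of cup descent, just before
the levator hiatus reaches its maximum stretch of 2.09 (at 69.91 mm). Each
rest phase shows strictly positive stress relaxation — the second rest
relaxes the PFM stress by 23.9% — which is the mechanical argument for
longer rest intervals. Running the full grid,

```
$ vadsim sweep --out out/ --seed 1
$ vadsim report out/
```

shows the two headline orderings: shorter timing (60 s contraction / 60 s
rest) loads the PFM harder than 90 s / 180 s at every pull count
(7.078 vs 6.569 MPa at two pulls), and at 60/60 timing the peak stress
falls monotonically from two to four pulls (7.078 → 6.958 → 6.457 MPa, an
8.8% reduction). The urogenital (perineal) ring is purely elastic, so its
stress–displacement curve is identical in all twelve scenarios.

Absolute stress and force magnitudes from the two-ring reduction are not
comparable to a full 3D contact model (see `docs/methods.md`); the
cross-scenario orderings and relaxation percentages are the meaningful
outputs.

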