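# Packaged defaults: published tissue parameters and the twelve-scenario
# clinical grid.  All stresses/moduli in the unit noted per entry; times in
# seconds; lengths in mm.
materials:
  pfm:
    model: martins
    c: 0.0185        # MPa
    b: 1.1730
    A: 0.0280        # MPa
    a: 0.6215
    T0M: 0.682       # MPa, inert while theta = 0
    theta: 0.0
    D: 0.1           # 1/MPa -> volumetric stiffness 10 MPa
    matrix_branches: [[1.5, 20.0], [0.7, 400.0], [0.5, 5000.0]]
    fiber_branches: [[1.2, 0.9], [0.5, 250.0], [0.3, 3500.0]]
  perineal_body:
    model: linear_elastic
    E: 23.8
    unit: kPa
    nu: 0.49
  bulbospongiosus:
    model: linear_elastic
    E: 23.8
    unit: kPa
    nu: 0.49
  anal_sphincter:
    model: neo_hookean
    c10: 0.1         # MPa
  fetal_head:
    model: linear_elastic
    E: 1.1
    unit: MPa
    nu: 0.25
protocol:
  engagement_duration: 10800.0
  contractions: [60.0, 90.0]
  rests: [60.0, 180.0]
  pulls: [2, 3, 4]
  total_descent: 100.0
  dt: 1.0
  engagement_dt: 60.0
anatomy:
  head_radius: 47.5
  lambda_eng: 1.3
  levator_area_mm2: 300.0
  urogenital_area_mm2: 150.0
calibration:
  nu: 0.25
  radius: 45.0
  max_deflection: 5.0
  n_points: 20
  noise_cv: 0.02
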