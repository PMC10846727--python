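# Default heart-disease linguistic model.
#
# Seven input variables and the 0-10 risk-score output.  Terms are
# listed in order of increasing risk contribution; risk_scores are the
# ordinal scores the rule generator combines into a weighted risk sum.
# Piecewise-linear shapes store only their breakpoints: shoulders
# saturate at degree 1 toward one end of the universe, crisp sets are
# half-open intervals [lo, hi) (right_closed marks the last one).
variables:
  chest_pain:
    display_name: Chest Pain
    units: code
    universe: [0, 8]
    terms:
      - {term: NoPain,     shape: crisp, vertices: [[0, 1], [2, 1]]}
      - {term: NonAnginal, shape: crisp, vertices: [[2, 1], [4, 1]]}
      - {term: Atypical,   shape: crisp, vertices: [[4, 1], [6, 1]]}
      - {term: Typical,    shape: crisp, vertices: [[6, 1], [8, 1]], right_closed: true}
    risk_scores: [0, 1, 2, 3]

  hba1c:
    display_name: HbA1c
    units: "%"
    universe: [3, 14]
    terms:
      - {term: VeryHealthy, shape: left-shoulder,  vertices: [[6.5, 1], [7, 0]]}
      - {term: Healthy,     shape: trapezoidal,    vertices: [[6.5, 0], [7, 1], [8.5, 1], [9, 0]]}
      - {term: High,        shape: right-shoulder, vertices: [[8.5, 0], [9, 1]]}
    risk_scores: [0, 1, 2]

  hdl:
    display_name: HDL
    units: mg/dL
    universe: [10, 80]
    terms:
      - {term: Healthy, shape: right-shoulder, vertices: [[40, 0], [50, 1]]}
      - {term: Low,     shape: left-shoulder,  vertices: [[40, 1], [50, 0]]}
    risk_scores: [0, 1]

  ldl:
    display_name: LDL
    units: mg/dL
    universe: [40, 200]
    terms:
      - {term: VeryHealthy, shape: left-shoulder,  vertices: [[70, 1], [80, 0]]}
      - {term: Healthy,     shape: trapezoidal,    vertices: [[70, 0], [80, 1], [100, 1], [110, 0]]}
      - {term: High,        shape: trapezoidal,    vertices: [[100, 0], [110, 1], [130, 1], [140, 0]]}
      - {term: VeryHigh,    shape: trapezoidal,    vertices: [[130, 0], [140, 1], [160, 1], [170, 0]]}
      - {term: ExtraHigh,   shape: right-shoulder, vertices: [[160, 0], [170, 1]]}
    risk_scores: [0, 1, 2, 3, 4]

  heart_rate:
    display_name: Heart Rate
    units: bpm
    universe: [40, 160]
    terms:
      - {term: VeryHealthy, shape: left-shoulder,  vertices: [[60, 1], [70, 0]]}
      - {term: Healthy,     shape: trapezoidal,    vertices: [[60, 0], [70, 1], [90, 1], [100, 0]]}
      - {term: High,        shape: right-shoulder, vertices: [[90, 0], [100, 1]]}
    risk_scores: [0, 0.5, 2]

  age:
    display_name: Age
    units: years
    universe: [20, 120]
    terms:
      - {term: Young,   shape: left-shoulder,  vertices: [[40, 1], [45, 0]]}
      - {term: Mid,     shape: trapezoidal,    vertices: [[40, 0], [45, 1], [60, 1], [65, 0]]}
      - {term: Old,     shape: trapezoidal,    vertices: [[60, 0], [65, 1], [80, 1], [85, 0]]}
      - {term: VeryOld, shape: right-shoulder, vertices: [[80, 0], [85, 1]]}
    risk_scores: [0, 1, 2, 3]

  blood_pressure:
    display_name: Blood Pressure
    units: mmHg
    universe: [80, 240]
    terms:
      - {term: Normal,   shape: left-shoulder,  vertices: [[120, 1], [140, 0]]}
      - {term: High,     shape: trapezoidal,    vertices: [[120, 0], [140, 1], [180, 1], [200, 0]]}
      - {term: VeryHigh, shape: right-shoulder, vertices: [[180, 0], [200, 1]]}
    risk_scores: [0, 1, 2]

  result:
    display_name: Heart Disease Status
    units: score
    universe: [0, 10]
    role: output
    terms:
      - {term: Healthy,    shape: triangular, vertices: [[0, 0], [2, 1], [4, 0]]}
      - {term: LowRisk,    shape: triangular, vertices: [[2, 0], [4, 1], [6, 0]]}
      - {term: MediumRisk, shape: triangular, vertices: [[4, 0], [6, 1], [8, 0]]}
      - {term: HighRisk,   shape: triangular, vertices: [[6, 0], [8, 1], [10, 0]]}
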