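{
  "theta1": -1.2504,
  "theta2": 0.4236,
  "theta3": 2.5152,
  "theta4": 0.2518,
  "theta5": 0.1639,
  "theta6": 0.3730,
  "theta7": 0.0699,
  "theta8": 0.8894,
  "theta9": 1.4741,
  "theta10": 7.8735,
  "theta11": 0.0002,
  "theta12": 1.6008,
  "tau_R": 1.0,
  "tau_D": 1.0,
  "M_min": 0.25,
  "dt": 0.125,
  "D_bounds": [0.0, 52.0],
  "R_bounds": [0.0, 39.0],
  "S_bounds": [0.0, null]
}
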