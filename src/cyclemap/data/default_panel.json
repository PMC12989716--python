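{
  "version": 1,
  "noise_sd": 0.2,
  "batch_shift_sd": 0.1,
  "batch_scale_sd": 0.0,
  "phase_segments": {
    "G1": [
      0.0,
      0.35
    ],
    "S": [
      0.35,
      0.6
    ],
    "G2": [
      0.6,
      0.8
    ],
    "M": [
      0.8,
      1.0
    ]
  },
  "endocycle_segment": [
    0.8,
    1.0
  ],
  "transition_halfwidth": 0.015,
  "endocycle_peak_time": 0.84,
  "endocycle_exit_blend": 0.5,
  "log_levels": {
    "pRB": {
      "G1": 1.6,
      "S": 1.8,
      "G2": 1.8,
      "M": 1.7,
      "endocycle": 1.7,
      "nonproliferative": 0.1
    },
    "AKT": {
      "G1": 1.0,
      "S": 1.1,
      "G2": 1.2,
      "M": 1.0,
      "endocycle": 1.6,
      "nonproliferative": 0.9
    },
    "p16": {
      "G1": 0.6,
      "S": 0.5,
      "G2": 0.5,
      "M": 0.5,
      "endocycle": 0.8,
      "nonproliferative": 1.5
    },
    "p21": {
      "G1": 0.7,
      "S": 0.5,
      "G2": 0.6,
      "M": 0.6,
      "endocycle": 1.1,
      "nonproliferative": 1.6
    },
    "RB": {
      "G1": 1.2,
      "S": 1.2,
      "G2": 1.3,
      "M": 1.3,
      "endocycle": 1.3,
      "nonproliferative": 1.1
    },
    "CDK6": {
      "G1": 1.4,
      "S": 1.0,
      "G2": 0.8,
      "M": 0.8,
      "endocycle": 0.9,
      "nonproliferative": 0.7
    },
    "Cyclin E2": {
      "G1": 1.0,
      "S": 1.7,
      "G2": 0.8,
      "M": 0.5,
      "endocycle": 1.2,
      "nonproliferative": 0.5
    },
    "Cyclin D1": {
      "G1": 1.8,
      "S": 1.0,
      "G2": 0.7,
      "M": 0.8,
      "endocycle": 0.9,
      "nonproliferative": 0.6
    },
    "CDK2": {
      "G1": 0.9,
      "S": 1.4,
      "G2": 1.5,
      "M": 1.0,
      "endocycle": 2.1,
      "nonproliferative": 0.7
    },
    "Wee1": {
      "G1": 0.7,
      "S": 0.9,
      "G2": 1.4,
      "M": 0.6,
      "endocycle": 2.0,
      "nonproliferative": 0.6
    },
    "Cyclin E1": {
      "G1": 1.1,
      "S": 1.8,
      "G2": 0.8,
      "M": 0.5,
      "endocycle": 1.1,
      "nonproliferative": 0.5
    },
    "p27": {
      "G1": 0.9,
      "S": 0.6,
      "G2": 0.6,
      "M": 0.8,
      "endocycle": 1.0,
      "nonproliferative": 1.5
    },
    "Smad4": {
      "G1": 1.0,
      "S": 1.0,
      "G2": 1.0,
      "M": 1.0,
      "endocycle": 1.1,
      "nonproliferative": 1.0
    },
    "CDK1": {
      "G1": 0.5,
      "S": 0.9,
      "G2": 1.7,
      "M": 2.4,
      "endocycle": 0.7,
      "nonproliferative": 0.4
    },
    "RAIDD": {
      "G1": 0.6,
      "S": 0.6,
      "G2": 0.7,
      "M": 0.6,
      "endocycle": 2.3,
      "nonproliferative": 0.6
    },
    "MDM2": {
      "G1": 1.0,
      "S": 1.0,
      "G2": 1.1,
      "M": 0.9,
      "endocycle": 1.4,
      "nonproliferative": 0.9
    },
    "cMyc": {
      "G1": 1.5,
      "S": 1.2,
      "G2": 1.0,
      "M": 0.9,
      "endocycle": 1.1,
      "nonproliferative": 0.8
    }
  }
}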