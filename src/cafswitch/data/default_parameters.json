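{
  "cancer": {
    "k1": 0.0015,
    "k2": 0.0487,
    "k21": 0.1,
    "k24": 0.012,
    "k3": 0.122,
    "k32": 0.502,
    "k4": 8.05e-05,
    "k42": 0.0115,
    "k5": 0.00016,
    "k52": 0.32
  },
  "fibroblast": {
    "floor_rates": true,
    "h1": 0.0514,
    "h11": {
      "m0": 0.053,
      "m1": -0.01,
      "m2": -0.05,
      "m3": -0.1
    },
    "h12": {
      "m0": 0.05,
      "m1": -0.5,
      "m2": -0.5,
      "m3": -1.0
    },
    "h32": {
      "m0": 0.05,
      "m1": 0.5,
      "m2": 0.5,
      "m3": 0.0
    },
    "h34": 8e-05,
    "h35": 0.0013,
    "h4": 0.109,
    "h42": 0.00015,
    "h54": 0.01
  }
}
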