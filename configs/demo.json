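{
  "seed": 17,
  "cohort": {
    "n": 60,
    "noise_sd": 0.003,
    "group_effects": {
      "sexlike": {
        "width": 2.5,
        "fat": -2.0
      }
    }
  },
  "scheme": "torso52",
  "channels": [
    "thickness",
    "leanness"
  ],
  "reflect": true,
  "variance_threshold": 0.95,
  "frame": {
    "margin": 0.05,
    "output_scale": 0.5
  },
  "annotate": {
    "method": "truth"
  },
  "stats": {
    "outcomes": [
      "sexlike"
    ],
    "p_enter": 0.05,
    "p_stay": 0.05
  }
}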