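{
  "ks_between_strata": {},
  "strata": {
    "close": {
      "category_fractions": {
        "0": {
          "high": 0.2,
          "intermediate": 0.65,
          "rare": 0.15
        },
        "1": {
          "high": 0.3,
          "intermediate": 0.6,
          "rare": 0.1
        },
        "2": {
          "high": 0.35,
          "intermediate": 0.65,
          "rare": 0.0
        }
      },
      "delta_rate": [
        -0.5,
        1.5,
        2.5,
        -1.5,
        -1.0,
        0.0,
        0.5,
        -2.0,
        3.0,
        4.5,
        -0.5,
        2.0,
        2.5,
        -2.5,
        -2.0,
        0.0,
        1.5,
        2.5,
        0.0,
        -2.5
      ],
      "n_neurons": 20,
      "reoccurrence": {
        "high": 1.0,
        "intermediate": 0.7692307692307693,
        "rare": 0.0
      }
    },
    "distant": {
      "n_neurons": 0
    }
  }
}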