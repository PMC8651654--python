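{
  "0-1": {
    "frac_abs_delta_le_2": 0.8,
    "mean_delta_rate": 0.15,
    "novel_high": {
      "ci": [
        0.5,
        3.5
      ],
      "frac_from_intermediate": 1.0,
      "mean_gain": 2.0,
      "n": 2
    },
    "recruitment_int_to_high": 0.15384615384615385,
    "reoccurrence": {
      "high": 1.0,
      "intermediate": 0.7692307692307693,
      "rare": 0.3333333333333333
    },
    "similarity_index": 0.7602053209491847,
    "similarity_null_mean": -0.021539150760226906,
    "transition_counts": [
      [
        1,
        2,
        0
      ],
      [
        1,
        10,
        2
      ],
      [
        0,
        0,
        4
      ]
    ]
  },
  "0-2": {
    "frac_abs_delta_le_2": 0.65,
    "mean_delta_rate": 0.4,
    "novel_high": {
      "ci": [
        2.5,
        4.5
      ],
      "frac_from_intermediate": 1.0,
      "mean_gain": 3.1666666666666665,
      "n": 3
    },
    "recruitment_int_to_high": 0.23076923076923078,
    "reoccurrence": {
      "high": 1.0,
      "intermediate": 0.7692307692307693,
      "rare": 0.0
    },
    "similarity_index": 0.6577574840540268,
    "similarity_null_mean": -0.06589155077935589,
    "transition_counts": [
      [
        0,
        3,
        0
      ],
      [
        0,
        10,
        3
      ],
      [
        0,
        0,
        4
      ]
    ]
  }
}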