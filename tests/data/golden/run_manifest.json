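{
  "config": {
    "aggregation": "pooled",
    "binarize_k_sd": 2.0,
    "binarize_smooth_frames": 20,
    "cohort": "app",
    "detect_duration_frames": 10,
    "detect_k_sd": 3.0,
    "detect_min_distance_frames": 15,
    "detect_smooth_frames": 5,
    "detrend_pct": 8.0,
    "detrend_window_s": 50.0,
    "distance_bin_edges_um": [
      0.0,
      50.0,
      100.0,
      150.0,
      200.0
    ],
    "f0_short_window_s": 1.0,
    "frame_rate_hz": 10.0,
    "frames_per_session": 1200,
    "lowpass_cutoff_hz": 5.0,
    "n_neurons": 20,
    "n_sessions": 3,
    "n_shuffles": 20,
    "neuropil_factor": 0.7,
    "noise_band_pct": 60.0,
    "out_dir": "tests/data/golden",
    "proximity_cutoff_um": 40.0,
    "seed": 7,
    "stack_path": null,
    "traces_path": null,
    "whisk_min_duration_s": 0.33,
    "whisk_path": null,
    "whisk_window_max_s": 2.0,
    "whisk_window_min_s": 1.0
  },
  "n_events_total": 364,
  "n_neurons": 20,
  "n_sessions": 3,
  "seed": 7,
  "version": "0.1.0"
}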