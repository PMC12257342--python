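{
  "name": "bmb-15mv-in-field",
  "alloy": {"Cu": 0.70, "Zn": 0.30},
  "irradiation": {"beam_energy_mv": 15.0, "mu": 500.0, "in_field": true},
  "detector": {"resolution_k": 2.0, "efficiency": 0.05, "background_rate": 0.2},
  "seed": 20250714,
  "simulation": {
    "decay_components": {"Cu-62": 0.87, "Zn-63": 0.13},
    "rate_at_t0_cpm": 100000.0,
    "duration_min": 120.0,
    "dt_min": 1.0,
    "background_cpm": 0.0,
    "spectrum_window_min": [0.0, 5.0],
    "roi_kev": [480.0, 545.0]
  },
  "fit": {"model": "mixture", "candidates": ["Cu-62", "Cu-64", "Zn-63"], "allow_background": false},
  "dosimetry": {
    "rate_calibration": {"value": 1.70, "reference_mu": 1000.0},
    "integrated_calibration": {
      "value": 17.13,
      "reference_mu": 1000.0,
      "contact_duration_min": 120.0,
      "first_interval_fraction": 0.0539
    },
    "scenario": {
      "mu_per_fraction": 500.0,
      "n_fractions": 25,
      "handling_time_min": 1.0,
      "handling_delay_min": 0.0,
      "full_decay_between_fractions": true
    },
    "limits": {"tede_mrem": 5000.0, "extremity_mrem": 50000.0}
  }
}
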