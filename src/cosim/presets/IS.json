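{
  "fixtures": {
    "n_regions": 16,
    "density": 1.0,
    "length_scale_mm": 10.0,
    "min_distance_mm": 2.0,
    "n_spiking": 2,
    "seed": 1,
    "speed_mm_per_ms": 1.0,
    "weight_normalization": "row_sum"
  },
  "spiking": {
    "dt": 0.1,
    "n_ex": 1600,
    "n_in": 400,
    "n_ext_synapses_per_neuron": 100,
    "background_rate_hz": 25.0,
    "I_ext_pA": 0.0,
    "n_record": 20,
    "record_interval_ms": 1.0,
    "adex_ex": {
      "C": 200.0,
      "g_L": 10.0,
      "E_L": -63.0,
      "V_T": -50.0,
      "Delta_T": 2.0,
      "V_peak": 0.0,
      "V_reset": -65.0,
      "tau_w": 680.0,
      "a": 0.0,
      "b": 100.0,
      "t_ref": 5.0
    },
    "adex_in": {
      "C": 200.0,
      "g_L": 10.0,
      "E_L": -65.0,
      "V_T": -50.0,
      "Delta_T": 0.5,
      "V_peak": 0.0,
      "V_reset": -65.0,
      "tau_w": 1.0,
      "a": 0.0,
      "b": 0.0,
      "t_ref": 5.0
    },
    "synapse": {
      "E_ex": 0.0,
      "E_in": -80.0,
      "tau_ex": 5.0,
      "tau_in": 5.0,
      "Q_ex": 7.5,
      "Q_in": 25.0,
      "p_conn": 0.05,
      "d_min": 0.1
    }
  },
  "mass": {
    "dt": 0.1,
    "record_interval_ms": 1.0,
    "init_rate_hz": 5.0,
    "params": {
      "T": 20.0,
      "nu_max": 60.0,
      "theta_e": 4.0,
      "theta_i": 8.0,
      "sigma_s": 2.0,
      "J_ee": 0.8,
      "J_ei": 1.2,
      "J_ie": 1.2,
      "J_ii": 0.8,
      "b_w": 0.0,
      "tau_w": 500.0,
      "w_scale": 1.0,
      "G": 0.6,
      "noise_sigma": 1.0
    }
  },
  "transfer": {
    "mip_c": 0.1,
    "timeout_s": 60.0
  },
  "sensors": {
    "n_per_hemisphere": 8,
    "exponent": 2.0,
    "gain": 1.0,
    "elevation_mm": 2.0
  },
  "run": {
    "t_end_ms": 11000.0,
    "sync_step_ms": 2.0,
    "master_seed": 42,
    "backend": "threads",
    "run_dir": "cosim_run_IS",
    "throttle_s": {}
  }
}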