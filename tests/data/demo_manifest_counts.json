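{
  "simulate_rnaseq": {
    "n_features": 2000,
    "n_samples": 12,
    "n_affected": 100
  },
  "de_call": {
    "n_features": 2000,
    "n_up": 288,
    "n_down": 307,
    "n_conflicts": 8
  },
  "simulate_chip": {
    "n_peaks": 2000,
    "n_samples": 10,
    "n_affected": 40
  },
  "chip_signature": {
    "n_consensus": 2000,
    "n_supported": 1999,
    "component": 5,
    "n_pc_correlated": 42,
    "n_state_filtered": 33,
    "n_gene_annotated": 27,
    "n_subtracted_runs": 2000
  },
  "simulate_cohort": {
    "n_patients": 240,
    "n_events": 176
  },
  "stratify": {
    "n_patients": 240,
    "n_groups": 4,
    "n_events": 176,
    "logrank_p_lt_0.05": 1
  }
}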