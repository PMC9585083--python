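# Demonstration pipeline on synthetic data: paired transcriptome, paired
# acetylation-peak experiment, and a survival cohort, with the planted-effect
# conditions the generators default to.
seed: 42

rnaseq:
  n_patients: 6
  n_features: 2000
  frac_affected: 0.05
  effect_log2fc_mean: 1.0
  effect_log2fc_sd: 0.0
  patient_effect_sd: 0.3
  dispersion: 10.0
  lib_size_range: [500000.0, 2000000.0]

de_call:
  criterion: standard
  fc_threshold: 0.5
  pseudocount: 1.0

chip:
  n_patients: 5
  n_features: 2000
  pc_effect_frac: 0.02
  effect_log2fc_mean: 1.5
  effect_log2fc_sd: 0.0
  patient_effect_sd: 0.4
  dispersion: 100.0
  lib_size_range: [500000.0, 2000000.0]

chip_signature:
  component: auto
  alpha: 0.05
  min_support: 2
  promoter_extension: 1500

cohort:
  n_patients: 240
  baseline_hazard: 0.15
  hazard_ratio_risk_group: 3.0
  censoring_rate: 0.08
  mutation_odds_ratio_low_ciita: 2.0

stratify:
  notch_threshold: median
  ciita_threshold: median
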