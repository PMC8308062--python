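# Demo pipeline configuration: a small synthetic cohort with two diseases,
# sized so the full chain (simulate -> preprocess -> train PGS/BMRS/gBMRS/PRS
# -> evaluate -> calibrate) runs in a few minutes on one CPU.
seed: 1

simulation:
  n_samples: 1600
  n_snps: 300
  n_biomarkers: 5
  n_causal_per_biomarker: 12
  heritability_h2: 0.5
  shared_env_var: 0.15
  sex_offset: 0.4
  age_slope: 0.02
  repeat_noise_sd: 0.3
  n_sibling_pairs: 120
  maf_range: [0.05, 0.5]
  fst_divergence: 0.1
  disease_specs:
    - name: metabolic
      biomarker_weights: {bm01: 1.0, bm02: 0.6, bm03: 0.3}
      direct_genetic_weight: 0.3
      noise_var: 0.5
      prevalence: 0.15
    - name: cardiac
      biomarker_weights: {bm04: 0.8, bm05: 0.8}
      direct_genetic_weight: 0.0
      noise_var: 1.0
      prevalence: 0.1

solver:
  n_lambda: 40
  min_ratio: 0.001

splits:
  n_folds: 5
  n_validation: 80

predictors:
  dropped_biomarkers: []
  sex_stratified_bmrs: true

evaluation:
  percentiles: [50, 70, 80, 90, 95]
  sibling_thresholds: [0.5, 1.0, 1.5]
  n_boot: 100

calibration:
  n_bins: 20
  window: 5
  curve_bins: 10
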