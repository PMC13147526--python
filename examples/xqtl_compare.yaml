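# Three-scan comparison on the synthetic known-founder selection experiment.
# Any key omitted falls back to the defaults in poolscan.pipeline.XQTLConfig;
# unknown keys are hard errors.
experiment: xqtl_compare
xqtl:
  n_founders: 8
  region_bp: 400000
  max_sites: 20000
  map_length_cM: 100.0
  generations: 33
  n_replicates: 12
  n_control: 400
  n_case: 285
  selection_fraction: 0.07
  coverage_control_total: 983.0
  coverage_case_total: 739.0
  double_control_replicates: [5, 6, 8, 11, 12]
  qtl_cM: 50.0
  qtl_effect: 0.25
  env_sd: 1.0
  width_cM: 1.5
  step_cM: 0.25
  efficiency_k: 1.0
  threshold: 5.0
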