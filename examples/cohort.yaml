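# Control-cohort configuration for `fsclineage simulate`.
# Omitting `params` uses the built-in control parameterization
# (censuses 8/5/3, q_div from the control EdU gradient, p_fc = 0.616).
n_germaria: 500
snapshot_days: [6, 12]
edu_days: [6]
genotype: control
seed: 1
labeling:
  n_fsc_total: 16
  mean_labeled: 3.2
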