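# Full-pipeline configuration: simulate a default two-experiment study and
# run every analysis stage. Replace the `simulation` section with an
# `inputs` section (counts_exp1/counts_exp2/host/metadata TSV paths) to
# analyse real tables instead.
analysis:
  cumulative_abundance_threshold: 0.9995
  heatmap_p_threshold: 0.05
  host_fdr: 0.05
  asv_fdr: 0.1
  edge_p_threshold: 0.05
  n_null_networks: 10000
simulation:
  n_mice_per_group: 5
  n_experiments: 2
  n_asvs: 200
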